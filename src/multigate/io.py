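"""Reader/writer layer: GenBank, FASTA, GFF3, BED, TSV, YAML, JSON.

All in-memory coordinates are 0-based half-open on the top strand; GenBank
output uses the format's native 1-based convention (handled by biopython).
GenBank circularity is read from the LOCUS-line topology field; records
without one are treated as linear with a warning.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .seqcore import Feature, SequenceRecord

__all__ = [
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_bed",
    "write_tsv",
    "read_tsv",
    "load_yaml",
    "write_json_report",
]


def _to_internal(rec: SeqRecord, path: str = "") -> SequenceRecord:
    topology = rec.annotations.get("topology")
    if topology not in ("linear", "circular"):
        warnings.warn(f"{rec.id} ({path}): no topology on LOCUS line; assuming linear")
        topology = "linear"
    feats = []
    for f in rec.features:
        label = f.qualifiers.get("label", [f.type])[0]
        quals = tuple(
            (k, v[0] if isinstance(v, list) and v else str(v))
            for k, v in f.qualifiers.items() if k != "label"
        )
        feats.append(Feature(label=label, kind=f.type,
                             start=int(f.location.start), end=int(f.location.end),
                             strand=f.location.strand or 1, qualifiers=quals))
    return SequenceRecord(rec.id, str(rec.seq).upper(), topology, feats)


def _to_biopython(record: SequenceRecord) -> SeqRecord:
    rec = SeqRecord(Seq(record.bases), id=record.id, name=record.id[:16],
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    n = len(record.bases)
    for f in record.features:
        start, end = f.start, f.end
        if start >= end:  # origin-wrapping feature: emit as two-part location
            loc = FeatureLocation(start, n, f.strand) + FeatureLocation(0, end, f.strand)
        else:
            loc = FeatureLocation(start, end, f.strand)
        quals = {"label": [f.label]}
        quals.update({k: [v] for k, v in f.qualifiers})
        rec.features.append(SeqFeature(loc, type=f.kind or "misc_feature",
                                       qualifiers=quals))
    return rec


def read_genbank(path: str | Path) -> list[SequenceRecord]:
    return [_to_internal(r, str(path)) for r in SeqIO.parse(str(path), "genbank")]


def write_genbank(records: SequenceRecord | Iterable[SequenceRecord],
                  path: str | Path) -> None:
    if isinstance(records, SequenceRecord):
        records = [records]
    SeqIO.write([_to_biopython(r) for r in records], str(path), "genbank")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """FASTA with an optional 'circular'/'linear' token in the description
    (default linear)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        words = rec.description.split()
        topology = "circular" if "circular" in words else "linear"
        out.append(SequenceRecord(rec.id, str(rec.seq).upper(), topology))
    return out


def write_fasta(records: SequenceRecord | Iterable[SequenceRecord],
                path: str | Path) -> None:
    if isinstance(records, SequenceRecord):
        records = [records]
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id} {r.topology}\n")
            for i in range(0, len(r.bases), 70):
                fh.write(r.bases[i : i + 70] + "\n")


def read_gff3_genes(path: str | Path,
                    kinds: tuple[str, ...] = ("gene",)) -> list[dict]:
    """Features of the requested kinds from a GFF3 file, as dicts with 0-based
    half-open coordinates: seqid, kind, start, end, strand, attributes."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out = []
    for kind in kinds:
        for f in db.features_of_type(kind):
            out.append({
                "seqid": f.seqid,
                "kind": f.featuretype,
                "start": f.start - 1,  # GFF3 is 1-based inclusive
                "end": f.end,
                "strand": f.strand,
                "attributes": {k: v for k, v in f.attributes.items()},
            })
    out.sort(key=lambda d: (d["seqid"], d["start"]))
    return out


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED
    (already 0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(rows: list[dict], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype=str)


def load_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
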