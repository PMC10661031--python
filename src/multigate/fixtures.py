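"""Deterministic toy kit and toy genome generator.

Every other module is testable against this fixture set without any
downloads: a 96-entry plasmid registry mirroring the real kit's scale
(Level-0 parts, 10 marker cartridges, 18 prebuilt assembly cassettes, 18
spacers, 10 markerless integration vectors, 10 spacer vectors, and two
CRISPR backbones) plus a ~50 kb three-chromosome genome with exactly
``n_loci`` planted intergenic windows that satisfy the integration-locus
distance rules, each carrying one genome-unique Cas9 site at its center.

All payload sequence is random DNA domesticated to remove every BsaI /
BsmBI / BbsI / NotI site; reporter CDSs are labeled placeholder features,
not real ORFs.  Identical config + seed always produces byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .grammar import KitEntry, KitRegistry, PartRole, load_overhang_tables
from .seqcore import Feature, SequenceRecord, revcomp
from . import io as mio

__all__ = ["FixtureConfig", "ToyGenome", "generate_toy_genome",
           "generate_toy_kit", "make_fixtures", "FORBIDDEN_MOTIFS"]

# recognition sequences (both orientations) that payload DNA must never contain
FORBIDDEN_MOTIFS = ("GGTCTC", "GAGACC", "CGTCTC", "GAGACG",
                    "GAAGAC", "GTCTTC", "GCGGCCGC")
NOTI = "GCGGCCGC"
MARKER_NAMES = ("URA3", "LEU2", "HIS3", "TRP1", "LYS2",
                "MET17", "KanR", "NatR", "HygR", "ZeoR")


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 17
    n_loci: int = 10
    chromosomes: int = 3
    gene_length: int = 600
    invalid_gap: int = 1300   # too narrow to leave a legal window
    valid_gap: int = 1699     # leaves a 201 bp legal window
    arm_length: int = 500
    hom_core: int = 22        # random core of each 30 bp connector homology block
    start_threshold: int = 1000
    stop_threshold: int = 500
    # plant the chosen locus's protospacer a second time (inside a gene) to
    # exercise the uniqueness filter
    duplicate_protospacer_locus: int | None = None


# -- random DNA with domestication -------------------------------------------


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    seq = "".join(rng.choice(("A", "C", "G", "T"), size=n))
    return _domesticate(rng, seq)


def _domesticate(rng: np.random.Generator, seq: str) -> str:
    """Re-randomize any window containing a forbidden recognition motif."""
    s = list(seq)
    for _ in range(200):
        text = "".join(s)
        hit = None
        for motif in FORBIDDEN_MOTIFS:
            i = text.find(motif)
            if i >= 0:
                hit = (i, len(motif))
                break
        if hit is None:
            return text
        i, m = hit
        for k in range(i, i + m):
            s[k] = str(rng.choice(("A", "C", "G", "T")))
    raise RuntimeError("domestication did not converge")


def _scan_motifs(text: str, circular_len: int | None = None) -> set[tuple[str, int]]:
    """(motif, position) pairs in ``text``; when ``circular_len`` is given the
    text is expected to be the doubled circle and positions are reported
    modulo the circle."""
    hits = set()
    for motif in FORBIDDEN_MOTIFS:
        i = text.find(motif)
        while i >= 0:
            pos = i if circular_len is None else i % circular_len
            if circular_len is None or i < circular_len:
                hits.add((motif, pos))
            i = text.find(motif, i + 1)
    return hits


class _Builder:
    """Assemble a plasmid from fixed tokens and random filler.

    After filling, the builder verifies that every enzyme recognition motif
    in the final circle is one that the fixed tokens deliberately placed
    (computed by masking the random filler to N); if random filler created an
    extra site across a junction, the filler is redrawn.
    """

    def __init__(self) -> None:
        self.tokens: list[tuple[str, object]] = []  # ("f", seq) | ("r", length)
        self.features: list[Feature] = []
        self._pos = 0

    def add(self, seq: str | None = None, n: int | None = None,
            feature: tuple | None = None) -> "_Builder":
        if (seq is None) == (n is None):
            raise ValueError("give exactly one of seq / n")
        length = len(seq) if seq is not None else n
        if feature:
            label, kind, *quals = feature
            self.features.append(Feature(label, kind, self._pos,
                                         self._pos + length, 1,
                                         tuple(quals[0]) if quals else ()))
        self.tokens.append(("f", seq) if seq is not None else ("r", n))
        self._pos += length
        return self

    def build(self, record_id: str, rng: np.random.Generator,
              topology: str = "circular", max_tries: int = 60) -> SequenceRecord:
        masked = "".join(t if kind == "f" else "N" * t  # type: ignore[arg-type]
                         for kind, t in self.tokens)
        n = len(masked)
        designed = _scan_motifs(masked + masked, n) if topology == "circular" \
            else _scan_motifs(masked)
        for _ in range(max_tries):
            parts = [t if kind == "f" else _rand_dna(rng, t)  # type: ignore
                     for kind, t in self.tokens]
            bases = "".join(parts)
            got = _scan_motifs(bases + bases, n) if topology == "circular" \
                else _scan_motifs(bases)
            if got == designed:
                return SequenceRecord(record_id, bases, topology,
                                      list(self.features))
        raise RuntimeError(f"{record_id}: could not avoid stray enzyme sites")


# -- toy genome ---------------------------------------------------------------


@dataclass
class ToyGenome:
    records: list[SequenceRecord]
    annotation: list[dict]
    truth: list[dict]  # one row per planted locus

    def record(self, chrom: str) -> SequenceRecord:
        return next(r for r in self.records if r.id == chrom)


def _split_loci(n_loci: int, chromosomes: int) -> list[int]:
    base = n_loci // chromosomes
    extra = n_loci % chromosomes
    return [base + (1 if i < extra else 0) for i in range(chromosomes)]


def generate_toy_genome(config: FixtureConfig = FixtureConfig()) -> ToyGenome:
    """Random genome with planted genes arranged so that exactly
    ``config.n_loci`` intergenic windows satisfy the distance thresholds,
    each containing one genome-unique NGG target at its center."""
    rng = np.random.default_rng(config.seed)
    gl = config.gene_length
    records, annotation, truth = [], [], []
    planted: list[dict] = []

    for c, v_loci in enumerate(_split_loci(config.n_loci, config.chromosomes)):
        chrom = f"chr{c + 1}"
        # interleave: invalid, valid, invalid, valid, ..., invalid
        gaps: list[tuple[int, bool]] = [(config.invalid_gap, False)]
        for _ in range(v_loci):
            gaps.append((config.valid_gap, True))
            gaps.append((config.invalid_gap, False))
        pieces = [_rand_dna(rng, 100)]
        pos = 100
        gene_idx = 0

        def add_gene():
            nonlocal pos, gene_idx
            pieces.append(_rand_dna(rng, gl))
            annotation.append({"seqid": chrom, "kind": "gene", "start": pos,
                               "end": pos + gl, "strand": "+",
                               "attributes": {"ID": [f"{chrom}_g{gene_idx}"]}})
            pos += gl
            gene_idx += 1

        add_gene()
        for gap, valid in gaps:
            gap_seq = _rand_dna(rng, gap)
            if valid:
                ws = 498           # window start, relative to gap start
                plant_rel = ws + 89
                proto = _rand_dna(rng, 20)
                while proto[:2] == "CC" or proto[18:20] == "CC":
                    proto = _rand_dna(rng, 20)
                mer = proto + "TGG"
                gap_seq = (gap_seq[: plant_rel - 2] + "TA" + mer + "TA"
                           + gap_seq[plant_rel + 25:])
                planted.append({
                    "chrom": chrom,
                    "window_start": pos + ws,
                    "window_end": pos + gap - config.start_threshold,
                    "position": pos + plant_rel,
                    "strand": "+",
                    "protospacer": proto,
                    "pam": "TGG",
                    "cut_position": pos + plant_rel + 17,
                })
            pieces.append(gap_seq)
            pos += gap
            add_gene()
        pieces.append(_rand_dna(rng, 300))
        pos += 300
        records.append(SequenceRecord(chrom, "".join(pieces), "linear"))

    # optional second copy of one protospacer inside a gene body
    if config.duplicate_protospacer_locus is not None:
        row = planted[config.duplicate_protospacer_locus]
        mer = row["protospacer"] + row["pam"]
        rec = records[0]
        g0 = next(a for a in annotation if a["seqid"] == rec.id)
        i = g0["start"] + 50
        records[0] = SequenceRecord(
            rec.id, rec.bases[: i - 2] + "TA" + mer + "TA" + rec.bases[i + 25:],
            "linear")

    # planted 23-mers must be genome-unique (astronomically likely already)
    all_bases = [r.bases for r in records]
    for k, row in enumerate(planted):
        mer = row["protospacer"] + row["pam"]
        count = sum(b.count(mer) + b.count(revcomp(mer)) for b in all_bases)
        expect = 2 if k == config.duplicate_protospacer_locus else 1
        if count != expect:
            raise RuntimeError(f"planted target {k} occurs {count}x")
        row["locus"] = f"Int.{k + 1}"
        truth.append(row)

    return ToyGenome(records, annotation, truth)


# -- toy kit ------------------------------------------------------------------


def _bsa_open(oh: str) -> str:      # recognition upstream, cut releases oh
    return "GGTCTC" + "A" + oh


def _bsa_close(oh: str) -> str:     # oh, spacer, reverse-strand recognition
    return oh + "A" + "GAGACC"


def _bsmb_open(oh: str) -> str:
    return "CGTCTC" + "A" + oh


def _bsmb_close(oh: str) -> str:
    return oh + "A" + "GAGACG"


def _bbs_open(oh: str) -> str:
    return "GAAGAC" + "AA" + oh


def _bbs_close(oh: str) -> str:
    return oh + "AA" + "GTCTTC"


def _backbone_block(b: _Builder, n: int = 250) -> None:
    b.add(n=n // 2, feature=("ColE1_ori", "backbone"))
    b.add(n=n - n // 2, feature=("AmpR", "backbone"))


def _part_plasmid(pid: str, label: str, category: str, up: str, down: str,
                  core, rng: np.random.Generator) -> KitEntry:
    """Level-0 part: payload (up_oh + core) released clean by BsaI."""
    b = _Builder()
    _backbone_block(b)
    b.add(seq="GGTCTC" + "A")
    if callable(core):
        core(b, up)
    else:
        b.add(seq=up)
        b.add(n=core, feature=(label, _CORE_KIND.get(category, "misc_feature")))
    b.add(seq=_bsa_close(down))
    b.add(n=60)
    rec = b.build(pid, rng)
    return KitEntry(pid, rec, PartRole(category, up, down), {"label": label})


_CORE_KIND = {"type2": "promoter", "type3": "cds", "type3a": "cds",
              "type3b": "cds", "type4": "terminator", "type4a": "terminator",
              "type4b": "terminator", "type6": "marker", "type7": "rep_origin",
              "type8": "backbone"}


def _connector_blocks(tables: dict, rng: np.random.Generator,
                      hom_core: int) -> dict[str, dict[str, str]]:
    """Per-connector fixed sequences: the BsmBI overhang and the shared
    homology core R used in the gap-repair blocks.

    Each R is resampled until it creates no stray recognition site in either
    of the fixed contexts it will be embedded in (left- and right-connector
    blocks), since R becomes a fixed token that the builder's junction check
    cannot redraw."""
    out = {}
    for name, oh in tables["level2_connectors"].items():
        for _ in range(100):
            r = _rand_dna(rng, hom_core)
            ctx_left = NOTI + r + "GC" + "CGTCTC" + "A"
            ctx_right = oh + "A" + "GAGACG" + "GGCCGC" + r + NOTI
            masked_l = NOTI + "N" * hom_core + "GC" + "CGTCTC" + "A"
            masked_r = oh + "A" + "GAGACG" + "GGCCGC" + "N" * hom_core + NOTI
            if (_scan_motifs(ctx_left) == _scan_motifs(masked_l)
                    and _scan_motifs(ctx_right) == _scan_motifs(masked_r)):
                out[name] = {"oh": oh, "R": r}
                break
        else:
            raise RuntimeError(f"could not place homology core for {name}")
    return out


def _left_connector(b: _Builder, con: dict) -> None:
    """NotI site, homology completion, BsmBI cut releasing the connector
    overhang into the payload."""
    b.add(seq=NOTI)
    b.add(seq=con["R"] + "GC")
    b.add(seq="CGTCTC" + "A")
    b.add(seq=con["oh"])
    b.add(n=8)


def _right_connector(b: _Builder, con: dict) -> None:
    b.add(n=8)
    b.add(seq=_bsmb_close(con["oh"]))
    b.add(seq="GGCCGC" + con["R"])
    b.add(seq=NOTI)


def _cassette_plasmid(pid: str, position: int, terminal: bool, spacer: bool,
                      cons: dict, tables: dict,
                      rng: np.random.Generator) -> KitEntry:
    left = cons[f"con{position}"]
    right = cons["terminal" if terminal else f"con{position + 1}"]
    pt = tables["part_types"]
    b = _Builder()
    _backbone_block(b, 300)
    _left_connector(b, left)
    kind = "T" if terminal else "I"
    if spacer:
        b.add(n=8)
        b.add(n=120, feature=(f"Spacer-{position}{kind}", "spacer_payload"))
        b.add(n=8)
    else:
        # BsaI acceptor slot for a Level-1 TU (types 2-4), sfGFP dropout inside
        b.add(seq=pt["type2"]["upstream"])
        b.add(seq="A" + "GAGACC")
        b.add(n=10)
        b.add(n=120, feature=("sfGFP", "reporter_dropout", (("stage", "both"),)))
        b.add(n=10)
        b.add(seq="GGTCTC" + "A")
        b.add(seq=pt["type4"]["downstream"])
    _right_connector(b, right)
    rec = b.build(pid, rng)
    role = PartRole("spacer" if spacer else "cassette", left["oh"], right["oh"])
    return KitEntry(pid, rec, role,
                    {"position": position, "terminal": terminal})


def _marker_plasmid(pid: str, name: str, tables: dict,
                    rng: np.random.Generator) -> KitEntry:
    ms = tables["marker_swap"]
    b = _Builder()
    _backbone_block(b)
    b.add(seq=_bbs_open(ms["upstream"]))
    b.add(n=8)
    b.add(n=350, feature=(name, "marker"))
    b.add(n=8)
    b.add(seq=_bbs_close(ms["downstream"]))
    b.add(n=100)
    rec = b.build(pid, rng)
    return KitEntry(pid, rec, PartRole("marker_cartridge", ms["upstream"],
                                       ms["downstream"]), {"marker": name})


def _marker_acceptor(b: _Builder, tables: dict,
                     installed: str | None = None) -> None:
    """BbsI cloning site; the removable stuffer carries both recognition
    sites (and the currently installed marker, if any)."""
    ms = tables["marker_swap"]
    b.add(seq=ms["upstream"])
    b.add(seq="AA" + "GTCTTC")
    if installed:
        b.add(n=10)
        b.add(n=350, feature=(installed, "marker"))
        b.add(n=10)
    else:
        b.add(n=80, feature=("marker_stuffer", "stuffer"))
    b.add(seq="GAAGAC" + "AA")
    b.add(seq=ms["downstream"])


def _vector_plasmid(pid: str, locus: dict, genome: ToyGenome, cons: dict,
                    tables: dict, config: FixtureConfig,
                    rng: np.random.Generator) -> KitEntry:
    cut = locus["cut_position"]
    chrom_seq = genome.record(locus["chrom"]).bases
    arm5 = chrom_seq[cut - config.arm_length : cut]
    arm3 = chrom_seq[cut : cut + config.arm_length]
    con1, term = cons["con1"], cons["terminal"]
    b = _Builder()
    _backbone_block(b, 300)
    _marker_acceptor(b, tables)
    b.add(n=60)
    b.add(seq=NOTI)
    b.add(seq="TA")  # neutral separator: genomic arms are arbitrary sequence
    b.add(seq=arm5, feature=(f"{locus['locus']}-5p", "homology_arm",
                             (("side", "5p"),)))
    b.add(seq="TA")
    b.add(seq="GGCCGC" + con1["R"])
    b.add(seq=NOTI)
    b.add(seq=con1["R"] + "GC")
    b.add(n=8)
    b.add(seq=con1["oh"])
    b.add(seq="A" + "GAGACG")
    b.add(n=10)
    b.add(n=120, feature=("mScarlet", "reporter_dropout", (("stage", "ecoli"),)))
    b.add(n=10)
    b.add(n=120, feature=("mScarlet", "reporter_dropout", (("stage", "yeast"),)))
    b.add(n=10)
    b.add(seq="CGTCTC" + "A")
    b.add(seq=term["oh"])
    b.add(n=8)
    b.add(seq="GGCCGC" + term["R"])
    b.add(seq=NOTI)
    b.add(seq=term["R"] + "GC")
    b.add(seq="TA")
    b.add(seq=arm3, feature=(f"{locus['locus']}-3p", "homology_arm",
                             (("side", "3p"),)))
    b.add(seq="TA")
    b.add(seq=NOTI)
    rec = b.build(pid, rng)
    meta = {"locus": locus["locus"], "locus_chrom": locus["chrom"],
            "cut_position": cut, "marker": None}
    return KitEntry(pid, rec, PartRole("integration_vector", con1["oh"],
                                       term["oh"]), meta)


def _spacer_vector_plasmid(pid: str, locus: dict, genome: ToyGenome,
                           tables: dict, config: FixtureConfig,
                           rng: np.random.Generator) -> KitEntry:
    cut = locus["cut_position"]
    chrom_seq = genome.record(locus["chrom"]).bases
    b = _Builder()
    _backbone_block(b, 300)
    _marker_acceptor(b, tables)
    b.add(n=60)
    b.add(seq=NOTI)
    b.add(seq="TA")
    b.add(seq=chrom_seq[cut - config.arm_length : cut],
          feature=(f"{locus['locus']}-5p", "homology_arm", (("side", "5p"),)))
    b.add(n=150, feature=(f"Spacer-{locus['locus']}", "spacer_payload"))
    b.add(seq=chrom_seq[cut : cut + config.arm_length],
          feature=(f"{locus['locus']}-3p", "homology_arm", (("side", "3p"),)))
    b.add(seq="TA")
    b.add(seq=NOTI)
    rec = b.build(pid, rng)
    return KitEntry(pid, rec, PartRole("spacer_vector"),
                    {"locus": locus["locus"], "marker": None})


def _crispr_plasmid(pid: str, tables: dict, rng: np.random.Generator,
                    transient: bool) -> KitEntry:
    arr = tables["array_fusion_sites"]
    b = _Builder()
    _backbone_block(b, 300)
    b.add(seq=NOTI)
    b.add(n=40)
    b.add(n=600, feature=("Cas9", "cds"))
    b.add(n=30)
    if not transient:
        _marker_acceptor(b, tables, installed="URA3")
        b.add(n=30)
    b.add(seq=arr["head"])
    b.add(seq="A" + "GAGACC")
    b.add(n=10)
    b.add(n=150, feature=("sfGFP", "reporter_dropout", (("stage", "both"),)))
    b.add(n=10)
    # scaffold starts TA / tRNA ends TA so user spacers abutting them in PCR
    # products can never complete a recognition motif across the junction
    scaffold_start = b._pos
    b.add(seq="TA")
    b.add(n=58)
    b.features.append(Feature("scaffold", "scaffold", scaffold_start,
                              b._pos, 1))
    trna_start = b._pos
    b.add(n=58)
    b.add(seq="TA")
    b.features.append(Feature("tRNA", "tRNA", trna_start, b._pos, 1))
    b.add(n=10)
    b.add(n=150, feature=("mScarlet", "reporter_dropout", (("stage", "both"),)))
    b.add(n=10)
    b.add(seq="GGTCTC" + "A")
    b.add(seq=arr["tail"])
    b.add(n=40)
    rec = b.build(pid, rng)
    meta = {"marker": None if transient else "URA3", "transient": transient}
    return KitEntry(pid, rec, PartRole("crispr_backbone", arr["head"],
                                       arr["tail"]), meta)


def generate_toy_kit(config: FixtureConfig = FixtureConfig(),
                     genome: ToyGenome | None = None) -> KitRegistry:
    """Build the full 96-entry toy registry (deterministic in config.seed)."""
    rng = np.random.default_rng(config.seed + 1_000_000)
    tables = load_overhang_tables()
    pt = tables["part_types"]
    if genome is None:
        genome = generate_toy_genome(config)
    cons = _connector_blocks(tables, rng, config.hom_core)
    reg = KitRegistry(overhangs=tables)
    counter = iter(range(1, 200))

    def pid() -> str:
        return f"pTOY{next(counter):03d}"

    def tp(cat):  # (up, down) for a part type
        return pt[cat]["upstream"], pt[cat]["downstream"]

    # -- Level-0 parts (28) --
    def conl1_core(b: _Builder, up: str) -> None:
        b.add(seq=up)
        _left_connector(b, cons["con1"])

    def conre_core(b: _Builder, up: str) -> None:
        b.add(seq=up)
        _right_connector(b, cons["terminal"])
        b.add(n=8)

    reg.add(_part_plasmid(pid(), "ConL1", "type1", *tp("type1"), conl1_core, rng))
    for i in range(8):
        reg.add(_part_plasmid(pid(), f"pProm{i + 1}", "type2", *tp("type2"), 200, rng))
    for i in range(2):
        reg.add(_part_plasmid(pid(), f"ToyCDS{i + 1}", "type3", *tp("type3"), 400, rng))
    for i in range(2):
        reg.add(_part_plasmid(pid(), f"ToyCDS3a_{i + 1}", "type3a", *tp("type3a"), 300, rng))
    for i in range(2):
        reg.add(_part_plasmid(pid(), f"ToyCDS3b_{i + 1}", "type3b", *tp("type3b"), 300, rng))
    for i in range(4):
        reg.add(_part_plasmid(pid(), f"tTerm{i + 1}", "type4", *tp("type4"), 150, rng))
    reg.add(_part_plasmid(pid(), "tTerm4a", "type4a", *tp("type4a"), 100, rng))
    reg.add(_part_plasmid(pid(), "tTerm4b", "type4b", *tp("type4b"), 100, rng))
    reg.add(_part_plasmid(pid(), "ConRE-T", "type5", *tp("type5"), conre_core, rng))
    for i in range(2):
        reg.add(_part_plasmid(pid(), f"YeastMarker{i + 1}", "type6", *tp("type6"), 200, rng))
    for i in range(2):
        reg.add(_part_plasmid(pid(), f"YeastOri{i + 1}", "type7", *tp("type7"), 150, rng))
    for i in range(2):
        reg.add(_part_plasmid(pid(), f"EcoliBackbone{i + 1}", "type8", *tp("type8"), 300, rng))

    # -- marker cartridges (10) --
    for name in MARKER_NAMES:
        reg.add(_marker_plasmid(pid(), name, tables, rng))

    # -- 18 assembly cassettes, then 18 spacers --
    configurations = ([(p, False) for p in range(1, 10)]
                      + [(p, True) for p in range(2, 11)])
    for spacer in (False, True):
        for position, terminal in configurations:
            reg.add(_cassette_plasmid(pid(), position, terminal, spacer,
                                      cons, tables, rng))

    # -- integration vectors (10) + spacer vectors (10) --
    for locus in genome.truth:
        reg.add(_vector_plasmid(pid(), locus, genome, cons, tables, config, rng))
    for locus in genome.truth:
        reg.add(_spacer_vector_plasmid(pid(), locus, genome, tables, config, rng))

    # -- CRISPR backbones --
    reg.add(_crispr_plasmid(pid(), tables, rng, transient=False))
    reg.add(_crispr_plasmid(pid(), tables, rng, transient=True))
    return reg


# -- disk output --------------------------------------------------------------


def _write_gff3(annotation: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, a in enumerate(annotation):
            attrs = a.get("attributes", {})
            ident = attrs.get("ID", [f"feat{i}"])[0]
            fh.write("\t".join([
                a["seqid"], "toy", a["kind"], str(a["start"] + 1), str(a["end"]),
                ".", a["strand"], ".", f"ID={ident}"]) + "\n")


def make_fixtures(config: FixtureConfig, out_dir: str | Path) -> tuple[KitRegistry, ToyGenome]:
    """Write the complete fixture set: kit directory (GenBank + manifest),
    genome FASTA, GFF3 annotation, and the planted-locus truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_toy_genome(config)
    kit = generate_toy_kit(config, genome)
    kit.save(out / "kit")
    mio.write_fasta(genome.records, out / "genome.fasta")
    _write_gff3(genome.annotation, out / "genome.gff3")
    mio.write_tsv(genome.truth, out / "loci_truth.tsv")
    return kit, genome
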