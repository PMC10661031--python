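"""Genomic integration-locus selection.

Candidate loci are intergenic windows in which every position is more than
1 kb from the nearest start codon and more than 0.5 kb from the nearest stop
codon of any gene (strand-aware; distances to the codon's first base), does
not fall inside a gene body, and overlaps none of a blacklist of fragile
features (tRNA/rRNA/ARS/LTR/telomere by default).  Within a window the tool
enumerates Cas9 target sites (20-mer + NGG on either strand), keeps only
those whose 23-mer is unique in the whole genome, and ranks them by distance
from the window center.  Homology arms of ~500 bp are then taken on either
side of the cut site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seqcore import SequenceRecord, revcomp

__all__ = [
    "LocusDesignError",
    "TargetSite",
    "HomologyArm",
    "LocusCandidate",
    "start_stop_codon_positions",
    "scan_intergenic",
    "pick_target_site",
    "extract_homology_arms",
    "longest_shared_repeat",
    "occurs_in_all",
    "design_loci",
]

START_THRESHOLD = 1000  # bp; integration site must be > this from any start codon
STOP_THRESHOLD = 500    # bp; and > this from any stop codon
ARM_LENGTH = 500
DEFAULT_BLACKLIST = ("tRNA", "rRNA", "ARS", "LTR", "telomere",
                     "tRNA_gene", "rRNA_gene", "long_terminal_repeat")


class LocusDesignError(ValueError):
    pass


@dataclass(frozen=True)
class TargetSite:
    chrom: str
    position: int       # top-strand start of the 23-mer (protospacer+PAM)
    strand: str         # '+' or '-'
    protospacer: str    # 20 nt, 5'->3' on the targeted strand
    pam: str            # 3 nt
    cut_position: int   # top-strand coordinate of the blunt Cas9 cut

    @property
    def site_23mer(self) -> str:
        return (self.protospacer + self.pam if self.strand == "+"
                else revcomp(self.protospacer + self.pam))


@dataclass(frozen=True)
class HomologyArm:
    chrom: str
    start: int
    end: int
    sequence: str


@dataclass(frozen=True)
class LocusCandidate:
    chrom: str
    window: tuple[int, int]
    target: TargetSite
    arm5: HomologyArm
    arm3: HomologyArm


def start_stop_codon_positions(gene: dict) -> tuple[int, int]:
    """(start-codon first base, stop-codon first base) for a gene dict with
    0-based half-open ``start``/``end`` and ``strand``."""
    s, e = gene["start"], gene["end"]
    if gene["strand"] == "+":
        return s, e - 3
    if gene["strand"] == "-":
        return e - 1, s + 2
    raise ValueError("gene without strand")


def scan_intergenic(genome: list[SequenceRecord], annotation: list[dict],
                    start_threshold: int = START_THRESHOLD,
                    stop_threshold: int = STOP_THRESHOLD,
                    blacklist_kinds: tuple[str, ...] = DEFAULT_BLACKLIST,
                    ) -> list[tuple[str, int, int]]:
    """Maximal windows in which every position passes all distance rules.

    ``annotation`` is a list of feature dicts (see io.read_gff3_genes);
    entries of kind 'gene' define codon distances and excluded bodies,
    blacklisted kinds are excluded outright.  Genes without a strand are
    skipped with a warning.  Windows are sorted by (chromosome, start).
    """
    masks = {g.id: np.ones(len(g.bases), dtype=bool) for g in genome}

    def exclude(chrom: str, a: int, b: int) -> None:
        if chrom in masks:
            n = len(masks[chrom])
            masks[chrom][max(a, 0):min(b, n)] = False

    for feat in annotation:
        chrom, kind = feat["seqid"], feat["kind"]
        if kind in blacklist_kinds:
            exclude(chrom, feat["start"], feat["end"])
            continue
        if kind != "gene":
            continue
        if feat.get("strand") not in ("+", "-"):
            warnings.warn(f"gene at {chrom}:{feat['start']} has no strand; skipped")
            continue
        c_start, c_stop = start_stop_codon_positions(feat)
        exclude(chrom, feat["start"], feat["end"])                      # gene body
        exclude(chrom, c_start - start_threshold, c_start + start_threshold + 1)
        exclude(chrom, c_stop - stop_threshold, c_stop + stop_threshold + 1)

    windows: list[tuple[str, int, int]] = []
    for g in genome:
        mask = masks[g.id]
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))
                                       .astype(np.int8)))
        for a, b in zip(edges[::2], edges[1::2]):
            windows.append((g.id, int(a), int(b)))
    return sorted(windows)


def _all_23mer_hits(genome: list[SequenceRecord], mer: str) -> int:
    count = 0
    rc = revcomp(mer)
    for g in genome:
        for needle in {mer, rc}:
            i = g.bases.find(needle)
            while i >= 0:
                count += 1
                i = g.bases.find(needle, i + 1)
    return count


def pick_target_site(window: tuple[str, int, int],
                     genome: list[SequenceRecord]) -> list[TargetSite]:
    """All genome-unique Cas9 sites inside a window, ranked by distance from
    the window center (deterministic ties: position, then strand)."""
    chrom, start, end = window
    record = next(g for g in genome if g.id == chrom)
    if end - start < 23:
        return []
    bases = record.bases
    center = (start + end) / 2
    candidates: list[TargetSite] = []
    for i in range(start, end - 23 + 1):
        mer = bases[i : i + 23]
        if "N" in mer:
            continue
        if mer[21:23] == "GG":
            candidates.append(TargetSite(chrom, i, "+", mer[:20], mer[20:23],
                                         cut_position=i + 17))
        if mer[0:2] == "CC":
            candidates.append(TargetSite(chrom, i, "-", revcomp(mer[3:23]),
                                         revcomp(mer[0:3]), cut_position=i + 6))
    unique = [t for t in candidates
              if _all_23mer_hits(genome, bases[t.position : t.position + 23]) == 1]
    unique.sort(key=lambda t: (abs((t.position + 11.5) - center), t.position,
                               t.strand))
    return unique


def extract_homology_arms(record: SequenceRecord, cut_position: int,
                          arm_length: int = ARM_LENGTH,
                          genome: list[SequenceRecord] | None = None,
                          ) -> tuple[HomologyArm, HomologyArm]:
    """The ``arm_length`` bases immediately upstream and downstream of a cut.

    Raises on insufficient flank; warns (does not fail) when an arm's exact
    sequence occurs more than once in the genome, since recombination could
    then target the wrong copy.
    """
    n = len(record.bases)
    if cut_position < arm_length or cut_position + arm_length > n:
        raise LocusDesignError(
            f"cut at {cut_position} leaves less than {arm_length} bp of flank")
    arm5 = HomologyArm(record.id, cut_position - arm_length, cut_position,
                       record.bases[cut_position - arm_length : cut_position])
    arm3 = HomologyArm(record.id, cut_position, cut_position + arm_length,
                       record.bases[cut_position : cut_position + arm_length])
    if genome is not None:
        for arm, side in ((arm5, "5'"), (arm3, "3'")):
            if _all_23mer_hits(genome, arm.sequence) != 1:
                warnings.warn(f"{side} arm at {record.id}:{arm.start} is not "
                              "genome-unique")
    return arm5, arm3


def _shared_kmer(a: str, b: str, k: int) -> str | None:
    if k == 0 or k > len(a) or k > len(b):
        return None
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    for i in range(len(b) - k + 1):
        if b[i : i + k] in kmers:
            return b[i : i + k]
    return None


def _longest_common_substring(a: str, b: str) -> str:
    lo, hi, best = 0, min(len(a), len(b)), ""
    while lo < hi:  # binary search on length; shared k-mer => shared j-mer for j<k
        mid = (lo + hi + 1) // 2
        hit = _shared_kmer(a, b, mid)
        if hit is not None:
            best, lo = hit, mid
        else:
            hi = mid - 1
    return best


def longest_shared_repeat(sequences: list[str],
                          include_revcomp: bool = True,
                          ) -> tuple[int, tuple[int, int], str, bool]:
    """Longest substring shared by any pair of sequences, in either
    orientation.

    Returns (length, (i, j), substring, on_reverse_complement).  Used to
    enforce the design rule that co-installed promoters/parts share at most a
    couple of dozen bases of repeat, minimizing recombination between them.
    """
    if len(sequences) < 2:
        raise LocusDesignError("need at least two sequences")
    seqs = [s.upper() for s in sequences]
    best = (0, (0, 1), "", False)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            fwd = _longest_common_substring(seqs[i], seqs[j])
            if len(fwd) > best[0]:
                best = (len(fwd), (i, j), fwd, False)
            if include_revcomp:
                rev = _longest_common_substring(seqs[i], revcomp(seqs[j]))
                if len(rev) > best[0]:
                    best = (len(rev), (i, j), rev, True)
    return best


def occurs_in_all(needles: list[str], genomes: list[list[SequenceRecord]]) -> bool:
    """True iff every needle occurs exactly once (either strand) in every
    supplied genome -- the conservation filter applied across strains."""
    return all(_all_23mer_hits(g, s) == 1 for g in genomes for s in needles)


def design_loci(genome: list[SequenceRecord], annotation: list[dict],
                start_threshold: int = START_THRESHOLD,
                stop_threshold: int = STOP_THRESHOLD,
                arm_length: int = ARM_LENGTH,
                blacklist_kinds: tuple[str, ...] = DEFAULT_BLACKLIST,
                extra_genomes: list[list[SequenceRecord]] | None = None,
                ) -> list[LocusCandidate]:
    """Full pipeline: scan windows, pick the best unique target per window,
    extract arms; optionally restrict to candidates conserved (exact match of
    protospacer and both arms) in every extra genome."""
    out: list[LocusCandidate] = []
    for window in scan_intergenic(genome, annotation, start_threshold,
                                  stop_threshold, blacklist_kinds):
        targets = pick_target_site(window, genome)
        record = next(g for g in genome if g.id == window[0])
        for target in targets:
            try:
                arm5, arm3 = extract_homology_arms(record, target.cut_position,
                                                   arm_length, genome)
            except LocusDesignError:
                continue
            if extra_genomes and not occurs_in_all(
                    [target.site_23mer, arm5.sequence, arm3.sequence],
                    extra_genomes):
                continue
            out.append(LocusCandidate(window[0], (window[1], window[2]),
                                      target, arm5, arm3))
            break  # best-ranked viable target only
    return out
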