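"""In-yeast gap-repair assembly planning.

NotI digestion releases homology-armed fragments from the integration vector
and the Level-1 cassettes; co-transformed into yeast, the cell's homologous
recombination machinery stitches them together wherever their ends share
sequence.  The planner models that as an overlap graph (exact suffix-prefix
matches of at least ``min_overlap`` bp) and demands a *unique* Hamiltonian
path from the vector's 5' homology arm to its 3' arm -- any ambiguity is an
error, never a silent choice, because in vivo it would produce a mixture.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from .seqcore import Enzyme, Fragment, SequenceRecord, digest, revcomp

__all__ = [
    "GapRepairError",
    "AmbiguousPathError",
    "HomologyJunction",
    "IntegrationPlan",
    "PrimerPair",
    "release_fragments",
    "plan_gap_repair",
    "predict_junction_amplicons",
]

DEFAULT_MIN_OVERLAP = 20  # conservative floor for yeast homologous recombination
DISCARD_FEATURE_KINDS = ("backbone", "reporter_dropout")


class GapRepairError(ValueError):
    pass


class AmbiguousPathError(GapRepairError):
    def __init__(self, paths):
        self.paths = paths
        super().__init__(
            f"{len(paths)} distinct fragment orders satisfy the overlaps: "
            + "; ".join(" -> ".join(p) for p in paths))


@dataclass(frozen=True)
class HomologyJunction:
    upstream_id: str
    downstream_id: str
    overlap_length: int
    overlap_sequence: str


@dataclass
class IntegrationPlan:
    locus: SequenceRecord
    chain: list[Fragment]
    junctions: list[HomologyJunction]
    integrated: SequenceRecord
    replaced_interval: tuple[int, int]  # locus coordinates substituted


def _frag_id(f: Fragment) -> str:
    if f.provenance:
        p = f.provenance[0]
        return f"{p.record_id}[{p.start}:{p.end}]"
    return f"fragment({len(f.bases)}bp)"


def release_fragments(pool: list[SequenceRecord], noti: Enzyme,
                      min_expected_sites: int = 2) -> list[Fragment]:
    """NotI-digest every record and keep the assembly-relevant fragments.

    Fragments annotated as plasmid backbone or as a reporter dropout are
    discarded (they carry no homology into the final construct).  A record
    with fewer NotI sites than expected is passed through uncut with a
    warning -- the wet-lab equivalent of an undigested plasmid in the pot.
    """
    released: list[Fragment] = []
    for record in pool:
        frags = digest(record, noti)
        n_cuts = len(frags) if record.is_circular or len(frags) == 1 else len(frags) - 1
        if len(frags) == 1 and frags[0].left_end.kind == "blunt":
            n_cuts = 0
        if n_cuts < min_expected_sites:
            warnings.warn(
                f"{record.id}: only {n_cuts} NotI cut(s) "
                f"(expected >= {min_expected_sites}); passed through uncut")
            released.append(Fragment(
                record.bases, provenance=frags[0].provenance,
                features=tuple(record.features)))
            continue
        for f in frags:
            if any(ft.kind in DISCARD_FEATURE_KINDS for ft in f.features):
                continue
            released.append(f)
    return released


def _overlap(a: str, b: str, min_overlap: int, max_overlap: int = 500) -> int:
    """Longest k with min_overlap <= k such that a's suffix of length k equals
    b's prefix of length k (0 if none)."""
    top = min(len(a), len(b), max_overlap)
    for k in range(top, min_overlap - 1, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


def _arm_fragments(fragments: list[Fragment]) -> tuple[int, int]:
    five, three = [], []
    for i, f in enumerate(fragments):
        for ft in f.features:
            if ft.kind == "homology_arm":
                side = dict(ft.qualifiers).get("side")
                (five if side == "5p" else three).append(i)
    if len(five) != 1 or len(three) != 1:
        raise GapRepairError(
            f"need exactly one 5' and one 3' arm fragment; "
            f"found {len(five)} and {len(three)}")
    return five[0], three[0]


def plan_gap_repair(fragments: list[Fragment], locus: SequenceRecord,
                    min_overlap: int = DEFAULT_MIN_OVERLAP,
                    crispr_cut: int | None = None) -> IntegrationPlan:
    """Chain released fragments into the unique integrated-locus product.

    The chain must start at the fragment carrying the 5' homology arm and end
    at the 3' arm, visiting every fragment once.  The final sequence is the
    genomic locus with the segment between the arm matches replaced by the
    overlap-merged chain.  ``crispr_cut`` (a locus coordinate) optionally
    asserts that the transient CRISPR target falls inside the replaced
    segment between the arms.
    """
    if not fragments:
        raise GapRepairError("no fragments to assemble")
    start, goal = _arm_fragments(fragments)
    n = len(fragments)
    ov = [[0] * n for _ in range(n)]
    for i, j in itertools.product(range(n), repeat=2):
        if i != j:
            ov[i][j] = _overlap(fragments[i].bases, fragments[j].bases, min_overlap)

    paths: list[list[int]] = []

    def extend(path: list[int], used: set[int]) -> None:
        if len(paths) > 1:
            return  # two paths already prove ambiguity
        here = path[-1]
        if here == goal:
            if len(path) == n:
                paths.append(list(path))
            return
        for j in range(n):
            if j not in used and ov[here][j]:
                path.append(j)
                used.add(j)
                extend(path, used)
                path.pop()
                used.remove(j)

    extend([start], {start})
    if not paths:
        loose = [
            _frag_id(f) for i, f in enumerate(fragments)
            if (not any(ov[i][j] for j in range(n)) and i != goal)
            or (not any(ov[j][i] for j in range(n)) and i != start)
        ]
        raise GapRepairError(
            "no fragment order satisfies the overlaps; unmatched ends on: "
            + (", ".join(loose) or "(all fragments connect, but no full path)"))
    if len(paths) > 1:
        raise AmbiguousPathError([[ _frag_id(fragments[i]) for i in p] for p in paths])

    order = paths[0]
    chain = [fragments[i] for i in order]
    merged = chain[0].bases
    offsets = [0]  # offset of each fragment's start within the merged string
    junctions: list[HomologyJunction] = []
    for prev, nxt in zip(order, order[1:]):
        k = ov[prev][nxt]
        junctions.append(HomologyJunction(
            _frag_id(fragments[prev]), _frag_id(fragments[nxt]), k,
            fragments[nxt].bases[:k]))
        offsets.append(len(merged) - k)
        merged += fragments[nxt].bases[k:]

    # locate genomic arm sequences in the locus and splice
    def arm_info(idx_in_order: int, frag: Fragment) -> tuple[str, int]:
        feat = next(ft for ft in frag.features if ft.kind == "homology_arm")
        seq = frag.bases[feat.start:feat.end]
        return seq, offsets[idx_in_order] + feat.start

    arm5_seq, arm5_off = arm_info(order.index(start), fragments[start])
    arm3_seq, arm3_off = arm_info(order.index(goal), fragments[goal])
    pos5 = locus.bases.find(arm5_seq)
    pos3 = locus.bases.find(arm3_seq)
    if pos5 < 0 or pos3 < 0:
        raise GapRepairError("homology arm sequence not found in the locus record")
    if locus.bases.find(arm5_seq, pos5 + 1) >= 0 or locus.bases.find(arm3_seq, pos3 + 1) >= 0:
        warnings.warn("homology arm matches the locus more than once")
    if pos3 < pos5:
        raise GapRepairError("3' arm maps upstream of the 5' arm in the locus")
    replaced = (pos5, pos3 + len(arm3_seq))
    if crispr_cut is not None:
        # closed interval: arms designed around the cut abut exactly at it
        inner = (pos5 + len(arm5_seq), pos3)
        if not inner[0] <= crispr_cut <= inner[1]:
            raise GapRepairError(
                f"CRISPR cut site {crispr_cut} lies outside the replaced "
                f"segment {inner}")
    payload = merged[arm5_off : arm3_off + len(arm3_seq)]
    integrated = SequenceRecord(
        f"{locus.id}_integrated",
        locus.bases[:pos5] + payload + locus.bases[replaced[1]:],
        locus.topology)
    return IntegrationPlan(locus, chain, junctions, integrated, replaced)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str  # 5'->3', binds the top strand
    reverse: str  # 5'->3', binds the bottom strand

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if set(seq.upper()) - set("ACGT"):
                raise ValueError(f"primer {self.name}: non-ACGT bases")


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def predict_junction_amplicons(
        plan: IntegrationPlan,
        primers: list[PrimerPair]) -> list[tuple[str, int | None]]:
    """Colony-PCR amplicon sizes across the assembly junctions.

    A primer binds where its full sequence matches exactly (forward on the
    top strand, reverse on the bottom); the amplicon length is the distance
    between the two outer 5' ends, or None if either primer is unbound or
    the pair points apart.  The i-th pair is reported against the i-th
    junction.
    """
    template = plan.integrated.bases
    out: list[tuple[str, int | None]] = []
    for i, pair in enumerate(primers):
        jid = (f"junction_{i + 1}" if i < len(plan.junctions)
               else f"extra_{i + 1}")
        fwd_hits = _find_all(template, pair.forward.upper())
        rev_hits = _find_all(template, revcomp(pair.reverse.upper()))
        for label, hits in (("forward", fwd_hits), ("reverse", rev_hits)):
            if len(hits) > 1:
                warnings.warn(
                    f"{pair.name}: {label} primer binds {len(hits)} positions "
                    f"{hits}")
        if not fwd_hits or not rev_hits:
            out.append((jid, None))
            continue
        # smallest convergent product
        best: int | None = None
        for f_pos in fwd_hits:
            for r_pos in rev_hits:
                end = r_pos + len(pair.reverse)
                if end > f_pos:
                    length = end - f_pos
                    if best is None or length < best:
                        best = length
        out.append((jid, best))
    return out
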