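"""Golden Gate assembly engine.

Models the one-pot cycled digestion/ligation reaction: every input plasmid is
digested with the Type IIS enzyme, fragments that still carry a recognition
site are treated as reaction intermediates (the thermocycler program re-cuts
them until none remain) and excluded, and the surviving fragments are chained
through a directed fusion-site graph.  Each distinct simple cycle of that
graph is a circular product -- the only kind of DNA that propagates in the
host, so linear concatemers are reported only as diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .seqcore import (
    Enzyme,
    Fragment,
    SequenceRecord,
    Provenance,
    canonical_circular,
    digest,
    find_sites,
    ligate,
    revcomp,
)

__all__ = [
    "AssemblyProduct",
    "AssemblyResult",
    "OverhangSet",
    "OverhangValidation",
    "assemble_golden_gate",
    "validate_overhang_set",
]


@dataclass
class AssemblyProduct:
    """One circular assembly outcome with ordered provenance."""

    sequence: SequenceRecord
    parts_order: list[tuple[Provenance, ...]]
    junctions: list[str]

    def __post_init__(self) -> None:
        if self.junctions and len(self.junctions) != len(self.parts_order):
            raise ValueError("junction count must equal fragment count")

    @property
    def canonical(self) -> str:
        return canonical_circular(self.sequence.bases)


@dataclass
class AssemblyResult:
    """Products of one reaction plus bookkeeping the wet-lab screen would
    give you: whether the outcome is forced (unique) and which fusion sites
    were left dangling when no circle could close."""

    products: list[AssemblyProduct] = field(default_factory=list)
    unique: bool = False
    ambiguous: bool = False
    dangling: list[str] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.products)

    def __len__(self) -> int:
        return len(self.products)

    def __getitem__(self, i):
        return self.products[i]

    def require_unique(self) -> AssemblyProduct:
        """The single forced product, or a ValueError with the diagnostics."""
        if self.unique and len(self.products) == 1:
            return self.products[0]
        detail = "; ".join(self.diagnostics) or "ambiguous assembly"
        raise ValueError(
            f"assembly is not unique ({len(self.products)} product(s)): {detail}")


def _cycle_product(frags: list[Fragment]) -> AssemblyProduct:
    seq = ligate(frags, circular=True, record_id="assembly")
    junctions = [f.left_end.seq for f in frags]
    return AssemblyProduct(seq, [f.provenance for f in frags], junctions)


def assemble_golden_gate(pool: list[SequenceRecord], enzyme: Enzyme) -> AssemblyResult:
    """Simulate a one-pot Golden Gate reaction over ``pool``.

    Returns one :class:`AssemblyProduct` per distinct simple cycle of the
    fusion-site graph, deduplicated under circular rotation/strand.  The
    result is flagged unique iff exactly one product exists and every fusion
    site occurs on at most one left end and one right end.  Circular records
    the enzyme does not cut pass through unchanged (they survive the
    reaction), which makes the operation idempotent on its own products.
    """
    if not pool:
        raise ValueError("empty assembly pool")
    if not enzyme.type_iis:
        raise ValueError(f"{enzyme.name} is not a Type IIS enzyme")

    result = AssemblyResult()
    keep: list[Fragment] = []
    for record in pool:
        frags = digest(record, enzyme)
        if record.is_circular and len(frags) == 1 and frags[0].left_end.kind == "blunt":
            # uncut plasmid: survives the pot as-is
            result.products.append(
                AssemblyProduct(record, [frags[0].provenance], []))
            continue
        for f in frags:
            if f.left_end.kind != "fusion" or f.right_end.kind != "fusion":
                result.diagnostics.append(
                    f"linear/blunt fragment from {f.provenance[0].record_id} ignored")
                continue
            if f.has_site(enzyme):
                # reaction intermediate; gets re-cut during cycling
                continue
            keep.append(f)

    graph = nx.DiGraph()
    graph.add_nodes_from(range(len(keep)))
    for i, a in enumerate(keep):
        for j, b in enumerate(keep):
            if a.right_end.seq == b.left_end.seq:
                graph.add_edge(i, j)

    seen: dict[str, AssemblyProduct] = {}
    for cycle in nx.simple_cycles(graph):
        product = _cycle_product([keep[i] for i in cycle])
        seen.setdefault(product.canonical, product)
    result.products.extend(seen.values())

    lefts = [f.left_end.seq for f in keep]
    rights = [f.right_end.seq for f in keep]
    collision_free = all(lefts.count(s) <= 1 for s in set(lefts)) and all(
        rights.count(s) <= 1 for s in set(rights))
    result.unique = len(result.products) == 1 and collision_free
    result.ambiguous = len(result.products) > 1 or not collision_free
    if result.ambiguous:
        result.diagnostics.append(
            f"{len(result.products)} distinct circular product(s); "
            "fusion sites reused" if not collision_free else
            f"{len(result.products)} distinct circular product(s)")

    if not result.products:
        unmatched_left = sorted(set(lefts) - set(rights))
        unmatched_right = sorted(set(rights) - set(lefts))
        result.dangling = sorted(set(unmatched_left + unmatched_right))
        result.diagnostics.append(
            "no circular product; dangling fusion sites: "
            + (", ".join(result.dangling) or "none"))
    return result


@dataclass(frozen=True)
class OverhangSet:
    """A set of 4-nt fusion sites intended to be used together in one pot."""

    sites: tuple[str, ...]

    def __post_init__(self) -> None:
        for s in self.sites:
            if len(s) != 4 or set(s) - set("ACGT"):
                raise ValueError(f"malformed overhang {s!r}: must be 4 nt over ACGT")


@dataclass
class OverhangValidation:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_overhang_set(s: OverhangSet, min_pair_mismatches: int = 1) -> OverhangValidation:
    """Check a fusion-site set for ligation crosstalk hazards.

    Flags duplicates, palindromic (self-reverse-complement) sites,
    reverse-complement pairs, and any pair whose site-versus-reverse-
    complement-of-the-other Hamming distance is below
    ``min_pair_mismatches`` (a simple mispairing heuristic: an overhang
    anneals to the reverse complement of whichever site it mispairs with).
    """
    report = OverhangValidation()
    sites = list(s.sites)
    seen: set[str] = set()
    for site in sites:
        if site in seen:
            report.violations.append(f"duplicate site {site}")
        seen.add(site)
        if site == revcomp(site):
            report.violations.append(f"palindromic site {site}")
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            if a == revcomp(b):
                report.violations.append(f"reverse-complement pair {a}/{b}")
            elif _hamming(a, revcomp(b)) < min_pair_mismatches:
                report.violations.append(
                    f"crosstalk pair {a}/{b} "
                    f"(distance {_hamming(a, revcomp(b))} < {min_pair_mismatches})")
    return report
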