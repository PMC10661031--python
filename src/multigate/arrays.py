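"""Multiplexed gRNA-tRNA array design and assembly simulation.

Arrays follow the tRNA-spaced architecture: each PCR-derived fragment carries
one 20-nt spacer followed by the gRNA scaffold and a tRNA, with primer tails
adding BsaI sites whose overhangs chain the fragments in order into the CRISPR
backbone's dropout slot.  In vivo the tRNAs are processed out, releasing the
individual guides; here we only model the DNA design and the one-pot BsaI
assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .assembly import AssemblyProduct, assemble_golden_gate
from .grammar import GrammarError, KitEntry, predict_screen_color
from .seqcore import Enzyme, SequenceRecord, find_sites, revcomp

__all__ = [
    "ArrayDesignError",
    "GuideSpacer",
    "SpacerReport",
    "ArrayPrimer",
    "ArrayDesign",
    "validate_spacer",
    "design_array_primers",
    "simulate_pcr",
    "simulate_array_assembly",
    "extract_spacers",
]

SPACER_LENGTH = 20
ANNEAL_LENGTH = 20
MAX_ARRAY = 10


class ArrayDesignError(ValueError):
    pass


@dataclass(frozen=True)
class GuideSpacer:
    name: str
    sequence: str
    target_locus: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class SpacerReport:
    """Per-check outcome of spacer validation (True = pass, None = skipped)."""

    checks: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(v is not False for v in self.checks.values())


def _count_hits(genome: SequenceRecord, needle: str) -> list[tuple[int, str]]:
    hits = []
    for strand, seq in (("+", needle), ("-", revcomp(needle))):
        i = genome.bases.find(seq)
        while i >= 0:
            hits.append((i, strand))
            i = genome.bases.find(seq, i + 1)
    return sorted(hits)


def validate_spacer(spacer: GuideSpacer, enzymes: dict[str, Enzyme],
                    genome: SequenceRecord | None = None) -> SpacerReport:
    """Report every design-rule check for one spacer.

    Checks: 20-nt length; no internal recognition site of any assembly enzyme
    (BsaI/BsmBI/BbsI/NotI); and, when a genome is supplied, a single exact
    protospacer match with NGG immediately 3'.
    """
    report = SpacerReport()
    seq = spacer.sequence
    report.checks["length"] = len(seq) == SPACER_LENGTH
    if set(seq) - set("ACGT"):
        report.checks["alphabet"] = False
        report.notes.append("non-ACGT characters")
    else:
        report.checks["alphabet"] = True
    rec = SequenceRecord(spacer.name or "spacer", seq or "N", "linear")
    clean = True
    for enz in enzymes.values():
        if find_sites(rec, enz):
            clean = False
            report.notes.append(f"contains {enz.name} site")
    report.checks["no_internal_sites"] = clean
    if genome is None:
        report.checks["genome_unique"] = None
        report.checks["pam"] = None
        return report
    hits = _count_hits(genome, seq) if report.checks["length"] else []
    report.checks["genome_unique"] = len(hits) == 1
    if len(hits) != 1:
        report.notes.append(f"{len(hits)} genome matches")
        report.checks["pam"] = False
        return report
    pos, strand = hits[0]
    g = genome.bases
    if strand == "+":
        pam = g[pos + SPACER_LENGTH : pos + SPACER_LENGTH + 3]
    else:
        pam = revcomp(g[max(pos - 3, 0) : pos])
    report.checks["pam"] = len(pam) == 3 and pam[1:] == "GG"
    if not report.checks["pam"]:
        report.notes.append(f"PAM {pam!r} is not NGG")
    return report


@dataclass(frozen=True)
class ArrayPrimer:
    name: str
    forward: str
    reverse: str
    fwd_anneal: int = ANNEAL_LENGTH
    rev_anneal: int = ANNEAL_LENGTH


@dataclass
class ArrayDesign:
    spacers: list[GuideSpacer]
    primers: list[ArrayPrimer]
    fusion_sites: list[tuple[str, str]]  # (left, right) per fragment
    template_id: str


def _array_fusions(n: int, tables: dict) -> list[tuple[str, str]]:
    t = tables["array_fusion_sites"]
    sites = []
    for i in range(1, n + 1):
        left = t["head"] if i == 1 else t[f"internal_{i - 1}"]
        right = t["tail"] if i == n else t[f"internal_{i}"]
        sites.append((left, right))
    return sites


def _template_feature(entry: KitEntry, kind: str):
    for f in entry.record.features:
        if f.kind == kind:
            return f
    raise ArrayDesignError(f"{entry.id}: no {kind} feature on the template")


def design_array_primers(spacers: list[GuideSpacer], template: KitEntry,
                         tables: dict) -> ArrayDesign:
    """One primer pair per gRNA-tRNA fragment.

    The forward tail encodes a BsaI site, the position's fusion overhang and
    the spacer; the reverse tail encodes the next position's overhang behind
    its own BsaI site.  First/last fragments carry the backbone-matching
    head/tail overhangs.
    """
    n = len(spacers)
    if not 1 <= n <= MAX_ARRAY:
        raise ArrayDesignError(f"array size {n} outside 1..{MAX_ARRAY}")
    seen: dict[str, str] = {}
    for s in spacers:
        if s.sequence in seen:
            raise ArrayDesignError(
                f"duplicate spacer {s.name}/{seen[s.sequence]}: arrays with "
                "repeated spacers recombine and mis-assemble")
        seen[s.sequence] = s.name
        if len(s.sequence) != SPACER_LENGTH:
            raise ArrayDesignError(f"spacer {s.name} is not {SPACER_LENGTH} nt")

    scaffold_f = _template_feature(template, "scaffold")
    trna_f = _template_feature(template, "tRNA")
    scaffold = template.record.slice(scaffold_f.start, scaffold_f.end)
    trna = template.record.slice(trna_f.start, trna_f.end)

    fusions = _array_fusions(n, tables)
    primers = []
    for spacer, (left, right) in zip(spacers, fusions):
        # the TA buffer after the fusion site cannot extend any Type IIS /
        # NotI recognition motif across the junction (none contains TA)
        fwd = ("CC" + "GGTCTC" + "A" + left + "TA" + spacer.sequence
               + scaffold[:ANNEAL_LENGTH])
        rev_top_tail = right + "A" + "GAGACC" + "GG"
        rev = revcomp(trna[-ANNEAL_LENGTH:] + rev_top_tail)
        primers.append(ArrayPrimer(f"{spacer.name}", fwd, rev))
    return ArrayDesign(list(spacers), primers, fusions, template.id)


def simulate_pcr(template: SequenceRecord, primer: ArrayPrimer) -> SequenceRecord:
    """Exact-match PCR: each primer's 3' annealing block must match the
    template exactly and uniquely; tails are appended verbatim."""
    f_anneal = primer.forward[-primer.fwd_anneal:]
    r_anneal_top = revcomp(primer.reverse[-primer.rev_anneal:])
    doubled = (template.bases + template.bases) if template.is_circular else template.bases
    a = doubled.find(f_anneal)
    b = doubled.find(r_anneal_top, a + 1 if a >= 0 else 0)
    if a < 0 or b < 0:
        raise ArrayDesignError(
            f"primer {primer.name}: annealing block not found on template "
            f"{template.id}")
    top = primer.forward[:-primer.fwd_anneal] + doubled[a : b + len(r_anneal_top)] \
        + revcomp(primer.reverse[:-primer.rev_anneal])
    return SequenceRecord(f"pcr_{primer.name}", top, "linear")


def simulate_array_assembly(design: ArrayDesign, backbone: KitEntry,
                            enzymes: dict[str, Enzyme]) -> AssemblyProduct:
    """PCR every fragment off the backbone's template region, then run the
    one-pot BsaI assembly into the backbone.  The unique product has lost the
    sfGFP/mScarlet dropout and carries the spacers 5'->3' in design order."""
    if not design.spacers:
        raise ArrayDesignError("empty array design")
    products = [simulate_pcr(backbone.record, p) for p in design.primers]
    result = assemble_golden_gate(products + [backbone.record], enzymes["BsaI"])
    product = result.require_unique()
    scaffold_f = _template_feature(backbone, "scaffold")
    scaffold = backbone.record.slice(scaffold_f.start, scaffold_f.end)
    got = extract_spacers(product.sequence, scaffold)
    want = [s.sequence for s in design.spacers]
    if got != want:
        raise ArrayDesignError(
            f"assembled spacer order {got} != designed order {want}")
    if predict_screen_color(product, "ecoli") != "white":
        raise GrammarError("array product still carries a dropout reporter")
    return product


def extract_spacers(record: SequenceRecord, scaffold: str,
                    spacer_length: int = SPACER_LENGTH) -> list[str]:
    """Read the spacers back out of an assembled array by scaffold anchoring.

    On a circular record the array is located as the run of scaffold hits
    downstream of the longest scaffold-free stretch (the backbone)."""
    bases = record.bases
    n = len(bases)
    doubled = bases + bases if record.is_circular else bases
    hits = []
    i = doubled.find(scaffold)
    while i >= 0 and i < n:
        hits.append(i)
        i = doubled.find(scaffold, i + 1)
    if not hits:
        return []
    if record.is_circular and len(hits) > 1:
        gaps = [(hits[(k + 1) % len(hits)] - h) % n for k, h in enumerate(hits)]
        first = (gaps.index(max(gaps)) + 1) % len(hits)
        hits = hits[first:] + hits[:first]
    out = []
    for h in hits:
        start = h - spacer_length
        if record.is_circular:
            out.append(doubled[start + n : h + n] if start < 0 else doubled[start:h])
        else:
            out.append(bases[max(start, 0):h])
    return out
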