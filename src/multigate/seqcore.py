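"""Sequence data model, restriction-site scanning, and Type IIS digestion.

This module is the substrate for the whole assembly engine.  DNA molecules are
:class:`SequenceRecord` objects (linear or circular, 0-based half-open,
top-strand coordinates).  Digestion with a Type IIS enzyme such as BsaI cuts at
a fixed offset outside the recognition site and leaves a short 5' extension --
the *fusion site* (overhang) that Golden Gate cloning uses to program fragment
order.  Fragments store their fusion sites normalized to the top-strand
sequence the junction will have after ligation, so two ends are joinable iff
the upstream fragment's right fusion string equals the downstream fragment's
left fusion string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import yaml

__all__ = [
    "Feature",
    "SequenceRecord",
    "Enzyme",
    "RecognitionSite",
    "End",
    "Fragment",
    "Provenance",
    "revcomp",
    "iupac_match",
    "find_sites",
    "digest",
    "ligate",
    "canonical_circular",
    "records_equal",
    "load_enzymes",
    "BUILTIN_ENZYME_PATH",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# IUPAC code -> set of concrete bases it stands for.  N in the *sequence* is
# deliberately absent from every set: an ambiguous genome base never calls a
# restriction site (conservative site calling).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(seq: str, pattern: str) -> bool:
    """True iff ``seq`` (concrete bases) matches ``pattern`` (IUPAC)."""
    if len(seq) != len(pattern):
        return False
    for s, p in zip(seq, pattern):
        if s not in IUPAC.get(p, ""):
            return False
    return True


@dataclass(frozen=True)
class Feature:
    """Annotated interval on a record (0-based half-open; circular features
    may wrap, in which case start > end)."""

    label: str
    kind: str
    start: int
    end: int
    strand: int = 1
    qualifiers: tuple = ()


@dataclass
class SequenceRecord:
    """A DNA molecule: uppercase bases over {A,C,G,T,N}, linear or circular."""

    id: str
    bases: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear|circular, got {self.topology!r}")
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise ValueError(f"record {self.id}: non-DNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def slice(self, start: int, end: int) -> str:
        """Top-strand bases of [start, end); wraps the origin on circular
        records (indices taken modulo length)."""
        n = len(self.bases)
        if self.is_circular:
            start %= n
            end %= n
            if end == start:
                return ""
            if end > start:
                return self.bases[start:end]
            return self.bases[start:] + self.bases[:end]
        if not (0 <= start <= end <= n):
            raise IndexError(f"[{start}, {end}) outside linear record of length {n}")
        return self.bases[start:end]

    def rotated(self, offset: int) -> "SequenceRecord":
        """Same circular molecule with the origin moved to ``offset``."""
        if not self.is_circular:
            raise ValueError("cannot rotate a linear record")
        n = len(self.bases)
        offset %= n
        feats = [
            replace(f, start=(f.start - offset) % n, end=(f.end - offset) % n)
            for f in self.features
        ]
        return SequenceRecord(self.id, self.bases[offset:] + self.bases[:offset],
                              "circular", feats)

    def feature_sequence(self, feat: Feature) -> str:
        s = self.slice(feat.start, feat.end)
        return s if feat.strand >= 0 else revcomp(s)


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme geometry.

    For Type IIS enzymes the cut offsets are measured downstream from the 3'
    end of the recognition site on the recognition strand (REBASE "(1/5)"
    style).  For within-site cutters (``type_iis=False``) the offsets are
    measured from the 5' start of the recognition site.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int
    type_iis: bool = True

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition length must be >= 4")
        if abs(self.cut_top - self.cut_bottom) > 8:
            raise ValueError(f"{self.name}: overhang longer than 8 nt unsupported")

    @property
    def overhang_length(self) -> int:
        return abs(self.cut_top - self.cut_bottom)


@dataclass(frozen=True, order=True)
class RecognitionSite:
    """One occurrence of a recognition pattern (position of its first base on
    the top strand; '-' means the pattern's reverse complement is on top)."""

    position: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class End:
    """Fragment terminus: blunt, a 4-nt fusion site, or a homology terminus."""

    kind: str  # 'blunt' | 'fusion' | 'homology'
    seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("blunt", "fusion", "homology"):
            raise ValueError(f"bad end kind {self.kind!r}")
        if self.kind == "fusion" and not self.seq:
            raise ValueError("fusion end requires a site sequence")


BLUNT = End("blunt")


@dataclass(frozen=True)
class Provenance:
    record_id: str
    start: int
    end: int


@dataclass(frozen=True)
class Fragment:
    """Double-stranded piece written as its top strand 5'->3'.

    By convention a fragment *includes* the single-stranded 5' extension at
    its left end and *excludes* the extension at its right end, so that
    ligating upstream+downstream is plain string concatenation and every
    junction's 4 nt are counted exactly once.
    """

    bases: str
    left_end: End = BLUNT
    right_end: End = BLUNT
    provenance: tuple[Provenance, ...] = ()
    features: tuple[Feature, ...] = ()

    def __len__(self) -> int:
        return len(self.bases)

    def has_site(self, enzyme: Enzyme) -> bool:
        """True if the double-stranded core still carries a recognition site
        of ``enzyme`` (on either strand)."""
        rec = SequenceRecord("_frag", self.bases, "linear")
        return bool(find_sites(rec, enzyme))


def _scan_one_strand(bases: str, pattern: str, circular: bool) -> Iterator[int]:
    n, m = len(bases), len(pattern)
    if n == 0 or m == 0 or (not circular and m > n):
        return
    search = bases + bases[: m - 1] if circular else bases
    limit = n if circular else n - m + 1
    for i in range(limit):
        if iupac_match(search[i : i + m], pattern):
            yield i


def find_sites(record: SequenceRecord, enzyme: Enzyme) -> list[RecognitionSite]:
    """All occurrences of the enzyme's recognition pattern on either strand.

    Circular records are scanned across the origin.  Deterministic order:
    ascending position, '+' before '-'.
    """
    pattern = enzyme.recognition.upper()
    rc = revcomp(pattern)
    hits = [RecognitionSite(p, "+") for p in
            _scan_one_strand(record.bases, pattern, record.is_circular)]
    hits += [RecognitionSite(p, "-") for p in
             _scan_one_strand(record.bases, rc, record.is_circular)]
    return sorted(hits, key=lambda s: (s.position, s.strand))


def _cut_pair(site: RecognitionSite, enzyme: Enzyme) -> tuple[int, int]:
    """(top_cut, bottom_cut) coordinates for one site.

    A cut coordinate c means the backbone is severed between positions c-1 and
    c on that strand (top-strand coordinates throughout).
    """
    p, m = site.position, len(enzyme.recognition)
    if enzyme.type_iis:
        if site.strand == "+":
            return p + m + enzyme.cut_top, p + m + enzyme.cut_bottom
        return p - enzyme.cut_bottom, p - enzyme.cut_top
    # within-site cutter (e.g. NotI): offsets from the recognition 5' start
    if site.strand == "+":
        return p + enzyme.cut_top, p + enzyme.cut_bottom
    return p + m - enzyme.cut_bottom, p + m - enzyme.cut_top


def digest(record: SequenceRecord, enzyme: Enzyme) -> list[Fragment]:
    """Complete digestion of ``record`` with ``enzyme``.

    Linear record with n internal cuts -> n+1 fragments (blunt outer ends);
    circular record with n >= 1 cuts -> n fragments, each carrying two fusion
    ends.  A record with no cuts comes back as a single uncut fragment.  Cut
    positions that fall off the end of a linear record are skipped with a
    warning (the enzyme cannot cut past the molecule's end).
    """
    n = len(record.bases)
    sites = find_sites(record, enzyme)
    cuts: list[tuple[int, int]] = []
    for site in sites:
        top, bottom = _cut_pair(site, enzyme)
        if record.is_circular:
            t = top % n
            cuts.append((t, t + (bottom - top)))
        else:
            if not (0 <= top <= n and 0 <= bottom <= n):
                warnings.warn(
                    f"{record.id}: {enzyme.name} site at {site.position}{site.strand} "
                    f"cuts outside the linear record; skipped"
                )
                continue
            cuts.append((top, bottom))
    # dedupe double-counted palindromic sites and coincident cuts
    uniq: dict[int, tuple[int, int]] = {}
    for top, bottom in cuts:
        lo = min(top, bottom)
        boundary = lo % n if record.is_circular else lo
        uniq.setdefault(boundary, (top, bottom))
    boundaries = sorted(uniq)

    prov = lambda a, b: (Provenance(record.id, a, b),)

    if not boundaries:
        return [Fragment(record.bases, BLUNT, BLUNT, prov(0, n),
                         tuple(record.features))]

    def overhang_at(boundary: int) -> End:
        top, bottom = uniq[boundary]
        length = abs(bottom - top)
        if length == 0:
            return BLUNT
        return End("fusion", record.slice(boundary, boundary + length))

    frags: list[Fragment] = []
    if record.is_circular:
        for i, b in enumerate(boundaries):
            nxt = boundaries[(i + 1) % len(boundaries)]
            if nxt == b:  # single cut: linearize the whole circle
                seq = record.bases[b:] + record.bases[:b]
            else:
                seq = record.slice(b, nxt)
            frags.append(
                Fragment(seq, overhang_at(b), overhang_at(nxt), prov(b, nxt),
                         _features_within(record, b, nxt)))
        return frags
    edges = [0] + boundaries + [n]
    for a, b in zip(edges, edges[1:]):
        if a == b:
            continue
        left = overhang_at(a) if a in uniq else BLUNT
        right = overhang_at(b) if b in uniq else BLUNT
        frags.append(Fragment(record.bases[a:b], left, right, prov(a, b),
                              _features_within(record, a, b)))
    return frags


def _features_within(record: SequenceRecord, start: int, end: int) -> tuple[Feature, ...]:
    """Features fully contained in [start, end), re-based to the fragment."""
    n = len(record.bases)
    span = (end - start) % n if record.is_circular and end != start else end - start
    if span <= 0:
        span += n
    out = []
    for f in record.features:
        if record.is_circular:
            length = (f.end - f.start) % n
            fs = (f.start - start) % n
            fe = fs + length
        else:
            fs, fe = f.start - start, f.end - start
        if 0 <= fs and fe <= span and fs < fe:
            out.append(replace(f, start=fs, end=fe))
    return tuple(out)


def ligate(fragments: list[Fragment], circular: bool = True,
           record_id: str = "ligation") -> SequenceRecord:
    """Join fragments in the given order, enforcing the fusion-site
    normalization rule at every junction (including the closing junction for
    circular ligations)."""
    if not fragments:
        raise ValueError("nothing to ligate")
    pairs = list(zip(fragments, fragments[1:]))
    if circular:
        pairs.append((fragments[-1], fragments[0]))
    for up, down in pairs:
        if up.right_end.kind != "fusion" or down.left_end.kind != "fusion":
            raise ValueError("cannot ligate non-fusion ends")
        if up.right_end.seq != down.left_end.seq:
            raise ValueError(
                f"fusion mismatch: {up.right_end.seq} != {down.left_end.seq}")
    bases = "".join(f.bases for f in fragments)
    feats: list[Feature] = []
    off = 0
    for f in fragments:
        feats.extend(replace(ft, start=ft.start + off, end=ft.end + off)
                     for ft in f.features)
        off += len(f.bases)
    return SequenceRecord(record_id, bases,
                          "circular" if circular else "linear", feats)


def _min_rotation(s: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm)."""
    if not s:
        return s
    ss = s + s
    n = len(s)
    i, j, k = 0, 1, 0
    while i < n and j < n and k < n:
        a, b = ss[i + k], ss[j + k]
        if a == b:
            k += 1
            continue
        if a > b:
            i = max(i + k + 1, j)
        else:
            j = max(j + k + 1, i)
        if i == j:
            j += 1
        k = 0
    start = min(i, j)
    return ss[start : start + n]


def canonical_circular(bases: str) -> str:
    """Canonical form of a circular sequence: the smaller of the minimal
    rotations of the top strand and its reverse complement.  Two circular
    molecules are biologically identical iff their canonical forms match."""
    return min(_min_rotation(bases), _min_rotation(revcomp(bases)))


def records_equal(a: SequenceRecord, b: SequenceRecord) -> bool:
    """Biological equality: rotation- and strand-invariant for circular
    records; sequence or reverse-complement identity for linear ones."""
    if a.topology != b.topology:
        return False
    if a.is_circular:
        return canonical_circular(a.bases) == canonical_circular(b.bases)
    return a.bases == b.bases or a.bases == revcomp(b.bases)


BUILTIN_ENZYME_PATH = "data/enzymes.yaml"


def load_enzymes(path: Optional[str | Path] = None) -> dict[str, Enzyme]:
    """Load the enzyme geometry table (YAML).  Defaults to the packaged table
    covering BsaI, BsmBI, BbsI, and NotI."""
    if path is None:
        text = resources.files("multigate").joinpath(BUILTIN_ENZYME_PATH).read_text()
    else:
        text = Path(path).read_text()
    table = yaml.safe_load(text)
    out: dict[str, Enzyme] = {}
    for name, spec in table.items():
        out[name] = Enzyme(
            name=name,
            recognition=spec["recognition"].upper(),
            cut_top=int(spec["cut_top"]),
            cut_bottom=int(spec["cut_bottom"]),
            type_iis=bool(spec.get("type_iis", True)),
        )
    return out
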