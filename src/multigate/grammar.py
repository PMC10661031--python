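"""Part-type and connector grammar for the modular-cloning kit.

The kit follows the MoClo yeast standard: Level-0 parts (types 1-8, with 3a/3b
and 4a/4b subtypes) carry fixed BsaI fusion sites that force their order in a
Level-1 transcriptional-unit (TU) cassette; cassettes carry BsmBI connector
fusion sites that force their position in a Level-2 multigene construct of up
to 10 TUs inside an integration vector.  Selectable markers are exchanged
through a separate BbsI reaction so any of the 10 markers can be placed in any
of the 10 integration vectors.

Cassette-position model: an internal cassette at position i carries connectors
i -> i+1; a terminal cassette at position i carries connector i -> terminal.
Nine internal (positions 1-9) plus nine terminal (positions 2-10)
configurations cover every assembly size from 2 to 10 TUs -- the kit's 18
prebuilt cassettes.  A single-TU construct is assembled directly with
position-1 terminal connectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .assembly import AssemblyProduct, AssemblyResult, assemble_golden_gate
from .seqcore import Enzyme, SequenceRecord, canonical_circular, digest, find_sites
from . import io as mio

__all__ = [
    "GrammarError",
    "AmbiguityError",
    "UnsupportedCountError",
    "IncompatibleMarkerError",
    "PartRole",
    "ConnectorScheme",
    "KitEntry",
    "KitRegistry",
    "load_overhang_tables",
    "plan_level1",
    "plan_level2",
    "swap_marker",
    "predict_screen_color",
    "validate_kit",
]

PART_CATEGORIES = (
    "type1", "type2", "type3", "type3a", "type3b", "type4", "type4a", "type4b",
    "type5", "type6", "type7", "type8",
)
OTHER_CATEGORIES = (
    "cassette", "spacer", "integration_vector", "spacer_vector",
    "marker_cartridge", "crispr_backbone", "genome",
)


class GrammarError(ValueError):
    """A pool of parts violates the kit grammar."""


class AmbiguityError(GrammarError):
    """More than one part competes for the same fusion interval."""


class UnsupportedCountError(GrammarError):
    """Requested TU count outside what the connector scheme supports."""


class IncompatibleMarkerError(GrammarError):
    """Marker cartridge and target do not share BbsI fusion sites."""


@dataclass(frozen=True)
class PartRole:
    """Grammar role of a kit entry.

    For payload entries (parts, cassettes, spacers, markers) the fusion pair
    is that of the released payload; for acceptor entries (integration
    vectors, the CRISPR backbone) it is the interval the acceptor's dropout
    spans, i.e. the chain must start at ``upstream_fusion`` and end at
    ``downstream_fusion``.
    """

    category: str
    upstream_fusion: str = ""
    downstream_fusion: str = ""

    def __post_init__(self) -> None:
        if self.category not in PART_CATEGORIES + OTHER_CATEGORIES:
            raise ValueError(f"unknown part category {self.category!r}")


@dataclass
class KitEntry:
    id: str
    record: SequenceRecord
    role: PartRole
    metadata: dict = field(default_factory=dict)


def load_overhang_tables(path: str | Path | None = None) -> dict:
    """Fusion-site tables (part types, Level-2 connectors, array sites,
    marker-swap pair).  Defaults to the packaged tables."""
    if path is None:
        text = resources.files("multigate").joinpath("data/overhangs.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


class ConnectorScheme:
    """Connector assignments for multigene assemblies of 1-10 TUs."""

    MAX_TUS = 10

    def __init__(self, connectors: dict[str, str]):
        # connectors: {"con1": "AACC", ..., "con10": ..., "terminal": ...}
        self.connector_sites = dict(connectors)
        missing = [k for k in
                   [f"con{i}" for i in range(1, self.MAX_TUS + 1)] + ["terminal"]
                   if k not in connectors]
        if missing:
            raise ValueError(f"connector table missing {missing}")

    def site(self, name: str) -> str:
        return self.connector_sites[name]

    def cassette_sites(self, position: int, terminal: bool) -> tuple[str, str]:
        """(left, right) fusion sites of a cassette at ``position``."""
        if not 1 <= position <= self.MAX_TUS:
            raise UnsupportedCountError(
                f"position {position} outside 1..{self.MAX_TUS}")
        left = self.site(f"con{position}")
        if terminal:
            return left, self.site("terminal")
        if position == self.MAX_TUS:
            raise UnsupportedCountError(
                f"position {self.MAX_TUS} must be terminal")
        return left, self.site(f"con{position + 1}")

    def chain(self, n_tus: int) -> list[tuple[int, bool]]:
        """(position, is_terminal) for each cassette of an ``n_tus``
        assembly."""
        if not 1 <= n_tus <= self.MAX_TUS:
            raise UnsupportedCountError(
                f"{n_tus} TUs unsupported (standard scheme covers 1..{self.MAX_TUS})")
        return [(i, i == n_tus) for i in range(1, n_tus + 1)]

    def required_configurations(self, sizes=range(2, 11)) -> set[tuple[int, bool]]:
        """Distinct prebuilt cassette configurations needed to cover every
        assembly size in ``sizes`` (18 for the standard 2..10 range)."""
        needed: set[tuple[int, bool]] = set()
        for n in sizes:
            needed.update(self.chain(n))
        return needed


class KitRegistry:
    """Catalog of kit entries with grammar roles and metadata."""

    def __init__(self, entries: list[KitEntry] | None = None,
                 overhangs: dict | None = None):
        self.entries: dict[str, KitEntry] = {}
        self.overhangs = overhangs or load_overhang_tables()
        for e in entries or []:
            self.add(e)

    def add(self, entry: KitEntry) -> None:
        if entry.id in self.entries:
            raise ValueError(f"duplicate kit entry {entry.id}")
        self.entries[entry.id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key: str) -> KitEntry:
        return self.entries[key]

    def __iter__(self):
        return iter(self.entries.values())

    def by_category(self, *categories: str) -> list[KitEntry]:
        return [e for e in self if e.role.category in categories]

    @property
    def scheme(self) -> ConnectorScheme:
        return ConnectorScheme(self.overhangs["level2_connectors"])

    # -- persistence: directory of GenBank files + YAML manifest -------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"overhangs": self.overhangs, "entries": {}}
        for e in self:
            fname = f"{e.id}.gb"
            mio.write_genbank(e.record, directory / fname)
            manifest["entries"][e.id] = {
                "file": fname,
                "category": e.role.category,
                "upstream_fusion": e.role.upstream_fusion,
                "downstream_fusion": e.role.downstream_fusion,
                "metadata": e.metadata,
            }
        (directory / "manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "KitRegistry":
        directory = Path(directory)
        manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
        reg = cls(overhangs=manifest.get("overhangs"))
        for eid, spec in sorted(manifest["entries"].items()):
            (record,) = mio.read_genbank(directory / spec["file"])
            record.id = eid
            reg.add(KitEntry(
                id=eid,
                record=record,
                role=PartRole(spec["category"], spec.get("upstream_fusion", ""),
                              spec.get("downstream_fusion", "")),
                metadata=spec.get("metadata") or {},
            ))
        return reg


# -- planners ----------------------------------------------------------------


def _interval_name(tables: dict, upstream: str) -> str:
    """Human-readable name of the part-type interval starting at a fusion
    site, for grammar diagnostics."""
    for name, pair in tables["part_types"].items():
        if pair["upstream"] == upstream:
            return name
    return upstream


def check_level1_grammar(parts: list[KitEntry], backbone: KitEntry,
                         tables: dict) -> list[KitEntry]:
    """Walk the fusion chain from the backbone's acceptor interval and report
    grammar violations before any simulation.  Returns the parts in chain
    order."""
    if backbone.role.category == "cassette":
        # prebuilt cassette backbones accept the type 2-4 interval by BsaI
        cursor = tables["part_types"]["type2"]["upstream"]
        stop = tables["part_types"]["type4"]["downstream"]
    elif backbone.role.category in PART_CATEGORIES:
        # a type-8 style backbone part: the chain continues from its payload
        # end all the way around to its payload start
        cursor = backbone.role.downstream_fusion
        stop = backbone.role.upstream_fusion
    else:
        cursor = backbone.role.upstream_fusion
        stop = backbone.role.downstream_fusion
    remaining = list(parts)
    ordered: list[KitEntry] = []
    for _ in range(len(parts) + 1):
        if cursor == stop and not remaining:
            return ordered
        candidates = [p for p in remaining if p.role.upstream_fusion == cursor]
        if not candidates:
            raise GrammarError(
                f"no part spans fusion interval {_interval_name(tables, cursor)} "
                f"(cursor {cursor})")
        if len(candidates) > 1:
            names = ", ".join(p.id for p in candidates)
            raise AmbiguityError(
                f"fusion interval {_interval_name(tables, cursor)} is ambiguous: "
                f"{names}")
        part = candidates[0]
        ordered.append(part)
        remaining.remove(part)
        cursor = part.role.downstream_fusion
    raise GrammarError(f"chain does not close at {stop}; stuck at {cursor}")


def plan_level1(parts: list[KitEntry], backbone_cassette: KitEntry,
                enzymes: dict[str, Enzyme],
                tables: dict | None = None) -> AssemblyProduct:
    """Plan a Level-1 (BsaI) TU assembly into a cassette backbone.

    Grammar violations (missing role, duplicated fusion interval) are raised
    before the reaction is simulated; the simulated product must be unique.
    """
    tables = tables or load_overhang_tables()
    check_level1_grammar(parts, backbone_cassette, tables)
    pool = [p.record for p in parts] + [backbone_cassette.record]
    result = assemble_golden_gate(pool, enzymes["BsaI"])
    return result.require_unique()


def plan_level2(cassettes: list[KitEntry], vector: KitEntry,
                enzymes: dict[str, Enzyme],
                allow_spacers: bool = True) -> AssemblyProduct:
    """Plan a Level-2 (BsmBI) multigene assembly of 1-10 cassettes into an
    integration vector.

    The connector chain must close through the vector; the product contains
    every cassette payload in positional order and has lost the vector's
    mScarlet dropout.
    """
    n = len(cassettes)
    if not 1 <= n <= ConnectorScheme.MAX_TUS:
        raise UnsupportedCountError(
            f"{n} TUs unsupported (standard scheme covers 1..{ConnectorScheme.MAX_TUS})")
    if not allow_spacers:
        spacers = [c.id for c in cassettes if c.role.category == "spacer"]
        if spacers:
            raise GrammarError(f"spacer cassettes not allowed here: {spacers}")
    pool = [c.record for c in cassettes] + [vector.record]
    result = assemble_golden_gate(pool, enzymes["BsmBI"])
    product = result.require_unique()
    dropouts = [f for f in product.sequence.features if f.kind == "reporter_dropout"]
    vec_dropouts = [f for f in vector.record.features if f.kind == "reporter_dropout"]
    if vec_dropouts and len(dropouts) >= len(vec_dropouts):
        raise GrammarError("vector dropout survived the assembly")
    return product


def swap_marker(vector_or_crispr: KitEntry, marker: KitEntry,
                enzymes: dict[str, Enzyme]) -> AssemblyProduct:
    """Insert a selectable-marker cartridge into an integration vector (or
    the CRISPR backbone) by BbsI Golden Gate.  BbsI sites are consumed; every
    other feature of the target is preserved."""
    bbsi = enzymes["BbsI"]
    if not find_sites(marker.record, bbsi):
        raise IncompatibleMarkerError(f"{marker.id} carries no BbsI site")
    if not find_sites(vector_or_crispr.record, bbsi):
        raise IncompatibleMarkerError(
            f"{vector_or_crispr.id} carries no BbsI cloning site")
    payloads = [f for f in digest(marker.record, bbsi)
                if f.left_end.kind == "fusion" and not f.has_site(bbsi)]
    targets = [f for f in digest(vector_or_crispr.record, bbsi)
               if f.left_end.kind == "fusion" and not f.has_site(bbsi)]
    if not payloads or not targets or not any(
            p.left_end.seq == t.right_end.seq and p.right_end.seq == t.left_end.seq
            for p in payloads for t in targets):
        raise IncompatibleMarkerError(
            f"{marker.id} fusion sites do not match {vector_or_crispr.id}")
    result = assemble_golden_gate(
        [vector_or_crispr.record, marker.record], bbsi)
    return result.require_unique()


_REPORTER_COLORS = {"sfGFP": "green", "mScarlet": "red"}


def predict_screen_color(product: AssemblyProduct | SequenceRecord,
                         stage: str = "ecoli") -> str:
    """Colony color implied by the reporter-dropout features still present.

    Dropout reporters are features of kind ``reporter_dropout`` whose label
    names the fluorophore and whose optional ``stage`` qualifier restricts
    the host ('ecoli', 'yeast', or 'both', the default).  White means every
    dropout has been replaced -- the screen for a correct assembly.
    """
    if stage not in ("ecoli", "yeast"):
        raise ValueError(f"stage must be ecoli|yeast, got {stage!r}")
    record = product.sequence if isinstance(product, AssemblyProduct) else product
    colors = []
    for f in record.features:
        if f.kind != "reporter_dropout":
            continue
        quals = dict(f.qualifiers)
        f_stage = quals.get("stage", "both")
        if f_stage not in (stage, "both"):
            continue
        for name, color in _REPORTER_COLORS.items():
            if name.lower() in f.label.lower() and color not in colors:
                colors.append(color)
    return "+".join(sorted(colors)) if colors else "white"


# -- kit validation ----------------------------------------------------------


def _clean_payloads(record: SequenceRecord, enzyme: Enzyme):
    return [f for f in digest(record, enzyme)
            if f.left_end.kind == "fusion" and f.right_end.kind == "fusion"
            and not f.has_site(enzyme)]


def _check_payload(entry: KitEntry, enzyme: Enzyme,
                   expected: tuple[str, str]) -> list[str]:
    frags = _clean_payloads(entry.record, enzyme)
    pairs = {(f.left_end.seq, f.right_end.seq) for f in frags}
    if expected not in pairs:
        return [f"{entry.id}: {enzyme.name} payload fusion sites {sorted(pairs)} "
                f"!= declared {expected}"]
    return []


def _check_acceptor(entry: KitEntry, enzyme: Enzyme,
                    expected: tuple[str, str]) -> list[str]:
    # acceptor backbone fragment: right end starts the chain, left end closes it
    frags = _clean_payloads(entry.record, enzyme)
    pairs = {(f.right_end.seq, f.left_end.seq) for f in frags}
    if expected not in pairs:
        return [f"{entry.id}: {enzyme.name} acceptor fusion sites {sorted(pairs)} "
                f"!= declared {expected}"]
    return []


def validate_kit(registry: KitRegistry,
                 enzymes: dict[str, Enzyme]) -> list[str]:
    """Check that every entry's declared fusion sites equal those produced by
    digesting its sequence with the level-appropriate enzyme.  Returns a list
    of violations (empty = kit is grammatical)."""
    tables = registry.overhangs
    marker_pair = (tables["marker_swap"]["upstream"],
                   tables["marker_swap"]["downstream"])
    array_pair = (tables["array_fusion_sites"]["head"],
                  tables["array_fusion_sites"]["tail"])
    problems: list[str] = []
    for e in registry:
        role = e.role
        declared = (role.upstream_fusion, role.downstream_fusion)
        if role.category in PART_CATEGORIES:
            table_pair = tables["part_types"].get(role.category)
            if table_pair and declared != (table_pair["upstream"],
                                           table_pair["downstream"]):
                problems.append(
                    f"{e.id}: declared sites {declared} differ from the "
                    f"{role.category} standard")
            problems += _check_payload(e, enzymes["BsaI"], declared)
        elif role.category in ("cassette", "spacer"):
            if role.category == "cassette":
                # unassembled cassette backbone: BsaI acceptor for types 2-4
                problems += _check_acceptor(
                    e, enzymes["BsaI"],
                    (tables["part_types"]["type2"]["upstream"],
                     tables["part_types"]["type4"]["downstream"]))
            problems += _check_payload(e, enzymes["BsmBI"], declared)
        elif role.category in ("integration_vector", "spacer_vector"):
            if role.category == "integration_vector":
                problems += _check_acceptor(e, enzymes["BsmBI"], declared)
            problems += _check_acceptor(e, enzymes["BbsI"], marker_pair)
        elif role.category == "marker_cartridge":
            problems += _check_payload(e, enzymes["BbsI"], marker_pair)
        elif role.category == "crispr_backbone":
            problems += _check_acceptor(e, enzymes["BsaI"], array_pair)
            if e.metadata.get("marker"):
                problems += _check_acceptor(e, enzymes["BbsI"], marker_pair)
    return problems
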