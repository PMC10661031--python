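"""Kit grammar: Level-1/Level-2 planning, connector scheme, marker swap, and
screening-color prediction on the toy kit."""

import pytest

from multigate.grammar import (
    AmbiguityError,
    ConnectorScheme,
    GrammarError,
    IncompatibleMarkerError,
    KitEntry,
    KitRegistry,
    PartRole,
    UnsupportedCountError,
    plan_level1,
    plan_level2,
    predict_screen_color,
    swap_marker,
    validate_kit,
)
from multigate.seqcore import SequenceRecord, canonical_circular, digest, find_sites


def by_label(kit, label):
    return next(e for e in kit if e.metadata.get("label") == label)


def test_toy_kit_is_grammatical(toy_kit, enzymes):
    assert validate_kit(toy_kit, enzymes) == []


def test_connector_scheme_covers_2_to_10_with_18_configurations(tables):
    scheme = ConnectorScheme(tables["level2_connectors"])
    assert len(scheme.required_configurations(range(2, 11))) == 18
    assert scheme.chain(2) == [(1, False), (2, True)]
    with pytest.raises(UnsupportedCountError):
        scheme.chain(11)
    with pytest.raises(UnsupportedCountError):
        scheme.chain(0)


def test_plan_level1_into_prebuilt_cassette(toy_kit, enzymes):
    cassette = next(e for e in toy_kit.by_category("cassette")
                    if e.metadata["position"] == 1 and not e.metadata["terminal"])
    parts = [by_label(toy_kit, "pProm1"), by_label(toy_kit, "ToyCDS1"),
             by_label(toy_kit, "tTerm1")]
    product = plan_level1(parts, cassette, enzymes, toy_kit.overhangs)
    # the cassette's BsmBI digestion releases the TU with the declared
    # connector fusion sites
    payloads = [f for f in digest(product.sequence, enzymes["BsmBI"])
                if not f.has_site(enzymes["BsmBI"])]
    pairs = {(f.left_end.seq, f.right_end.seq) for f in payloads}
    assert (cassette.role.upstream_fusion, cassette.role.downstream_fusion) in pairs
    assert not find_sites(product.sequence, enzymes["BsaI"])


def test_plan_level1_subtype_split(toy_kit, enzymes):
    """3a+3b and 4a+4b partition their parents' fusion intervals."""
    cassette = next(e for e in toy_kit.by_category("cassette")
                    if e.metadata["position"] == 2 and not e.metadata["terminal"])
    parts = [by_label(toy_kit, "pProm2"), by_label(toy_kit, "ToyCDS3a_1"),
             by_label(toy_kit, "ToyCDS3b_1"), by_label(toy_kit, "tTerm4a"),
             by_label(toy_kit, "tTerm4b")]
    product = plan_level1(parts, cassette, enzymes, toy_kit.overhangs)
    assert len(product.parts_order) == 6  # 5 parts + backbone


def test_plan_level1_missing_role(toy_kit, enzymes):
    cassette = toy_kit.by_category("cassette")[0]
    parts = [by_label(toy_kit, "pProm1"), by_label(toy_kit, "ToyCDS1")]
    with pytest.raises(GrammarError, match="type4"):
        plan_level1(parts, cassette, enzymes, toy_kit.overhangs)


def test_plan_level1_duplicate_interval(toy_kit, enzymes):
    cassette = toy_kit.by_category("cassette")[0]
    parts = [by_label(toy_kit, "pProm1"), by_label(toy_kit, "pProm2"),
             by_label(toy_kit, "ToyCDS1"), by_label(toy_kit, "tTerm1")]
    with pytest.raises(AmbiguityError, match="pTOY00"):
        plan_level1(parts, cassette, enzymes, toy_kit.overhangs)


def single_tu_cassette(kit, enzymes):
    parts = [by_label(kit, "ConL1"), by_label(kit, "pProm1"),
             by_label(kit, "ToyCDS1"), by_label(kit, "tTerm1"),
             by_label(kit, "ConRE-T"), by_label(kit, "YeastMarker1"),
             by_label(kit, "YeastOri1")]
    backbone = by_label(kit, "EcoliBackbone1")
    product = plan_level1(parts, backbone, enzymes, kit.overhangs)
    con = kit.overhangs["level2_connectors"]
    return KitEntry("singleTU", product.sequence,
                    PartRole("cassette", con["con1"], con["terminal"]))


@pytest.mark.parametrize("n", range(1, 11))
def test_plan_level2_all_sizes(toy_kit, enzymes, spacer_chain, n):
    """Every TU count from 1 to 10 closes into a unique product; N=1 uses a
    Level-1-built cassette with position-1 terminal connectors."""
    vector = toy_kit.by_category("integration_vector")[0]
    cassettes = ([single_tu_cassette(toy_kit, enzymes)] if n == 1
                 else spacer_chain(n))
    product = plan_level2(cassettes, vector, enzymes)
    assert predict_screen_color(product, "ecoli") == "white"
    payloads = [f for f in product.sequence.features if f.kind == "spacer_payload"]
    if n > 1:
        assert len(payloads) == n
        # positional order preserved left to right
        order = [int(f.label.split("-")[1].rstrip("IT")) for f in
                 sorted(payloads, key=lambda f: f.start)]
        assert order == sorted(order)


def test_plan_level2_rejects_unsupported_count(toy_kit, enzymes, spacer_chain):
    vector = toy_kit.by_category("integration_vector")[0]
    eleven = spacer_chain(9) + spacer_chain(2)
    with pytest.raises(UnsupportedCountError):
        plan_level2(eleven, vector, enzymes)


def test_plan_level2_wrong_terminal_connector(toy_kit, enzymes, spacer_chain):
    """An internal cassette in the final position cannot close the chain."""
    vector = toy_kit.by_category("integration_vector")[0]
    chain = spacer_chain(3)[:2]  # positions 1,2 internal; no terminal
    chain.append(next(e for e in toy_kit.by_category("spacer")
                      if e.metadata["position"] == 3 and not e.metadata["terminal"]))
    with pytest.raises(ValueError, match="not unique"):
        plan_level2(chain, vector, enzymes)


def test_swap_marker_payload_local(toy_kit, enzymes):
    vector = toy_kit.by_category("integration_vector")[0]
    marker = next(e for e in toy_kit.by_category("marker_cartridge")
                  if e.metadata["marker"] == "URA3")
    product = swap_marker(vector, marker, enzymes)
    assert not find_sites(product.sequence, enzymes["BbsI"])
    # payload-local: the vector's backbone fragment survives byte-identical
    backbone = next(f for f in digest(vector.record, enzymes["BbsI"])
                    if not f.has_site(enzymes["BbsI"]))
    assert backbone.bases in product.sequence.bases * 2
    assert any(f.label == "URA3" for f in product.sequence.features)
    # homology arms and dropout untouched
    for kind in ("homology_arm", "reporter_dropout"):
        assert (len([f for f in product.sequence.features if f.kind == kind])
                == len([f for f in vector.record.features if f.kind == kind]))


def test_swap_marker_full_cross_is_distinct(toy_kit, enzymes):
    vectors = toy_kit.by_category("integration_vector")[:3]
    markers = toy_kit.by_category("marker_cartridge")[:3]
    products = {canonical_circular(swap_marker(v, m, enzymes).sequence.bases)
                for v in vectors for m in markers}
    assert len(products) == 9


def test_swap_marker_into_crispr_backbone(toy_kit, enzymes):
    crispr = next(e for e in toy_kit.by_category("crispr_backbone")
                  if e.metadata["marker"] == "URA3")
    leu2 = next(e for e in toy_kit.by_category("marker_cartridge")
                if e.metadata["marker"] == "LEU2")
    product = swap_marker(crispr, leu2, enzymes)
    labels = [f.label for f in product.sequence.features]
    assert "LEU2" in labels and "URA3" not in labels


def test_swap_marker_incompatible(toy_kit, enzymes):
    vector = toy_kit.by_category("integration_vector")[0]
    no_site = KitEntry("bare", SequenceRecord("bare", "ATGCATGCATGC", "circular"),
                       PartRole("marker_cartridge", "TAGC", "ATGG"))
    with pytest.raises(IncompatibleMarkerError):
        swap_marker(vector, no_site, enzymes)


def test_screen_colors(toy_kit):
    vector = toy_kit.by_category("integration_vector")[0]
    assert predict_screen_color(vector.record, "ecoli") == "red"
    assert predict_screen_color(vector.record, "yeast") == "red"
    crispr = toy_kit.by_category("crispr_backbone")[0]
    assert predict_screen_color(crispr.record, "ecoli") == "green+red"
    cassette = toy_kit.by_category("cassette")[0]
    assert predict_screen_color(cassette.record, "ecoli") == "green"
    with pytest.raises(ValueError):
        predict_screen_color(vector.record, "plate")


def test_registry_save_load_roundtrip(toy_kit, tmp_path):
    toy_kit.save(tmp_path / "kit")
    loaded = KitRegistry.load(tmp_path / "kit")
    assert len(loaded) == len(toy_kit)
    for entry in toy_kit:
        other = loaded[entry.id]
        assert other.record.bases == entry.record.bases
        assert other.record.topology == entry.record.topology
        assert other.role == entry.role
        assert {(f.label, f.kind, f.start, f.end) for f in other.record.features} \
            == {(f.label, f.kind, f.start, f.end) for f in entry.record.features}
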