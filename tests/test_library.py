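"""Saturation libraries, substitution classes, stand-in effect scorer."""

import math

import pytest

import qtycode as q
from qtycode.library import (
    COGNATES,
    NONPOLAR_SET,
    POLAR_SET,
    SubstitutionClass,
    classify_substitution,
    library_size,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def test_site_library_has_19_alternatives():
    rec = q.ProteinRecord(id="p", sequence="MLK")
    lib = q.build_site_library(rec, 2)
    assert lib.wild_aa == "L"
    assert len(lib.alternatives) == 19
    assert "L" not in lib.alternatives
    assert "Q" in lib.alternatives
    with pytest.raises(IndexError):
        q.build_site_library(rec, 4)


def test_two_sites_are_independent():
    rec = q.ProteinRecord(id="p", sequence="MLKF")
    libs = [q.build_site_library(rec, 2), q.build_site_library(rec, 4)]
    assert library_size(libs) == 38


def test_build_tm_library_counts_planted_leucines():
    # exactly 5 leucines inside the TM helix, none elsewhere targeted
    rec = q.ProteinRecord(id="p", sequence="GGGLALALALLGGGG")
    topo = q.Topology(protein_id="p", segments=[
        q.TopologySegment(kind=q.SegmentKind.TM_HELIX, start=4, end=11, label="TM1")])
    sites = q.build_tm_library(rec, topo, target_aas={"L"})
    assert len(sites) == 5
    assert library_size(sites) == 95
    assert all(s.wild_aa == "L" for s in sites)


def test_build_tm_library_empty_when_no_targets():
    rec = q.ProteinRecord(id="p", sequence="GGGSSSGGG")
    topo = q.Topology(protein_id="p", segments=[
        q.TopologySegment(kind=q.SegmentKind.TM_HELIX, start=2, end=8)])
    assert q.build_tm_library(rec, topo) == []


def test_tm_library_size_matches_site_count(synthetic_transporter):
    rec, topo = synthetic_transporter
    sites = q.build_tm_library(rec, topo)
    tm_positions = topo.positions_of_kind({q.SegmentKind.TM_HELIX})
    expected = sum(1 for p in tm_positions if rec.sequence[p - 1] in "LIVF")
    assert len(sites) == expected
    assert library_size(sites) == 19 * expected


def test_substitution_classes_partition_every_site():
    """Cognate + other-polar + other-nonpolar cover all 19 alternatives, no overlap."""
    assert POLAR_SET | NONPOLAR_SET == set(AAS)
    assert not POLAR_SET & NONPOLAR_SET
    for wild in AAS:
        seen = {}
        for alt in AAS:
            if alt == wild:
                continue
            seen.setdefault(classify_substitution(wild, alt), set()).add(alt)
        assert sum(len(v) for v in seen.values()) == 19
        for a, b in [(x, y) for x in seen.values() for y in seen.values() if x is not y]:
            assert not a & b


def test_other_polar_count_for_wild_leucine():
    # the nine polar alternatives to L besides its cognate Q
    others = [alt for alt in AAS if alt != "L"
              and classify_substitution("L", alt) == SubstitutionClass.OTHER_POLAR]
    assert sorted(others) == sorted("DERKHNSTY")
    assert len(others) == 9


def test_threonine_has_two_cognates():
    assert COGNATES["T"] == frozenset("IV")
    assert classify_substitution("T", "I") == SubstitutionClass.QTY_COGNATE
    assert classify_substitution("T", "V") == SubstitutionClass.QTY_COGNATE


def test_standin_scorer_formula():
    rec = q.ProteinRecord(id="p", sequence="MLK")
    site = q.build_site_library(rec, 2)  # wild L
    # zero hydropathy distance -> zero score (I has KD 4.5 vs L 3.8; use exact twin)
    scorer0 = q.standin_scorer(rec)
    rec2 = q.ProteinRecord(id="p2", sequence="MIK")
    site_i = q.build_site_library(rec2, 2)  # wild I, KD 4.5
    assert scorer0(site_i, "V") == pytest.approx((4.5 - 4.2) / 9.0 * 0.5 * (5 / 9))
    # buried, grade 9, L->D: (7.3/9) * 1.0 * 1.0 = 0.811
    scorer = q.standin_scorer(rec, conservation_grade_per_site={2: 9},
                              burial_per_site={2: True})
    assert scorer(site, "D") == pytest.approx(0.811, abs=0.001)
    # clamp: every score in [0, 1]
    for alt in site.alternatives:
        assert 0.0 <= scorer(site, alt) <= 1.0


def test_aggregate_uniform_scores():
    rec = q.ProteinRecord(id="p", sequence="MLKF")
    sites = [q.build_site_library(rec, 2), q.build_site_library(rec, 4)]
    scores = {(s.position, alt): 0.5 for s in sites for alt in s.alternatives}
    agg = q.aggregate_by_class(scores, {s.position: s.wild_aa for s in sites})
    for cls in (SubstitutionClass.QTY_COGNATE, SubstitutionClass.OTHER_POLAR,
                SubstitutionClass.OTHER_NONPOLAR, SubstitutionClass.ALL):
        mean, n = agg[cls]
        assert mean == pytest.approx(0.5)
    assert agg[SubstitutionClass.ALL][1] == 38


def test_aggregate_hand_built_two_site_table():
    """Means equal hand-computed fractions on a tiny explicit table."""
    wilds = {1: "L", 2: "I"}
    scores = {
        (1, "Q"): 0.2,              # cognate
        (1, "D"): 0.8, (1, "E"): 0.6,   # other polar
        (1, "A"): 0.1,              # other nonpolar
        (2, "T"): 0.4,              # cognate
        (2, "N"): 1.0,              # other polar
    }
    agg = q.aggregate_by_class(scores, wilds)
    assert agg[SubstitutionClass.QTY_COGNATE] == (pytest.approx(0.3), 2)
    assert agg[SubstitutionClass.OTHER_POLAR] == (pytest.approx(0.8), 3)
    assert agg[SubstitutionClass.OTHER_NONPOLAR] == (pytest.approx(0.1), 1)
    assert agg[SubstitutionClass.ALL] == (pytest.approx(3.1 / 6), 6)


def test_aggregate_excludes_unknown_sites_with_warning():
    scores = {(1, "Q"): 0.2, (99, "D"): 0.9}
    with pytest.warns(UserWarning):
        agg = q.aggregate_by_class(scores, {1: "L"})
    assert agg[SubstitutionClass.ALL][1] == 1


def test_class_means_are_convex_combinations(synthetic_transporter):
    rec, topo = synthetic_transporter
    sites = q.build_tm_library(rec, topo)
    scorer = q.standin_scorer(rec, topo)
    scores = q.score_library(sites, scorer)
    agg = q.aggregate_by_class(scores, {s.position: s.wild_aa for s in sites})
    lo, hi = min(scores.values()), max(scores.values())
    for mean, n in agg.values():
        if n:
            assert lo - 1e-12 <= mean <= hi + 1e-12
        else:
            assert math.isnan(mean)


def test_qty_cognates_score_below_other_polar_on_generated_proteins():
    """Library-level mean: the QTY targets are the mildest polar substitutions."""
    for seed in (11, 23, 47):
        rec, topo = q.generate_transporter(q.GeneratorConfig(seed=seed))
        sites = q.build_tm_library(rec, topo)
        scorer = q.standin_scorer(rec, topo)
        agg = q.aggregate_by_class(q.score_library(sites, scorer),
                                   {s.position: s.wild_aa for s in sites})
        assert agg[SubstitutionClass.QTY_COGNATE][0] <= agg[SubstitutionClass.OTHER_POLAR][0]
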