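"""Nutrient Profile Model scoring: worked examples, band edges, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaudit.model import NutrientValues
from adaudit.npm import (
    THRESHOLDS,
    IngredientEntry,
    a_points,
    c_points,
    derive_fvn_percent,
    npm_score,
    per_portion_to_per_100,
    score_products_frame,
)


def profile(**kw) -> NutrientValues:
    base = dict(
        energy_kj_per_100=0, satfat_g_per_100=0, total_sugars_g_per_100=0,
        sodium_mg_per_100=0, fibre_g_per_100=0, protein_g_per_100=0,
    )
    base.update(kw)
    return NutrientValues(**base)


class TestAPoints:
    def test_all_zero_profile_scores_zero(self):
        comps, total = a_points(profile())
        assert total == 0 and all(v == 0 for v in comps.values())

    def test_handworked_example(self):
        # energy 1046 kJ (>1005), satfat 2.0 g (>1, not >2), sugars 26 g
        # (>22.5, not >27), sodium 100 mg (>90)
        comps, total = a_points(
            profile(energy_kj_per_100=1046, satfat_g_per_100=2.0,
                    total_sugars_g_per_100=26, sodium_mg_per_100=100)
        )
        assert comps == {"energy": 3, "satfat": 1, "sugars": 5, "sodium": 1}
        assert total == 10

    def test_components_cap_at_ten(self):
        comps, _ = a_points(profile(energy_kj_per_100=10_000))
        assert comps["energy"] == 10

    def test_negative_nutrient_rejected(self):
        with pytest.raises(Exception):
            profile(energy_kj_per_100=-1)


class TestCPoints:
    def test_full_fvn_scores_five(self):
        comps, _ = c_points(profile(), fvn_percent=100)
        assert comps["fvn"] == 5

    def test_handworked_example(self):
        comps, total = c_points(
            profile(fibre_g_per_100=0.8, protein_g_per_100=3.0).model_copy(
                update={"fibre_basis": "NSP"}
            ),
            fvn_percent=50,
        )
        assert comps == {"fvn": 1, "fibre": 1, "protein": 1}
        assert total == 3

    def test_fvn_threshold_is_strict(self):
        comps, _ = c_points(profile(), fvn_percent=40)
        assert comps["fvn"] == 0

    def test_fibre_basis_changes_banding(self):
        # 0.8 g is over the first NSP edge (0.7) but under the AOAC one (0.9)
        nsp = profile(fibre_g_per_100=0.8).model_copy(update={"fibre_basis": "NSP"})
        aoac = profile(fibre_g_per_100=0.8)
        assert c_points(nsp)[0]["fibre"] == 1
        assert c_points(aoac)[0]["fibre"] == 0


class TestNpmScore:
    def test_all_zero_drink_is_not_hfss(self):
        res = npm_score(profile(), "drink")
        assert res.total_score == 0 and not res.is_hfss

    def test_composed_example_is_hfss_food(self):
        # A = 10 from the A-points example; fvn 0, fibre(NSP) 1, protein 1
        p = profile(
            energy_kj_per_100=1046, satfat_g_per_100=2.0, total_sugars_g_per_100=26,
            sodium_mg_per_100=100, fibre_g_per_100=0.8, protein_g_per_100=3.0,
        ).model_copy(update={"fibre_basis": "NSP"})
        res = npm_score(p, "food", fvn_percent=0)
        assert res.a_points == 10
        assert res.total_score == 10 - (0 + 1 + 1) == 8
        assert res.is_hfss and not res.protein_capped

    def test_protein_cap_waived_by_full_fvn(self):
        # A = 12, FVN component 5, fibre 2, protein 4 -> no cap, total 1
        p = profile(
            energy_kj_per_100=1100,  # 3 pts
            satfat_g_per_100=4.5,  # 4 pts
            total_sugars_g_per_100=20,  # 4 pts
            sodium_mg_per_100=50,  # 1 pt... adjusted below
            fibre_g_per_100=2.0,  # AOAC: >1.8 -> 2
            protein_g_per_100=7.0,  # >6.4 -> 4
        )
        comps, a = a_points(p)
        assert a == 11  # 3+4+4+0
        p = p.model_copy(update={"sodium_mg_per_100": 95.0})  # +1 -> A=12
        res = npm_score(p, "food", fvn_percent=85)
        assert res.a_points == 12
        assert not res.protein_capped
        assert res.total_score == 12 - (5 + 2 + 4) == 1

    def test_protein_cap_applies_when_fvn_low(self):
        p = profile(
            energy_kj_per_100=2400, total_sugars_g_per_100=30,
            fibre_g_per_100=5.0, protein_g_per_100=10.0,
        )
        res = npm_score(p, "food", fvn_percent=0)
        assert res.a_points >= 11 and res.protein_capped
        assert res.total_score == res.a_points - res.c_components["fibre"]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="product_class"):
            npm_score(profile(), "snack")


def test_every_band_edge_scores_in_lower_band():
    """A nutrient value equal to a threshold scores strictly below it."""
    for nutrient, edges in THRESHOLDS["a_points"].items():
        for i, edge in enumerate(edges):
            at = a_points(profile(**{nutrient: float(edge)}))[0]
            above = a_points(profile(**{nutrient: edge + 1e-9}))[0]
            key = {"energy_kj_per_100": "energy", "satfat_g_per_100": "satfat",
                   "total_sugars_g_per_100": "sugars", "sodium_mg_per_100": "sodium"}[nutrient]
            assert at[key] == i
            assert above[key] == i + 1
    for edge, pts in zip([40, 60, 80], [1, 2, 5]):
        assert c_points(profile(), fvn_percent=edge)[0]["fvn"] < pts
        assert c_points(profile(), fvn_percent=edge + 1e-9)[0]["fvn"] == pts


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    energy=st.floats(0, 4000), satfat=st.floats(0, 15), sugars=st.floats(0, 60),
    sodium=st.floats(0, 1200), fibre=st.floats(0, 6), prot=st.floats(0, 12),
    fvn=st.floats(0, 100), bump=st.floats(1e-6, 500),
)
def test_total_score_monotone_in_nutrients(energy, satfat, sugars, sodium, fibre, prot, fvn, bump):
    p = profile(
        energy_kj_per_100=energy, satfat_g_per_100=satfat, total_sugars_g_per_100=sugars,
        sodium_mg_per_100=sodium, fibre_g_per_100=fibre, protein_g_per_100=prot,
    )
    base = npm_score(p, "food", fvn).total_score
    worse = p.model_copy(update={"total_sugars_g_per_100": sugars + bump})
    assert npm_score(worse, "food", fvn).total_score >= base
    better_fvn = min(100.0, fvn + bump)
    assert npm_score(p, "food", better_fvn).total_score <= base


class TestFvnDerivation:
    def test_declared_percent_sum(self):
        d = derive_fvn_percent(
            [IngredientEntry("tomato", 60, True), IngredientEntry("water", 30, False)]
        )
        assert (d.fvn_percent, d.provenance) == (60, "ingredients_sum")

    def test_no_source_assumes_zero(self):
        d = derive_fvn_percent(None, None)
        assert (d.fvn_percent, d.provenance) == (0.0, "assumed_zero")

    def test_overlapping_percentages_clamp_to_100(self):
        d = derive_fvn_percent(
            [IngredientEntry("apple", 70, True), IngredientEntry("grape", 40, True)]
        )
        assert (d.fvn_percent, d.provenance) == (100.0, "ingredients_sum")

    def test_reference_match(self):
        d = derive_fvn_percent(None, {"baked beans": 50.0}, "baked beans")
        assert (d.fvn_percent, d.provenance) == (50.0, "reference_match")

    def test_percent_above_100_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            derive_fvn_percent([IngredientEntry("tomato", 120, True)])


class TestPerPortion:
    def test_scaling(self):
        p = per_portion_to_per_100({"total_sugars_g": 10.0}, 50.0)
        assert p.total_sugars_g_per_100 == pytest.approx(20.0)
        p = per_portion_to_per_100({"energy_kj": 500.0}, 250.0)
        assert p.energy_kj_per_100 == pytest.approx(200.0)

    def test_no_weight_source_is_not_assessable(self):
        assert per_portion_to_per_100({"energy_kj": 500.0}, None, "none") is None

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            per_portion_to_per_100({"energy_kj": 1.0}, 0.0, "measured")


def test_batch_scoring_skips_out_of_scope_and_missing(study_counts_dataset):
    frame = score_products_frame(study_counts_dataset.products.values())
    # fixture products carry no nutrition, so nothing is assessable
    assert not frame["assessable"].any()
    assert len(frame) == len(study_counts_dataset.products)
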