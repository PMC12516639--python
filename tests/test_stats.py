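"""Kappa and chi-square against independent oracles; exposure tables."""

import numpy as np
import pandas as pd
import pytest

from adaudit.stats import (
    chisq_goodness_of_fit,
    chisq_independence,
    cohens_kappa,
    confusion_table,
    exposure_tables,
    round_share,
    run_exposure_tests,
)

from conftest import simple_dataset


# -- independent oracles (explicit double loops, no shared code path) -------


def kappa_oracle(table: np.ndarray) -> tuple[float, float, float]:
    k = table.shape[0]
    total = 0.0
    for i in range(k):
        for j in range(k):
            total += table[i, j]
    p_o = sum(table[i, i] for i in range(k)) / total
    p_e = 0.0
    for c in range(k):
        row_c = sum(table[c, j] for j in range(k))
        col_c = sum(table[i, c] for i in range(k))
        p_e += (row_c / total) * (col_c / total)
    return (p_o - p_e) / (1 - p_e), p_o, p_e


def chisq_oracle(obs: np.ndarray) -> tuple[float, int]:
    r, c = obs.shape
    total = obs.sum()
    stat = 0.0
    for i in range(r):
        for j in range(c):
            e = obs[i, :].sum() * obs[:, j].sum() / total
            stat += (obs[i, j] - e) ** 2 / e
    return stat, (r - 1) * (c - 1)


class TestKappa:
    def test_diagonal_table_gives_kappa_one(self):
        for diag in ([5, 3], [10, 1, 7], [2, 2, 2, 2]):
            res = cohens_kappa(np.diag(diag))
            assert res.kappa == pytest.approx(1.0)
            assert res.observed_agreement == pytest.approx(1.0)

    def test_handworked_2x2(self):
        res = cohens_kappa(np.array([[20, 5], [10, 15]]))
        assert res.observed_agreement == pytest.approx(0.70)
        assert res.expected_agreement == pytest.approx(0.50)
        assert res.kappa == pytest.approx(0.40)

    def test_chance_level_table_gives_zero(self):
        # identical rows proportional to the column margins
        res = cohens_kappa(np.array([[30, 10], [30, 10]]))
        assert res.kappa == pytest.approx(0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cohens_kappa(np.zeros((2, 2)))

    def test_degenerate_marginals_flagged_undefined(self):
        res = cohens_kappa(np.array([[7, 0], [0, 0]]))
        assert res.undefined and res.kappa is None

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = rng.integers(2, 6)
            tab = rng.integers(0, 30, size=(k, k)).astype(float)
            tab[rng.integers(k), rng.integers(k)] += 1  # never all-zero
            res = cohens_kappa(tab)
            if res.undefined:
                continue
            exp_k, exp_po, exp_pe = kappa_oracle(tab)
            assert abs(res.kappa - exp_k) < 1e-10
            assert abs(res.observed_agreement - exp_po) < 1e-10
            assert abs(res.expected_agreement - exp_pe) < 1e-10

    def test_matches_sklearn_on_label_pairs(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        r1 = rng.choice(list("abcd"), size=500)
        r2 = np.where(rng.random(500) < 0.7, r1, rng.choice(list("abcd"), size=500))
        res = cohens_kappa(confusion_table(r1, r2))
        assert res.kappa == pytest.approx(
            sklearn_metrics.cohen_kappa_score(r1, r2), abs=1e-12
        )


class TestChiSquare:
    def test_identical_rows_give_zero_statistic(self):
        res = chisq_independence(np.array([[4, 4, 4, 4, 4], [4, 4, 4, 4, 4]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_handworked_2x2_closed_form(self):
        # n(ad-bc)^2 / (r1 r2 c1 c2) = 60*(100-400)^2 / 30^4
        res = chisq_independence(np.array([[10, 20], [20, 10]]))
        assert res.statistic == pytest.approx(60 * (10 * 10 - 20 * 20) ** 2 / 30**4)
        assert res.statistic == pytest.approx(6.667, abs=5e-4)
        assert res.df == 1

    def test_cochran_rule_flags_sparse_tables(self):
        # four of ten expected cells are 1.0 (< 5): 60 % >= 5 fails the rule
        sparse = chisq_independence(np.array([[1, 1, 8, 8, 8], [1, 1, 8, 8, 8]]))
        assert not sparse.valid
        assert sparse.significant_at_95 is None
        dense = chisq_independence(np.array([[10, 12, 8], [9, 8, 13]]))
        assert dense.valid

    def test_zero_margin_rejected_with_name(self):
        with pytest.raises(ValueError, match="column 1"):
            chisq_independence(np.array([[5, 0], [5, 0]]))
        with pytest.raises(ValueError, match="row 0"):
            chisq_independence(np.array([[0, 0], [5, 5]]))

    def test_matches_bruteforce_and_scipy_on_random_tables(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(11)
        for _ in range(1000):
            r, c = rng.integers(2, 5, size=2)
            tab = rng.integers(1, 40, size=(r, c)).astype(float)
            res = chisq_independence(tab)
            stat, df = chisq_oracle(tab)
            assert abs(res.statistic - stat) < 1e-10
            assert res.df == df
            sp = chi2_contingency(tab, correction=False)
            assert res.statistic == pytest.approx(sp.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(sp.pvalue, abs=1e-12)
            np.testing.assert_allclose(res.expected, sp.expected_freq, atol=1e-9)

    def test_expected_matrix_preserves_total(self):
        tab = np.array([[3.0, 9, 2], [7, 1, 8]])
        res = chisq_independence(tab)
        assert res.expected.sum() == pytest.approx(tab.sum())

    def test_goodness_of_fit_uniform(self):
        res = chisq_goodness_of_fit([10, 10, 10, 10, 10])
        assert res.statistic == pytest.approx(0.0) and res.df == 4
        res = chisq_goodness_of_fit([20, 10], expected=[1, 1])
        assert res.statistic == pytest.approx((20 - 15) ** 2 / 15 + (10 - 15) ** 2 / 15)


def test_round_share_half_away_from_zero():
    assert round_share(365, 437) == 84  # 83.52...
    assert round_share(67, 437) == 15
    assert round_share(45, 200) == 23  # 22.5 rounds up, not to even
    assert round_share(0, 0) == 0


class TestExposureTables:
    def test_empty_dataset_gives_all_zero_tables(self):
        ds = simple_dataset([])
        tables = exposure_tables(ds)
        for name, tbl in tables.items():
            assert (tbl.to_numpy() == 0).all(), name

    def test_small_constructed_counts(self):
        ds = simple_dataset(
            [
                ("D1", 1, False, ["food", "food", "non_alcoholic_beverage"]),
                ("D2", 1, False, ["alcoholic_beverage"]),
                ("D3", 2, True, []),
                ("D4", 5, False, ["other"]),
            ]
        )
        tables = exposure_tables(ds)
        ptype = tables["product_types_by_quintile"]
        assert ptype.loc[1, "food"] == 1  # two food items, one advert
        assert ptype.loc[1, "non_alcoholic_beverage"] == 1
        fd = tables["food_drink_by_quintile"]
        assert fd.loc[1].tolist() == [1, 1]  # alcohol advert counts as other
        assert fd.loc[2, "food_drink"] == 1  # brand-only is food/drink
        assert tables["assets_by_quintile"].loc[5, "n_assets"] == 1

    def test_marginal_consistency(self, study_counts_dataset):
        tables = exposure_tables(study_counts_dataset)
        assert tables["assets_by_quintile"]["n_assets"].sum() == 295
        assert tables["adverts_by_quintile"]["n_adverts"].sum() == 437
        assert tables["size_by_quintile"].to_numpy().sum() == 295
        assert tables["asset_type_by_quintile"].to_numpy().sum() == 295
        assert tables["food_drink_by_quintile"].to_numpy().sum() == 437
        # heat-map column totals equal the deduplicated product-type counts
        heat = tables["asset_type_by_product_type"]
        ptype = tables["product_types_by_quintile"]
        assert heat.sum(axis=0).tolist() == ptype.sum(axis=0).tolist()


def test_sparse_compliance_test_is_flagged_invalid():
    # eight food/drink adverts spread over five quintiles: expected counts
    # far below Cochran's rule
    specs = [(f"D{i}", (i % 5) + 1, False, ["food"]) for i in range(8)]
    specs += [(f"E{i}", (i % 5) + 1, False, ["other"]) for i in range(40)]
    ds = simple_dataset(specs)
    verdicts = {f"D{i}": "would_be_non_compliant" if i % 2 else "compliant" for i in range(8)}
    res = run_exposure_tests(ds, verdicts)
    assert not res["non_compliant"].valid
    assert res["non_compliant"].significant_at_95 is None
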