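"""Composition cross-tab arithmetic and group-comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphtraj.composition import (
    anova_tukey,
    crosstab,
    division_index,
    kruskal_wallis,
    load_reference_crosstab,
    reference_crosstab_as_meta,
    subject_proportions,
)
from lymphtraj.synthdata import SimConfig, simulate_cohort


class TestCrosstab:
    def test_reference_grand_total(self):
        t = crosstab(reference_crosstab_as_meta())
        assert t.grand_total == 18851

    def test_reference_healthy_column_percents(self):
        """Every healthy-column percent matches the published 2-dp value."""
        expected = {
            "B naive": 2.04, "B intermediate": 1.44, "B memory": 1.14,
            "Plasmablast": 0.59, "CD4 T naive": 15.71,
            "CD4 T proliferating": 0.16, "CD4 TEM": 1.27, "CD4 TCM": 46.10,
            "CD4 CTL": 0.09, "Treg": 1.21, "CD8 T naive": 3.25,
            "CD8 T proliferating": 0.08, "CD8 TEM": 7.51, "CD8 TCM": 1.24,
            "dnT": 0.49, "gdT": 0.95, "MAIT": 0.52, "NK": 14.72,
            "NK Proliferating": 0.49, "NK CD56bright": 1.00,
        }
        t = crosstab(reference_crosstab_as_meta())
        for subtype, pct in expected.items():
            assert t.percents.loc[subtype, "HS"] == pct, subtype
        assert t.counts.loc["CD8 TEM", "HS"] == 926

    def test_reference_day4_column(self):
        t = crosstab(reference_crosstab_as_meta())
        assert t.counts.loc["CD4 TCM", "D4"] == 676
        assert t.column_totals["D4"] == 1044
        assert t.percents.loc["CD4 TCM", "D4"] == 64.75
        assert t.percents.loc["Plasmablast", "D4"] == 9.29

    def test_totals_telescope(self):
        t = crosstab(reference_crosstab_as_meta())
        assert (t.counts.sum(axis=0) == t.column_totals).all()
        assert t.grand_total == int(t.column_totals.sum())

    def test_single_type_is_hundred_percent(self):
        meta = pd.DataFrame({"consensus": ["NK"] * 30,
                             "cohort": ["HS"] * 10 + ["CCI"] * 20})
        t = crosstab(meta)
        assert (t.percents.loc["NK"] == 100.00).all()

    def test_empty_cohort_errors(self):
        meta = pd.DataFrame({"consensus": ["NK", "NK"], "cohort": ["HS", "HS"]})
        meta["cohort"] = pd.Categorical(meta["cohort"], categories=["HS", "CCI"])
        with pytest.raises(ValueError, match="empty cohort"):
            crosstab(meta)

    def test_row_order_matches_reference_layout(self):
        t = crosstab(reference_crosstab_as_meta())
        ref = load_reference_crosstab()
        assert list(t.counts.index) == list(ref["subtype"])
        assert list(t.counts.columns) == ["HS", "D4", "RAP", "CCI"]


class TestSubjectProportions:
    def test_simple_fraction(self):
        meta = pd.DataFrame({
            "donor": ["s1"] * 10, "cohort": ["HS"] * 10,
            "consensus": ["NK"] * 4 + ["B naive"] * 6,
        })
        fr = subject_proportions(meta)
        assert np.isclose(fr.loc["s1", "NK"], 0.4)

    def test_rows_sum_to_one(self, rng):
        meta = pd.DataFrame({
            "donor": rng.choice(["a", "b", "c"], size=200),
            "cohort": "HS",
            "consensus": rng.choice(["NK", "B naive", "CD4 TCM"], size=200),
        })
        fr = subject_proportions(meta)
        sums = fr.drop(columns="cohort").sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_recovers_planted_composition(self):
        cfg = SimConfig(seed=37, cohorts=("HS",), donors_per_cohort=8,
                        cells_per_donor=400, n_empty_droplets=0, doublet_rate=0.0)
        m, meta, _ = simulate_cohort(cfg)
        meta = meta.rename(columns={"cell_type": "consensus"})
        fr = subject_proportions(meta)
        probs = cfg.celltype_props["HS"]
        for t, p in probs.items():
            est = fr[t].mean()
            se = fr[t].std(ddof=1) / np.sqrt(len(fr))
            assert abs(est - p) <= 3 * max(se, 1e-6), t


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        res = anova_tukey([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res["F"] == 0.0 and res["p"] == 1.0

    def test_matches_statsmodels_reference(self):
        # fixed textbook-style 3-group fixture
        vals = np.array([4.2, 5.1, 4.8, 6.0, 6.3, 5.8, 7.1, 7.4, 6.9, 5.0, 5.5, 6.1])
        grp = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        res = anova_tukey(vals, grp)
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        df = pd.DataFrame({"y": vals, "g": grp})
        fit = ols("y ~ C(g)", data=df).fit()
        tab = sm.stats.anova_lm(fit)
        assert np.isclose(res["F"], tab["F"].iloc[0], atol=1e-6)
        assert np.isclose(res["p"], tab["PR(>F)"].iloc[0], atol=1e-6)
        hsd = pairwise_tukeyhsd(vals, grp)
        import itertools

        sm_pairs = list(itertools.combinations(hsd.groupsunique, 2))
        sm_p = dict(zip(sm_pairs, hsd.pvalues))
        for pair, p_adj in res["tukey"].items():
            key = pair if pair in sm_p else (pair[1], pair[0])
            assert np.isclose(p_adj, sm_p[key], atol=1e-6)

    def test_tukey_at_least_unadjusted(self, rng):
        from scipy import stats as ss

        vals = rng.normal(size=18)
        grp = np.repeat(["a", "b", "c"], 6)
        res = anova_tukey(vals, grp)
        for (a, b), p_adj in res["tukey"].items():
            raw = ss.ttest_ind(vals[grp == a], vals[grp == b]).pvalue
            assert p_adj >= raw - 1e-9

    def test_zero_residual_variance_flagged(self):
        res = anova_tukey([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert res["flag"] == "zero residual variance"
        assert np.isnan(res["p"])


class TestKruskalWallis:
    def test_closed_form_toy(self):
        """H for {1,2} vs {3,4}: brute-force rank formula gives 2.4."""
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        grp = np.array(["a", "a", "b", "b"])
        # independent brute-force computation from the rank definition
        ranks = np.argsort(np.argsort(vals)) + 1.0
        N = len(vals)
        H_brute = 12.0 / (N * (N + 1)) * sum(
            len(ranks[grp == g]) * (ranks[grp == g].mean() - (N + 1) / 2) ** 2
            for g in ("a", "b")
        )
        res = kruskal_wallis(vals, grp)
        assert np.isclose(H_brute, 2.4)
        assert np.isclose(res["H"], H_brute, atol=1e-12)

    def test_label_swap_symmetric(self):
        v = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        g1 = ["x", "x", "x", "y", "y", "y"]
        g2 = ["y", "y", "y", "x", "x", "x"]
        assert np.isclose(kruskal_wallis(v, g1)["H"], kruskal_wallis(v, g2)["H"])

    def test_ties_match_reference(self, rng):
        from scipy import stats as ss

        vals = rng.integers(0, 5, size=30).astype(float)  # many ties
        grp = rng.choice(["a", "b", "c"], size=30)
        res = kruskal_wallis(vals, grp)
        H_ref, p_ref = ss.kruskal(*(vals[grp == g] for g in ("a", "b", "c")))
        assert np.isclose(res["H"], H_ref, atol=1e-9)
        assert np.isclose(res["p"], p_ref, atol=1e-9)

    def test_all_identical_flagged(self):
        res = kruskal_wallis([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert res["flag"] == "all values identical"


class TestDivisionIndex:
    def test_zero_divisions(self):
        assert division_index(0, 100) == 0.0

    def test_direct_formula(self):
        assert division_index(50, 100) == 0.5

    @given(st.integers(1, 1000), st.integers(0, 5000), st.integers(1, 50))
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, start, divs, c):
        assert np.isclose(
            division_index(divs, start), division_index(c * divs, c * start)
        )

    def test_zero_start_errors(self):
        with pytest.raises(ValueError):
            division_index(10, 0)
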