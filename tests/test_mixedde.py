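"""Random-intercept REML model: estimation, inference, DE workflow."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphtraj.mixedde import (
    CELLTYPE_FDR_THRESHOLDS,
    _neg2_reml,
    _suffstats,
    bh_adjust,
    de_celltype,
    fit_lmm,
    lineage_fdr_threshold,
    pooled_ttest,
)


def _sim_gene(rng, n_donors=6, cells=40, tau=0.5, sigma=1.0, beta1=0.0):
    donors = np.repeat(np.arange(n_donors), cells)
    cond = (donors >= n_donors // 2).astype(float)
    y = 1.0 + beta1 * cond + rng.normal(0, tau, n_donors)[donors]
    y = y + rng.normal(0, sigma, n_donors * cells)
    return y, cond, donors


def _statsmodels_reml_oracle(y, cond, donors):
    """Independent REML fit: statsmodels' profiled likelihood maximized by
    tight 1-D bounded optimization over log(variance ratio)."""
    import statsmodels.api as sm
    from scipy import optimize
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    X = np.column_stack([np.ones_like(y), cond])
    md = sm.MixedLM(y, X, groups=donors)
    md.cov_pen = None
    md.reml = True

    def nll(loglam):
        pars = MixedLMParams.from_components(
            fe_params=None, cov_re=np.array([[np.exp(loglam)]])
        )
        return -md.loglike(pars, profile_fe=True)

    res = optimize.minimize_scalar(
        nll, bounds=(-18, 18), method="bounded", options={"xatol": 1e-10}
    )
    lam = np.exp(res.x)
    cov_re = np.array([[lam]])
    fe = md.get_fe_params(cov_re, np.empty(0))[0]
    scale = md.get_scale(fe, cov_re, np.empty(0))
    return fe[0], fe[1], lam * scale, scale


class TestFitLMM:
    def test_ols_limit_when_no_donor_variance(self, rng):
        y, cond, donors = _sim_gene(rng, tau=0.0, cells=80)
        fit = fit_lmm(y, cond, donors)
        ols_b1 = y[cond == 1].mean() - y[cond == 0].mean()
        assert abs(fit.beta1 - ols_b1) < 1e-6
        assert fit.tau2 < 0.05

    def test_matches_reml_oracle_on_simulated_genes(self, rng):
        """beta, tau^2, sigma^2 within 1e-4 of an independent REML fit."""
        worst = 0.0
        for _ in range(50):
            y, cond, donors = _sim_gene(rng)
            fit = fit_lmm(y, cond, donors)
            b0, b1, tau2, sigma2 = _statsmodels_reml_oracle(y, cond, donors)
            worst = max(
                worst,
                abs(fit.beta0 - b0), abs(fit.beta1 - b1),
                abs(fit.tau2 - tau2), abs(fit.sigma2 - sigma2),
            )
        assert worst < 1e-4

    def test_translation_equivariance(self, rng):
        y, cond, donors = _sim_gene(rng)
        f1 = fit_lmm(y, cond, donors)
        f2 = fit_lmm(y + 3.7, cond, donors)
        assert abs(f2.beta0 - f1.beta0 - 3.7) < 1e-10
        assert abs(f2.beta1 - f1.beta1) < 1e-10

    def test_reml_local_optimality_probe(self, rng):
        y, cond, donors = _sim_gene(rng, n_donors=10, tau=0.8)
        fit = fit_lmm(y, cond, donors)
        if fit.lam <= 1e-7:  # boundary optimum, probe one-sided
            pytest.skip("boundary solution")
        donors_u, codes = np.unique(donors, return_inverse=True)
        args = (y, cond) + _suffstats(y, cond, codes, len(donors_u)) + (float(len(y)),)
        f_opt = _neg2_reml(np.log(fit.lam), *args)
        assert f_opt <= _neg2_reml(np.log(fit.lam / 2), *args) + 1e-7
        assert f_opt <= _neg2_reml(np.log(fit.lam * 2), *args) + 1e-7

    def test_degenerate_constant_response(self):
        donors = np.repeat([0, 1, 2, 3], 10)
        cond = (donors >= 2).astype(float)
        fit = fit_lmm(np.ones(40), cond, donors)
        assert fit.degenerate and fit.p == 1.0

    def test_single_donor_errors(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_lmm(np.arange(10.0), np.zeros(10), np.zeros(10))

    def test_parameter_recovery_over_replicates(self, rng):
        """Mean beta1 error within 2 MC SEs; tau^2 median within 25%."""
        tau = 0.5
        b1_err, tau2_hat = [], []
        for _ in range(200):
            y, cond, donors = _sim_gene(rng, n_donors=8, tau=tau, beta1=1.0)
            fit = fit_lmm(y, cond, donors)
            b1_err.append(fit.beta1 - 1.0)
            tau2_hat.append(fit.tau2)
        se = np.std(b1_err, ddof=1) / np.sqrt(len(b1_err))
        assert abs(np.mean(b1_err)) <= 2 * se
        assert abs(np.median(tau2_hat) - tau**2) / tau**2 < 0.25


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == 0.37

    def test_hand_computed_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(bh_adjust(p), 0.05)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_permutation_invariance(self, p):
        p = np.asarray(p)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        direct = bh_adjust(p)
        via_perm = np.empty_like(direct)
        via_perm[perm] = bh_adjust(p[perm])
        assert np.allclose(direct, via_perm)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])


class TestDECelltype:
    def _make_stratum(self, rng, n_genes=40, beta_genes=(0, 1, 2), beta1=1.5):
        n_donors, cells = 8, 30
        donors = np.repeat([f"d{i}" for i in range(n_donors)], cells)
        cohort = np.where(
            np.repeat(np.arange(n_donors), cells) >= n_donors // 2, "CCI", "RAP"
        )
        X = rng.normal(2.0, 1.0, size=(n_donors * cells, n_genes)).clip(0)
        for g in beta_genes:
            X[cohort == "CCI", g] += beta1
        meta = pd.DataFrame({
            "consensus": "CD8 TEM", "cohort": cohort, "donor": donors,
        })
        genes = np.array([f"G{i}" for i in range(n_genes)], dtype=object)
        return X, genes, meta

    def test_planted_effects_found_with_correct_sign(self, rng):
        X, genes, meta = self._make_stratum(rng)
        tab = de_celltype(X, genes, meta, "CD8 TEM",
                          lineage_of={"CD8 TEM": "CD8 T"})
        top = tab.nsmallest(3, "p_adj")
        assert set(top["gene"]) == {"G0", "G1", "G2"}
        assert (top["direction"] == "up").all()
        assert top["significant"].all()

    def test_celltype_thresholds_follow_lineage(self):
        assert CELLTYPE_FDR_THRESHOLDS == {
            "B": 0.5, "CD8 T": 0.1, "CD4 T": 0.01, "NK": 0.01,
        }
        lineage = {"B memory": "B", "CD8 TEM": "CD8 T", "NK": "NK",
                   "CD4 TCM": "CD4 T"}
        assert lineage_fdr_threshold("B memory", lineage) == 0.5
        assert lineage_fdr_threshold("CD8 TEM", lineage) == 0.1
        assert lineage_fdr_threshold("CD4 TCM", lineage) == 0.01
        assert lineage_fdr_threshold("NK", lineage) == 0.01

    def test_significance_monotone_in_threshold(self, rng):
        X, genes, meta = self._make_stratum(rng, n_genes=60, beta1=0.8)
        counts = []
        for thr in (0.5, 0.1, 0.01):
            tab = de_celltype(X, genes, meta, "CD8 TEM", fdr_threshold=thr,
                              lineage_of={"CD8 TEM": "CD8 T"})
            counts.append(int(tab["significant"].sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_missing_condition_errors(self, rng):
        X, genes, meta = self._make_stratum(rng)
        meta.loc[meta.cohort == "CCI", "cohort"] = "RAP"
        with pytest.raises(ValueError, match="absent in cohort"):
            de_celltype(X, genes, meta, "CD8 TEM")

    def test_expression_filter_warns_when_everything_filtered(self, rng):
        X, genes, meta = self._make_stratum(rng)
        X[:] = 0.0
        with pytest.warns(UserWarning, match="expression filter"):
            tab = de_celltype(X, genes, meta, "CD8 TEM",
                              lineage_of={"CD8 TEM": "CD8 T"})
        assert len(tab) == 0


class TestPseudoreplication:
    def test_pooled_ttest_anticonservative_under_donor_variance(self, rng):
        """The donor-ignoring cell-level t-test wildly inflates type I error
        while the mixed model stays near nominal (small replicate check; the
        full calibration lives in the acceptance suite)."""
        rej_lmm = rej_pooled = 0
        n = 150
        for _ in range(n):
            y, cond, donors = _sim_gene(rng, n_donors=8, tau=0.5)
            rej_lmm += fit_lmm(y, cond, donors).p < 0.05
            rej_pooled += pooled_ttest(y, cond)[1] < 0.05
        assert rej_pooled / n > 0.10
        assert rej_lmm / n < 0.10
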