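"""Generator contracts: moments, determinism, layers, hierarchy."""

import numpy as np
import pandas as pd
import pytest

from lymphtraj.containers import read_10x_triplet, write_10x_triplet
from lymphtraj.synthdata import (
    MITO_GENES,
    SimConfig,
    build_reference_panels,
    simulate_cohort,
)


def _singlet_mask(meta):
    return (~meta.is_doublet & ~meta.is_empty).to_numpy()


class TestSimulateCohort:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=42, cells_per_donor=50, donors_per_cohort=2,
                        n_empty_droplets=100)
        m1, meta1, _ = simulate_cohort(cfg)
        m2, meta2, _ = simulate_cohort(SimConfig(seed=42, cells_per_donor=50,
                                                 donors_per_cohort=2,
                                                 n_empty_droplets=100))
        for layer in ("spliced", "unspliced", "ambiguous", "total"):
            assert (m1.layer(layer) != m2.layer(layer)).nnz == 0
        pd.testing.assert_frame_equal(meta1, meta2)

    def test_layers_sum_to_total_exactly(self):
        cfg = SimConfig(seed=3, cells_per_donor=40, donors_per_cohort=2,
                        n_empty_droplets=50)
        m, _, _ = simulate_cohort(cfg)
        s = m.layer("spliced") + m.layer("unspliced") + m.layer("ambiguous")
        assert (s != m.layer("total")).nnz == 0

    def test_degenerate_null_means_match_closed_form(self):
        # tau=0, no effects, huge theta -> Poisson around mu = L * p_g
        cfg = SimConfig(
            seed=5, cohorts=("HS",), donors_per_cohort=2, cells_per_donor=600,
            tau=0.0, theta=1e12, condition_effects={}, exhaustion_shift=0.0,
            doublet_rate=0.0, n_empty_droplets=0,
            libsize_lognormal=(np.log(2000.0), 0.0),
            mito_fraction_beta=(1e6, 1e6 * 32.33),  # essentially constant ~3%
        )
        m, meta, truth = simulate_cohort(cfg)
        t = "CD4 TCM"
        mask = (meta.cell_type == t).to_numpy()
        X = m.layer("total")[mask].toarray().astype(float)
        # closed-form mean: 2000 * normalized share of the type's program
        eta = truth.log_programs.loc[t].to_numpy()
        mito = np.isin(m.gene_ids, MITO_GENES)
        w = np.exp(eta)
        f = 1e6 / (1e6 + 1e6 * 32.33)
        p = np.where(mito, w / w[mito].sum() * f, w / w[~mito].sum() * (1 - f))
        mu = 2000.0 * p
        emp = X.mean(axis=0)
        se = np.sqrt(np.maximum(X.var(axis=0), 1e-12) / X.shape[0])
        big = mu > 1.0  # skip near-zero genes where SE estimate is unstable
        z = (emp[big] - mu[big]) / np.maximum(se[big], 1e-12)
        assert np.mean(np.abs(z) <= 3.0) > 0.98

    def test_nb_variance_matches_moment_oracle(self):
        # var = mu + mu^2/theta for NB; checked on >= 5000 homogeneous cells
        theta = 2.0
        cfg = SimConfig(
            seed=6, cohorts=("HS",), donors_per_cohort=1, cells_per_donor=5000,
            tau=0.0, theta=theta, doublet_rate=0.0, n_empty_droplets=0,
            celltype_props={"HS": {"NK": 1.0}},
            libsize_lognormal=(np.log(2000.0), 0.0),
            mito_fraction_beta=(1e6, 1e6 * 32.33),
        )
        m, meta, _ = simulate_cohort(cfg)
        X = m.layer("total").toarray().astype(float)
        mu = X.mean(axis=0)
        v_emp = X.var(axis=0, ddof=1)
        v_th = mu + mu**2 / theta
        big = mu > 5
        ratio = v_emp[big] / v_th[big]
        # per-gene variance ratios concentrate near 1
        assert abs(np.median(ratio) - 1.0) < 0.1
        assert np.mean(np.abs(ratio - 1.0) < 0.35) > 0.9

    def test_donor_variance_recovered_from_pseudobulk(self):
        # The intercept is shared across donor-variable genes, so with D
        # donors the estimable quantity is the realized variance of the D
        # planted intercepts, recovered from pseudobulk log-means (log of
        # per-donor mean counts; a small donor-variable fraction keeps the
        # library-renormalization leakage negligible).
        tau = 0.5
        cfg = SimConfig(
            seed=8, cohorts=("HS",), donors_per_cohort=10, cells_per_donor=250,
            tau=tau, doublet_rate=0.0, n_empty_droplets=0,
            donor_variable_frac=0.05,
            celltype_props={"HS": {"CD4 TCM": 1.0}},
            libsize_lognormal=(np.log(2500.0), 0.0),
        )
        m, meta, truth = simulate_cohort(cfg)
        u = np.array(list(truth.donor_intercepts.values()))
        realized = u.var(ddof=1)
        dv = np.isin(m.gene_ids, truth.donor_variable_genes)
        X = m.layer("total").toarray().astype(float)
        donors = meta.donor.to_numpy()
        pseudo = np.vstack([
            X[donors == d].mean(axis=0) for d in np.unique(donors)
        ])
        expressed = pseudo.min(axis=0) > 1.0
        cols = dv & expressed
        logmeans = np.log(pseudo[:, cols])
        est = (logmeans - logmeans.mean(axis=0)).var(axis=0, ddof=1)
        assert abs(np.median(est) - realized) / realized < 0.25
        # and the realized draw itself is consistent with tau^2
        assert 0.25 * tau**2 < realized < 4 * tau**2

    def test_doublet_library_size_twice_singlet_mean(self):
        cfg = SimConfig(seed=9, cells_per_donor=150, donors_per_cohort=2,
                        doublet_rate=0.2, n_empty_droplets=0)
        m, meta, _ = simulate_cohort(cfg)
        tot = m.total_counts()
        s = tot[_singlet_mask(meta)].mean()
        d = tot[meta.is_doublet.to_numpy()].mean()
        assert meta.is_doublet.sum() >= 100
        assert abs(d - 2 * s) / (2 * s) < 0.10

    def test_rejects_too_few_genes_and_cells(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimConfig(n_genes=100).validate()
        with pytest.raises(ValueError, match="cells_per_donor"):
            SimConfig(cells_per_donor=0).validate()

    def test_rejects_bad_proportions(self):
        props = {c: {"NK": 0.6, "B naive": 0.6} for c in ("HS", "D4", "RAP", "CCI")}
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(celltype_props=props).validate()

    def test_triplet_round_trip(self, tmp_path):
        cfg = SimConfig(seed=4, cells_per_donor=30, donors_per_cohort=1,
                        n_empty_droplets=20)
        m, _, _ = simulate_cohort(cfg)
        write_10x_triplet(m, tmp_path)
        back = read_10x_triplet(tmp_path)
        assert (back.layer("total") != m.layer("total")).nnz == 0
        assert list(back.gene_ids) == list(m.gene_ids)
        assert list(back.barcodes) == list(m.barcodes)
        assert back.layers_consistent()


class TestReferencePanels:
    def test_panel_count_and_distinct_draws(self):
        cfg = SimConfig(seed=13, n_empty_droplets=0)
        panels = build_reference_panels(cfg, n_panels=6, n_cells_per_label=40)
        assert len(panels) == 6
        # distinct seeds -> distinct profiles between panels
        assert not np.allclose(
            panels[0].profiles.to_numpy(), panels[1].profiles.to_numpy()
        )

    def test_coarse_panel_maps_to_lineages(self):
        cfg = SimConfig(seed=13, n_empty_droplets=0)
        panels = build_reference_panels(cfg, n_panels=6, n_cells_per_label=30)
        coarse = [p for p in panels if p.name.endswith("coarse")][0]
        assert set(coarse.labels) <= {"B", "CD4 T", "CD8 T", "NK", "other T"}
        assert all(coarse.harmonization[l] == l for l in coarse.labels)

    def test_profiles_cosine_similar_to_true_programs(self):
        cfg = SimConfig(seed=14, n_empty_droplets=0)
        panels = build_reference_panels(cfg, n_panels=3, n_cells_per_label=200)
        m, meta, truth = simulate_cohort(
            SimConfig(seed=14, cohorts=("HS",), donors_per_cohort=4,
                      cells_per_donor=400, n_empty_droplets=0, doublet_rate=0.0)
        )
        X = np.log1p(m.layer("total").toarray() / m.total_counts()[:, None] * 1e4)
        for t in cfg.cell_types:
            mask = (meta.cell_type == t).to_numpy()
            if mask.sum() < 200:
                continue
            true_prof = X[mask].mean(axis=0)
            pan = panels[0].profiles.loc[t].to_numpy()
            cos = pan @ true_prof / (np.linalg.norm(pan) * np.linalg.norm(true_prof))
            assert cos > 0.95, t

    def test_harmonization_must_be_total(self):
        from lymphtraj.synthdata import ReferencePanel

        with pytest.raises(ValueError, match="unmapped"):
            ReferencePanel(
                name="bad", labels=["A", "B"],
                profiles=pd.DataFrame(np.ones((2, 3)), index=["A", "B"]),
                harmonization={"A": "A"},
            )
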