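"""Hierarchical synthetic droplet scRNA-seq generator.

Emulates the statistical structure the downstream sepsis-lymphocyte analysis
assumes: cohort-structured donors (healthy HS, acute sepsis D4, rapid
recovery RAP, chronic critical illness CCI), per-cell-type negative-binomial
expression programs with donor random intercepts, cohort-specific
composition shifts, mitochondrial content, ambient/empty droplets, doublets,
and an exhaustion-panel expression shift in CCI cells of designated types.

The generative model for a singlet of donor d (cohort c) and cell type t is

    eta_g  = log(baseline_g) + m_{t,g} + beta_{t,g} I(c = CCI)
             + s_g * delta * I(c = CCI, t targeted) + u_d I(g donor-variable)
    p_g    = softmax-style share: exp(eta_g) normalized, with the cell's
             mitochondrial fraction f ~ Beta(a, b) fixing the mito share
    X_g    ~ NB(mean = L * p_g, size = theta),  L ~ LogNormal

with m the marker enrichment, beta the planted CCI-vs-RAP condition effect,
delta the signed exhaustion shift and u_d ~ N(0, tau^2) a donor intercept
shared across the donor-variable gene subset.  Counts split into spliced /
unspliced / ambiguous layers by fixed binomial thinning so the three layers
sum exactly to the total.  Empty droplets draw from the library-size-weighted
ambient profile; doublets are elementwise sums of two sampled singlets.

Default sizes are desk scale (hundreds of cells per donor); the study-scale
target of 5000 cells per donor is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import substream
from .containers import CountMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ReferencePanel",
    "simulate_cohort",
    "build_reference_panels",
    "LINEAGE_OF",
    "TABLE2_SUBTYPES",
    "default_config",
]

COHORTS = ("HS", "D4", "RAP", "CCI")

# Common 20-subtype vocabulary (cohort composition table rows), grouped by lineage.
TABLE2_SUBTYPES: dict[str, list[str]] = {
    "B": ["B naive", "B intermediate", "B memory", "Plasmablast"],
    "CD4 T": ["CD4 T naive", "CD4 T proliferating", "CD4 TEM", "CD4 TCM", "CD4 CTL", "Treg"],
    "CD8 T": ["CD8 T naive", "CD8 T proliferating", "CD8 TEM", "CD8 TCM"],
    "other T": ["dnT", "gdT", "MAIT"],
    "NK": ["NK", "NK Proliferating", "NK CD56bright"],
}
LINEAGE_OF: dict[str, str] = {
    sub: lin for lin, subs in TABLE2_SUBTYPES.items() for sub in subs
}

MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]

# Exhaustion-associated symbols carried as named genes so panel scoring works
# on synthetic data.  Signs follow the NK / CD8 TEM exhaustion panels.
EXHAUSTION_GENES = [
    "CD226", "KLRK1", "TIGIT", "TOX", "CD96", "LAG3", "LAMP1",
    "KLRG1", "TCF7", "TNFSF4", "CTLA4", "EOMES", "PDCD1", "HAVCR2", "FCGR3A",
]
EXHAUSTION_SIGNS = {
    "CD226": -1, "KLRK1": -1, "TCF7": -1,
    "TIGIT": +1, "TOX": +1, "CD96": +1, "LAG3": +1, "LAMP1": +1,
    "KLRG1": +1, "TNFSF4": +1, "CTLA4": +1, "EOMES": +1, "PDCD1": +1,
    "HAVCR2": +1,
    # FCGR3A/CD16 deliberately unshifted: a negative-control panel gene
    "FCGR3A": 0,
}

# Default desk-scale cell types (a subset of the 20-label vocabulary) and
# cohort compositions.  Proportions follow the published cohort composition
# pattern (CD4 TCM dominance in acute sepsis; CD8 TEM and NK expansion in
# CCI), renormalized over the simulated subtypes.
DEFAULT_CELLTYPES = ["B naive", "Plasmablast", "CD4 TCM", "CD8 TEM", "NK", "MAIT"]
_RAW_PROPS = {
    "HS": [251, 73, 5683, 926, 1815, 64],
    "D4": [8, 97, 676, 80, 47, 1],
    "RAP": [93, 198, 1290, 146, 381, 12],
    "CCI": [84, 179, 1042, 453, 595, 21],
}

SPLICE_SPLIT = (0.75, 0.20, 0.05)  # spliced, unspliced, ambiguous


def _normalized_props() -> dict[str, dict[str, float]]:
    out = {}
    for cohort, counts in _RAW_PROPS.items():
        tot = float(sum(counts))
        out[cohort] = {t: c / tot for t, c in zip(DEFAULT_CELLTYPES, counts)}
    return out


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort run.

    All effect sizes are natural-log units.  ``theta`` is the negative
    binomial size (var = mu + mu^2/theta); ``tau`` the donor-intercept SD.
    """

    seed: int = 0
    n_genes: int = 600
    cohorts: tuple[str, ...] = COHORTS
    donors_per_cohort: int = 4
    cells_per_donor: int = 300
    celltype_props: dict[str, dict[str, float]] = field(default_factory=_normalized_props)
    n_markers_per_type: int = 20
    marker_lfc: float = 2.0
    condition_effects: dict[tuple[str, str], float] | None = None  # (cell type, gene) -> beta
    n_condition_genes_up: int = 8
    n_condition_genes_down: int = 4
    condition_lfc: float = 1.0
    affected_types: tuple[str, ...] = ("CD8 TEM", "NK")
    tau: float = 0.5
    donor_variable_frac: float = 0.30
    theta: float = 2.0
    libsize_lognormal: tuple[float, float] = (np.log(2500.0), 0.35)
    mito_fraction_beta: tuple[float, float] = (2.0, 65.0)
    doublet_rate: float = 0.05
    n_empty_droplets: int = 2000
    empty_count_range: tuple[int, int] = (10, 150)
    exhaustion_shift: float = 1.0
    exhaustion_target_types: tuple[str, ...] = ("CD8 TEM", "NK")

    @property
    def cell_types(self) -> list[str]:
        return list(next(iter(self.celltype_props.values())).keys())

    def validate(self) -> None:
        for cohort in self.cohorts:
            if cohort not in self.celltype_props:
                raise ValueError(f"no cell-type proportions for cohort {cohort!r}")
            probs = np.array(list(self.celltype_props[cohort].values()))
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"cohort {cohort!r} proportions must be >=0 and sum to 1")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 0 <= self.doublet_rate <= 1:
            raise ValueError("doublet_rate must be in [0, 1]")
        if self.cells_per_donor < 1:
            raise ValueError("cells_per_donor must be >= 1")
        n_named = len(MITO_GENES) + len(EXHAUSTION_GENES)
        n_markers = self.n_markers_per_type * len(self.cell_types)
        if self.n_genes < n_named + n_markers + 50:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_named} named genes, "
                f"{n_markers} markers and a background pool"
            )


def default_config(**overrides) -> SimConfig:
    return SimConfig(**overrides)


@dataclass
class GroundTruth:
    """Per-barcode truth plus the planted per-gene condition-effect table."""

    cells: pd.DataFrame  # barcode, cell_type, donor, cohort, is_doublet, is_empty, parent types
    beta: pd.DataFrame  # cell_type, gene, beta
    marker_genes: dict[str, list[str]]
    donor_variable_genes: list[str]
    donor_intercepts: dict[str, float]
    log_programs: pd.DataFrame  # cell_type x gene baseline log-program (HS, no donor effect)


@dataclass
class ReferencePanel:
    """Labeled mean-expression profiles for reference-based annotation."""

    name: str
    labels: list[str]
    profiles: pd.DataFrame  # label x gene, log-normalized units
    harmonization: dict[str, str]
    sample_profiles: dict[str, np.ndarray] | None = None  # label -> samples x gene
    anchor_cells: tuple[np.ndarray, np.ndarray] | None = None  # (X log-norm, labels)

    def __post_init__(self) -> None:
        missing = [l for l in self.labels if l not in self.harmonization]
        if missing:
            raise ValueError(f"harmonization map not total; unmapped labels: {missing}")


def _gene_ids(config: SimConfig, rng: np.random.Generator):
    n_named = len(MITO_GENES) + len(EXHAUSTION_GENES)
    n_bg = config.n_genes - n_named
    bg = [f"G{i:05d}" for i in range(n_bg)]
    genes = np.array(bg + EXHAUSTION_GENES + MITO_GENES, dtype=object)
    return genes, np.array(bg, dtype=object)


def _build_programs(config: SimConfig, genes, bg_genes, rng):
    """Baseline log-shares, marker assignments and planted effects."""
    G = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(0.0, 1.0, G)
    # exhaustion panel genes sit high in the expression range so that
    # log1p-normalized shifts track the planted log-fold effects
    for g in EXHAUSTION_GENES:
        baseline[gene_index[g]] = rng.normal(2.5, 0.25)
    for g in MITO_GENES:
        baseline[gene_index[g]] = rng.normal(1.0, 0.5)

    # disjoint marker blocks drawn from the background pool
    perm = rng.permutation(len(bg_genes))
    markers: dict[str, list[str]] = {}
    pos = 0
    for t in config.cell_types:
        block = [bg_genes[i] for i in perm[pos : pos + config.n_markers_per_type]]
        markers[t] = block
        pos += config.n_markers_per_type
    marker_pool = pos

    # planted CCI-vs-RAP condition effects
    effects: dict[tuple[str, str], float] = {}
    if config.condition_effects is not None:
        effects = dict(config.condition_effects)
    else:
        for t in config.affected_types:
            n_eff = config.n_condition_genes_up + config.n_condition_genes_down
            block = [bg_genes[i] for i in perm[pos : pos + n_eff]]
            pos += n_eff
            for j, g in enumerate(block):
                sign = 1.0 if j < config.n_condition_genes_up else -1.0
                effects[(t, g)] = sign * config.condition_lfc

    # donor-variable subset: fixed fraction of all genes
    n_dv = int(round(config.donor_variable_frac * G))
    dv_idx = rng.choice(G, size=n_dv, replace=False)
    dv_genes = [genes[i] for i in sorted(dv_idx)]

    # per-(type) log program without donor/condition terms
    programs = {}
    for t in config.cell_types:
        eta = baseline.copy()
        for g in markers[t]:
            eta[gene_index[g]] += config.marker_lfc
        programs[t] = eta
    return baseline, markers, effects, dv_genes, programs, gene_index


def _nb_counts(mu, theta, rng):
    """Gamma-Poisson draw with NB size theta (Poisson limit for huge theta)."""
    if theta > 1e8:
        return rng.poisson(mu)
    lam = rng.gamma(theta, mu / theta)
    return rng.poisson(lam)


def _cell_mu(eta, f_mito, libsize, mito_mask):
    """Per-cell NB means: non-mito shares scaled to (1-f), mito to f."""
    w = np.exp(eta)
    w_m = w * mito_mask
    w_n = w * ~mito_mask
    p = w_n / w_n.sum() * (1.0 - f_mito)
    sm = w_m.sum()
    if sm > 0:
        p = p + w_m / sm * f_mito
    return libsize * p


def simulate_cohort(config: SimConfig):
    """Simulate one cohort run.

    Returns ``(CountMatrix, CellMetadata, GroundTruth)``.  The metadata holds
    one row per emitted barcode (singlets, doublets, empties) with donor,
    cohort and truth flags; identical seeds give identical outputs.
    """
    config.validate()
    rng_genes = substream(config.seed, "genes")
    genes, bg_genes = _gene_ids(config, rng_genes)
    baseline, markers, effects, dv_genes, programs, gene_index = _build_programs(
        config, genes, bg_genes, rng_genes
    )
    G = len(genes)
    mito_mask = np.isin(genes, MITO_GENES)
    dv_mask = np.isin(genes, dv_genes).astype(float)

    rng_donor = substream(config.seed, "donors")
    rng_cells = substream(config.seed, "cells")

    sign_vec = np.zeros(G)
    for g, s in EXHAUSTION_SIGNS.items():
        sign_vec[gene_index[g]] = s

    rows, metas = [], []
    donor_intercepts: dict[str, float] = {}
    donor_counter = 0
    for cohort in config.cohorts:
        props = config.celltype_props[cohort]
        types = list(props.keys())
        p_types = np.array([props[t] for t in types])
        for d in range(config.donors_per_cohort):
            donor_id = f"{cohort}_d{d:02d}"
            u_d = rng_donor.normal(0.0, config.tau)
            donor_intercepts[donor_id] = u_d
            n_cells = config.cells_per_donor
            type_draw = rng_cells.choice(len(types), size=n_cells, p=p_types)
            libsizes = np.exp(
                rng_cells.normal(*config.libsize_lognormal, size=n_cells)
            )
            f_mito = rng_cells.beta(*config.mito_fraction_beta, size=n_cells)
            for t_i in range(len(types)):
                sel = np.flatnonzero(type_draw == t_i)
                if sel.size == 0:
                    continue
                t = types[t_i]
                eta = programs[t] + u_d * dv_mask
                if cohort == "CCI":
                    for (tt, g), b in effects.items():
                        if tt == t:
                            eta[gene_index[g]] += b
                    if t in config.exhaustion_target_types and config.exhaustion_shift:
                        eta = eta + config.exhaustion_shift * sign_vec
                for c in sel:
                    mu = _cell_mu(eta, f_mito[c], libsizes[c], mito_mask)
                    counts = _nb_counts(mu, config.theta, rng_cells)
                    rows.append(counts)
                    metas.append((donor_id, cohort, t, False, False, t, ""))
            donor_counter += 1

    X = np.vstack(rows).astype(np.int64)
    meta = pd.DataFrame(
        metas,
        columns=["donor", "cohort", "cell_type", "is_doublet", "is_empty",
                 "parent_type_a", "parent_type_b"],
    )

    # doublets: sums of two sampled singlets from the same donor
    rng_dbl = substream(config.seed, "doublets")
    n_doublets = int(round(config.doublet_rate * len(meta)))
    dbl_rows, dbl_meta = [], []
    donors_arr = meta["donor"].to_numpy()
    for _ in range(n_doublets):
        d = rng_dbl.choice(np.unique(donors_arr))
        cand = np.flatnonzero(donors_arr == d)
        a, b = rng_dbl.choice(cand, size=2, replace=False)
        dbl_rows.append(X[a] + X[b])
        dbl_meta.append(
            (d, meta.at[a, "cohort"], "doublet", True, False,
             meta.at[a, "cell_type"], meta.at[b, "cell_type"])
        )

    # empties: ambient profile = library-size-weighted average of cell
    # profiles, i.e. the pooled count proportions over all true cells
    rng_amb = substream(config.seed, "ambient")
    ambient = X.sum(axis=0).astype(float)
    ambient /= ambient.sum()
    lo, hi = config.empty_count_range
    empty_tot = rng_amb.integers(lo, hi + 1, size=config.n_empty_droplets)
    if config.n_empty_droplets:
        empty_rows = rng_amb.multinomial(empty_tot, ambient)
    else:
        empty_rows = np.zeros((0, G), dtype=np.int64)
    all_donors = sorted(donor_intercepts)
    empty_meta = []
    for i in range(config.n_empty_droplets):
        d = all_donors[int(rng_amb.integers(len(all_donors)))]
        empty_meta.append((d, d.split("_")[0], "empty", False, True, "", ""))

    X_all = np.vstack([X, np.asarray(dbl_rows).reshape(-1, G), empty_rows]).astype(np.int64)
    meta_all = pd.concat(
        [meta, pd.DataFrame(dbl_meta, columns=meta.columns),
         pd.DataFrame(empty_meta, columns=meta.columns)],
        ignore_index=True,
    ).astype({"is_doublet": bool, "is_empty": bool})
    barcodes = np.array([f"BC{i:06d}" for i in range(len(meta_all))], dtype=object)
    meta_all.insert(0, "barcode", barcodes)

    # shuffle so empties are not trivially grouped at the end
    rng_shuf = substream(config.seed, "shuffle")
    order = rng_shuf.permutation(len(meta_all))
    X_all = X_all[order]
    meta_all = meta_all.iloc[order].reset_index(drop=True)

    # exact three-way layer split by binomial thinning
    rng_split = substream(config.seed, "layers")
    p_s, p_u, p_a = SPLICE_SPLIT
    spliced = rng_split.binomial(X_all, p_s)
    rest = X_all - spliced
    unspliced = rng_split.binomial(rest, p_u / (p_u + p_a))
    ambiguous = rest - unspliced

    m = CountMatrix(
        gene_ids=genes,
        barcodes=meta_all["barcode"].to_numpy(),
        layers={
            "spliced": sp.csr_matrix(spliced),
            "unspliced": sp.csr_matrix(unspliced),
            "ambiguous": sp.csr_matrix(ambiguous),
            "total": sp.csr_matrix(X_all),
        },
        provenance=[f"simulate_cohort(seed={config.seed})"],
    )

    beta_df = pd.DataFrame(
        [(t, g, b) for (t, g), b in effects.items()],
        columns=["cell_type", "gene", "beta"],
    )
    truth = GroundTruth(
        cells=meta_all,
        beta=beta_df,
        marker_genes=markers,
        donor_variable_genes=list(dv_genes),
        donor_intercepts=donor_intercepts,
        log_programs=pd.DataFrame(
            {t: programs[t] for t in config.cell_types}, index=genes
        ).T,
    )
    return m, meta_all, truth


COARSE_MAP = {t: LINEAGE_OF.get(t, t) for t in LINEAGE_OF}


def build_reference_panels(config: SimConfig, n_panels: int = 6, n_cells_per_label: int = 250,
                           n_samples_per_label: int = 8):
    """Simulate labeled reference panels from pure cells.

    Panels mimic heterogeneous external references: most carry the fine
    subtype vocabulary, one is coarse (lineages only), and the last doubles
    as the anchor set for embedding-space kNN transfer.  Each panel draws its
    pure cells with a distinct seed so annotator votes are not identical.
    Profiles and per-label pseudo-sample profiles are mean log1p-normalized
    expression (counts per 10k).
    """
    config.validate()
    rng_genes = substream(config.seed, "genes")
    genes, bg_genes = _gene_ids(config, rng_genes)
    baseline, markers, effects, dv_genes, programs, gene_index = _build_programs(
        config, genes, bg_genes, rng_genes
    )
    G = len(genes)
    mito_mask = np.isin(genes, MITO_GENES)
    panels = []
    for k in range(n_panels):
        coarse = k == n_panels - 2 and n_panels >= 2
        rng = substream(config.seed, f"refpanel{k}")
        labels = config.cell_types
        prof_rows, samp = {}, {}
        anchor_X, anchor_lab = [], []
        for t in labels:
            eta = programs[t]
            cells = []
            libs = np.exp(rng.normal(*config.libsize_lognormal, size=n_cells_per_label))
            f_m = rng.beta(*config.mito_fraction_beta, size=n_cells_per_label)
            for c in range(n_cells_per_label):
                mu = _cell_mu(eta, f_m[c], libs[c], mito_mask)
                cells.append(_nb_counts(mu, config.theta, rng))
            Xc = np.asarray(cells, dtype=float)
            tot = Xc.sum(axis=1, keepdims=True)
            Xn = np.log1p(Xc / tot * 1e4)
            prof_rows[t] = Xn.mean(axis=0)
            groups = np.array_split(np.arange(n_cells_per_label), n_samples_per_label)
            samp[t] = np.vstack([Xn[g].mean(axis=0) for g in groups])
            if k == n_panels - 1:
                anchor_X.append(Xn)
                anchor_lab.extend([t] * n_cells_per_label)
        profiles = pd.DataFrame(prof_rows, index=genes).T
        if coarse:
            lin = pd.Series({t: LINEAGE_OF.get(t, t) for t in labels})
            profiles = profiles.groupby(lin).mean()
            coarse_labels = list(profiles.index)
            samp_c = {}
            for L in coarse_labels:
                members = [t for t in labels if LINEAGE_OF.get(t, t) == L]
                samp_c[L] = np.vstack([samp[t] for t in members])
            panels.append(ReferencePanel(
                name=f"ref{k}_coarse",
                labels=coarse_labels,
                profiles=profiles,
                harmonization={L: L for L in coarse_labels},
                sample_profiles=samp_c,
            ))
        else:
            panels.append(ReferencePanel(
                name=f"ref{k}",
                labels=list(labels),
                profiles=profiles,
                harmonization={t: t for t in labels},
                sample_profiles=samp,
                anchor_cells=(np.vstack(anchor_X), np.array(anchor_lab, dtype=object))
                if k == n_panels - 1 else None,
            ))
    return panels
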