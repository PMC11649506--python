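"""Exhaustion gene-module scores and donor-aware cohort comparison.

A module score for a gene panel is the per-cell mean log-normalized
expression of the panel genes minus the mean of expression-bin-matched
control genes: genes are ranked into ``nbin`` equal-size bins by mean
expression across cells, and each panel gene contributes ``nctrl`` control
genes sampled without replacement from its bin.  Subtracting bin-matched
controls removes the depth/abundance component, leaving a centered score in
log-expression units.

Panels are signed: exhaustion involves up-regulated inhibitory receptors
(TIGIT, LAG3, PDCD1, TOX, ...) and down-regulated effector molecules
(DNAM-1/CD226, KLRK1, TCF7).  The signed score is score(plus genes) -
score(minus genes), so a more exhausted cell scores higher on both arms.
An unsigned mode (all genes pooled) is also available.

Cohort comparisons reuse the donor random-intercept model: the score is the
response, patient condition the fixed effect, and donor the random effect,
run per cell type (and optionally jointly with cell-type fixed effects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .mixedde import LMMFit, fit_lmm

__all__ = [
    "GenePanel",
    "ModuleScores",
    "module_score",
    "exhaustion_test",
    "NK_EXHAUSTION_PANEL",
    "CD8_TEM_EXHAUSTION_PANEL",
]


@dataclass
class GenePanel:
    """Signed gene panel: +1 = exhaustion-up, -1 = exhaustion-down."""

    name: str
    members: dict[str, int]
    target_cell_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("panel must be nonempty")
        bad = {g: w for g, w in self.members.items() if w not in (+1, -1)}
        if bad:
            raise ValueError(f"weights must be +1 or -1: {bad}")

    @property
    def plus_genes(self) -> list[str]:
        return [g for g, w in self.members.items() if w > 0]

    @property
    def minus_genes(self) -> list[str]:
        return [g for g, w in self.members.items() if w < 0]

    def flipped(self) -> "GenePanel":
        return GenePanel(self.name + "_flipped",
                         {g: -w for g, w in self.members.items()},
                         self.target_cell_types)


# Effector molecules down, negative regulators up; CD16/FCGR3A excluded
# (not significantly altered) but can be added back by the caller.
NK_EXHAUSTION_PANEL = GenePanel(
    "nk_exhaustion",
    {"CD226": -1, "KLRK1": -1, "TIGIT": +1, "TOX": +1, "CD96": +1,
     "LAG3": +1, "LAMP1": +1},
    target_cell_types=("NK",),
)

CD8_TEM_EXHAUSTION_PANEL = GenePanel(
    "cd8_tem_exhaustion",
    {"KLRG1": +1, "TCF7": -1, "TNFSF4": +1, "CTLA4": +1, "TIGIT": +1,
     "EOMES": +1, "TOX": +1, "LAG3": +1, "PDCD1": +1, "HAVCR2": +1},
    target_cell_types=("CD8 TEM",),
)


@dataclass
class ModuleScores:
    scores: pd.Series  # per cell, log-expression units, centered
    panel: str
    nbin: int
    nctrl: int
    seed: int
    unsigned: pd.DataFrame | None = None  # per-arm unsigned scores


def _bin_genes(mean_expr: np.ndarray, nbin: int) -> np.ndarray:
    """Equal-size expression bins by rank of mean expression."""
    order = np.argsort(mean_expr, kind="mergesort")
    bins = np.empty(len(mean_expr), dtype=int)
    bins[order] = np.minimum(
        (np.arange(len(mean_expr)) * nbin) // len(mean_expr), nbin - 1
    )
    return bins


def _score_gene_set(X, gene_pos, bins, rng, nctrl, exclude=None):
    """Unsigned score: mean over panel genes minus mean over the pooled
    control multiset (nctrl bin-matched controls per panel gene).

    Panel genes are excluded from the control pools; with few genes per bin
    the panel would otherwise contaminate its own control and cancel real
    signal.
    """
    exclude_set = set(gene_pos if exclude is None else exclude)
    ctrl_cols = []
    for gp in gene_pos:
        pool = np.array(
            [g for g in np.flatnonzero(bins == bins[gp]) if g not in exclude_set]
        )
        if len(pool) == 0:
            # bin exhausted by panel genes: borrow the nearest nonempty bin
            for off in range(1, bins.max() + 1):
                for b in (bins[gp] - off, bins[gp] + off):
                    cand = [g for g in np.flatnonzero(bins == b) if g not in exclude_set]
                    if cand:
                        pool = np.array(cand)
                        break
                if len(pool):
                    break
        take = min(nctrl, len(pool))
        ctrl_cols.append(rng.choice(pool, size=take, replace=False))
    ctrl = np.concatenate(ctrl_cols)
    return X[:, gene_pos].mean(axis=1) - X[:, ctrl].mean(axis=1)


def module_score(
    X,
    gene_ids,
    panel: GenePanel,
    nbin: int = 24,
    nctrl: int = 100,
    seed: int = 0,
    signed: bool = True,
) -> ModuleScores:
    """Per-cell module score with bin-matched control genes.

    ``X`` is cells x genes log-normalized expression.  Panel genes absent
    from ``gene_ids`` are dropped with a warning; an entirely absent panel
    is an error.  The control draw is keyed by ``seed`` and the panel name,
    so identical seeds reproduce identical scores.
    """
    X = np.asarray(X, dtype=float)
    gene_ids = np.asarray(gene_ids)
    if X.shape[1] < nbin:
        raise ValueError(f"need >= nbin={nbin} genes")
    pos = {g: i for i, g in enumerate(gene_ids)}
    present = {g: w for g, w in panel.members.items() if g in pos}
    missing = set(panel.members) - set(present)
    if not present:
        raise ValueError(f"panel {panel.name!r} entirely absent from the matrix")
    if missing:
        warnings.warn(f"panel {panel.name}: {len(missing)} genes absent, dropped")

    mean_expr = X.mean(axis=0)
    bins = _bin_genes(mean_expr, nbin)
    rng = substream(seed, f"module_score:{panel.name}")

    plus = [pos[g] for g, w in present.items() if w > 0]
    minus = [pos[g] for g, w in present.items() if w < 0]
    allpos = np.array(plus + minus)
    unsigned_parts = {}
    if signed:
        s_plus = (
            _score_gene_set(X, np.array(plus), bins, rng, nctrl, exclude=allpos)
            if plus else 0.0
        )
        s_minus = (
            _score_gene_set(X, np.array(minus), bins, rng, nctrl, exclude=allpos)
            if minus else 0.0
        )
        score = s_plus - s_minus
        if plus:
            unsigned_parts["plus"] = s_plus
        if minus:
            unsigned_parts["minus"] = s_minus
    else:
        score = _score_gene_set(X, allpos, bins, rng, nctrl, exclude=allpos)
        unsigned_parts["all"] = score
    return ModuleScores(
        scores=pd.Series(np.asarray(score), name=panel.name),
        panel=panel.name,
        nbin=nbin,
        nctrl=nctrl,
        seed=seed,
        unsigned=pd.DataFrame(unsigned_parts),
    )


def exhaustion_test(
    scores: ModuleScores,
    meta: pd.DataFrame,
    cohort_col: str = "cohort",
    donor_col: str = "donor",
    label_col: str = "consensus",
    reference: str = "RAP",
    comparison: str = "CCI",
    cell_types: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mixed-model cohort contrast on module scores, per cell type.

    For each cell type (default: the panel's targets present in the data)
    the score is modeled with condition fixed effect and donor random
    intercept; returns estimate, SE, p and fit diagnostics per stratum.
    """
    meta = meta.reset_index(drop=True)
    s = np.asarray(scores.scores)
    if len(s) != len(meta):
        raise ValueError("scores and metadata are misaligned")
    if cell_types is None:
        present = set(meta[label_col])
        cell_types = tuple(t for t in present if t != "unassigned")
    rows = []
    for t in cell_types:
        mask = (meta[label_col] == t) & meta[cohort_col].isin([reference, comparison])
        sub = meta.loc[mask]
        for grp in (reference, comparison):
            if (sub[cohort_col] == grp).sum() == 0:
                raise ValueError(f"cell type {t!r} absent in cohort {grp!r}")
        cond = (sub[cohort_col] == comparison).to_numpy().astype(float)
        fit: LMMFit = fit_lmm(s[mask.to_numpy()], cond, sub[donor_col].to_numpy())
        rows.append(
            {
                "cell_type": t,
                "contrast": f"{comparison}:{reference}",
                "estimate": fit.beta1,
                "se": fit.se_beta1,
                "p": fit.p,
                "tau2": fit.tau2,
                "sigma2": fit.sigma2,
                "n_cells": fit.n_cells,
                "n_donors": fit.n_donors,
            }
        )
    return pd.DataFrame(rows)
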