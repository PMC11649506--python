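"""Droplet cell-calling and cell-level QC filters.

Three filters, applied in order:

1. ``call_cells`` — distinguishes real cells from ambient (cell-free) RNA.
   The ambient profile is pooled from low-count barcodes; every barcode
   above that pool is tested for multinomial goodness of fit against the
   ambient proportions with a Monte-Carlo p-value, BH-adjusted, and kept at
   FDR < 0.01.  Barcodes above the knee of the ranked library-size curve are
   always called.
2. ``flag_doublets`` — scores each called cell by the fraction of artificial
   doublets (sums of random cell pairs) among its nearest neighbors in a
   joint PCA embedding.
3. ``mito_filter`` — keeps cells whose spliced mitochondrial read fraction
   is strictly below 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._rng import substream
from .containers import CountMatrix
from .mixedde import bh_adjust

__all__ = ["QCReport", "call_cells", "flag_doublets", "mito_filter", "run_qc", "knee_point"]


@dataclass
class QCReport:
    """Per-barcode QC scores and flags plus stage summary counts."""

    table: pd.DataFrame
    summary: dict[str, int] = field(default_factory=dict)

    def kept_barcodes(self) -> np.ndarray:
        return self.table.loc[self.table["kept"], "barcode"].to_numpy()


def knee_point(totals: np.ndarray, smooth: int = 11) -> float:
    """Knee of the ranked log-total vs log-rank curve.

    Returns the total-count value at the point of maximum negative second
    difference after moving-average smoothing; barcodes at or above this
    total sit on the cell plateau of the barcode-rank curve.
    """
    t = np.sort(np.asarray(totals))[::-1].astype(float)
    t = t[t > 0]
    if len(t) < 3 * smooth:
        return float(t[len(t) // 2]) if len(t) else 0.0
    logt = np.log10(t)
    kern = np.ones(smooth) / smooth
    sm = np.convolve(logt, kern, mode="valid")
    d2 = np.diff(sm, 2)
    knee_rank = int(np.argmin(d2)) + smooth // 2 + 1
    return float(t[min(knee_rank, len(t) - 1)])


def _mc_pvalues(counts: sp.csr_matrix, totals, test_idx, log_p, n_mc, rng):
    """Monte-Carlo goodness-of-fit p-values against the ambient profile.

    The statistic is the multinomial log-likelihood of the barcode under the
    ambient proportions, T = sum_g x_g log p_g - log x_g!; small T means the
    barcode is unlikely to be a pure ambient draw (one-sided lower tail).
    Null draws are built incrementally: simulated droplets grow from one
    tested total to the next by adding categorical draws, so the cost is
    O(n_mc * max_total) category samples overall.  p = (1 + #{T_sim <=
    T_obs}) / (n_mc + 1), so the smallest attainable p is 1/(n_mc+1).
    """
    G = len(log_p)
    p = np.exp(log_p)
    p = p / p.sum()
    order = np.argsort(totals[test_idx], kind="mergesort")
    test_sorted = test_idx[order]
    tot_sorted = totals[test_sorted].astype(int)

    sim_counts = np.zeros((n_mc, G), dtype=np.int64)
    sim_T = np.zeros(n_mc)
    cur_total = 0
    pvals = np.empty(len(test_sorted))
    pos = 0
    for u in np.unique(tot_sorted):
        delta = int(u) - cur_total
        if delta > 0:
            # grow every simulated droplet by `delta` ambient draws and
            # update T_j += sum_g [d log p - (lgamma(x+d+1) - lgamma(x+1))]
            draws = rng.choice(G, size=n_mc * delta, p=p)
            sim_of = np.repeat(np.arange(n_mc), delta)
            keys = sim_of.astype(np.int64) * G + draws
            uk, counts_k = np.unique(keys, return_counts=True)
            sj, gj = uk // G, uk % G
            x_old = sim_counts[sj, gj]
            contrib = counts_k * log_p[gj] - (
                gammaln(x_old + counts_k + 1.0) - gammaln(x_old + 1.0)
            )
            np.add.at(sim_T, sj, contrib)
            sim_counts[sj, gj] = x_old + counts_k
            cur_total = int(u)
        while pos < len(tot_sorted) and tot_sorted[pos] == u:
            row = counts.getrow(test_sorted[pos])
            x = row.data
            T_obs = float(x @ log_p[row.indices] - gammaln(x + 1.0).sum())
            pvals[pos] = (1.0 + np.sum(sim_T <= T_obs + 1e-9)) / (n_mc + 1.0)
            pos += 1
    out = np.empty(len(test_sorted))
    out[order] = pvals
    return out


def call_cells(
    raw: CountMatrix,
    ambient_count_max: int = 100,
    n_mc: int = 10000,
    fdr_threshold: float = 0.01,
    seed: int = 0,
    ambient_pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Ambient Monte-Carlo cell calling at FDR < ``fdr_threshold``.

    Returns a per-barcode frame with total_count, ambient_pvalue,
    ambient_fdr and the called_cell flag.  Barcodes with total at or below
    ``ambient_count_max`` form the ambient pool and are never called;
    barcodes above the knee of the rank curve are always called.
    """
    if n_mc < 100:
        raise ValueError("n_mc must be >= 100")
    totals = raw.total_counts()
    ambient_pool = totals <= ambient_count_max
    if not ambient_pool.any():
        raise ValueError("no ambient pool: no barcodes at or below ambient_count_max")
    X = raw.layer("total")
    ambient = np.asarray(X[ambient_pool].sum(axis=0)).ravel() + ambient_pseudocount
    log_p = np.log(ambient / ambient.sum())

    knee = knee_point(totals)
    # barcodes on the knee plateau are always called; Monte-Carlo testing is
    # reserved for the ambiguous zone between the ambient pool and the knee
    tested = np.flatnonzero((totals > ambient_count_max) & (totals < knee))
    rng = substream(seed, "call_cells")
    pvals = np.full(raw.n_cells, np.nan)
    fdr = np.full(raw.n_cells, np.nan)
    if len(tested):
        pvals[tested] = _mc_pvalues(X, totals, tested, log_p, n_mc, rng)
        fdr[tested] = bh_adjust(pvals[tested])
    called = np.zeros(raw.n_cells, dtype=bool)
    called[tested] = fdr[tested] < fdr_threshold
    called |= totals >= knee
    called &= totals > ambient_count_max
    return pd.DataFrame(
        {
            "barcode": raw.barcodes,
            "total_count": totals,
            "ambient_pvalue": pvals,
            "ambient_fdr": fdr,
            "called_cell": called,
        }
    )


def flag_doublets(
    called: CountMatrix,
    n_sim_doublets: int | None = None,
    k_neighbors: int = 25,
    score_threshold: float | None = None,
    expected_doublet_rate: float = 0.05,
    n_pcs: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Artificial-doublet kNN scoring.

    Simulated doublets are sums of random cell pairs.  In a joint PCA of
    log-normalized real + simulated profiles, each real cell's score is the
    fraction of simulated doublets among its ``k_neighbors`` nearest
    neighbors, rescaled by the real:simulated ratio so a score of ~1 means
    the local density of artificial doublets matches what a pure doublet
    neighborhood would show.  Without an explicit threshold the top
    ``expected_doublet_rate`` fraction of scores is flagged.
    """
    n = called.n_cells
    if n_sim_doublets is None:
        n_sim_doublets = n
    if n_sim_doublets < k_neighbors:
        raise ValueError("n_sim_doublets must be >= k_neighbors")
    if n < 2 * k_neighbors:
        raise ValueError("need at least 2*k_neighbors called cells")
    rng = substream(seed, "doublets")
    X = called.layer("total")
    pairs_a = rng.integers(0, n, size=n_sim_doublets)
    pairs_b = rng.integers(0, n, size=n_sim_doublets)
    sim = X[pairs_a] + X[pairs_b]
    joint = sp.vstack([X, sim]).tocsr()
    tot = np.asarray(joint.sum(axis=1)).ravel().astype(float)
    tot[tot == 0] = 1.0
    norm = joint.multiply(1e4 / tot[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    n_comp = min(n_pcs, norm.shape[1] - 1, norm.shape[0] - 1)
    emb = PCA(n_components=n_comp, svd_solver="randomized",
              random_state=int(seed) % (2**31)).fit_transform(norm.toarray())
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    idx = idx[:, 1:]  # drop self
    frac_sim = (idx >= n).mean(axis=1)
    score = frac_sim * (n / n_sim_doublets)
    if score_threshold is None:
        score_threshold = float(np.quantile(score, 1.0 - expected_doublet_rate))
        flag = score > score_threshold
    else:
        flag = score > score_threshold
    return pd.DataFrame(
        {"barcode": called.barcodes, "doublet_score": score, "doublet_flag": flag}
    )


def mito_filter(
    m: CountMatrix, mito_gene_ids, threshold: float = 0.05
) -> pd.DataFrame:
    """Spliced mitochondrial fraction filter (kept iff fraction < threshold).

    The strict inequality matters: a cell at exactly 5% is removed.  Cells
    with zero spliced counts have an undefined fraction and are removed with
    a warning.
    """
    mito_gene_ids = [g for g in mito_gene_ids]
    missing = set(mito_gene_ids) - set(m.gene_ids)
    if missing:
        raise ValueError(f"mito genes not in matrix: {sorted(missing)}")
    spliced = m.layer("spliced")
    mito_mask = np.isin(m.gene_ids, mito_gene_ids)
    mito_counts = np.asarray(spliced[:, mito_mask].sum(axis=1)).ravel()
    tot = np.asarray(spliced.sum(axis=1)).ravel()
    frac = np.full(len(tot), np.nan)
    nz = tot > 0
    frac[nz] = mito_counts[nz] / tot[nz]
    if (~nz).any():
        warnings.warn(f"{(~nz).sum()} cells with zero spliced counts removed")
    kept = nz & (frac < threshold)
    return pd.DataFrame(
        {"barcode": m.barcodes, "mito_fraction": frac, "kept": kept}
    )


def run_qc(
    raw: CountMatrix,
    mito_gene_ids,
    ambient_count_max: int = 100,
    n_mc: int = 10000,
    fdr_threshold: float = 0.01,
    mito_threshold: float = 0.05,
    expected_doublet_rate: float = 0.05,
    k_neighbors: int = 25,
    seed: int = 0,
) -> QCReport:
    """Full QC pass: call cells, flag doublets among called, mito-filter.

    The report's ``kept`` flag telescopes: kept = called - doublets_removed
    - mito_removed.
    """
    calls = call_cells(raw, ambient_count_max, n_mc, fdr_threshold, seed)
    called_idx = np.flatnonzero(calls["called_cell"].to_numpy())
    called_m = raw.subset_cells(called_idx, note="called cells")
    dbl = flag_doublets(
        called_m, k_neighbors=k_neighbors,
        expected_doublet_rate=expected_doublet_rate, seed=seed,
    )
    mito = mito_filter(called_m, mito_gene_ids, mito_threshold)

    table = calls.copy()
    table["doublet_score"] = np.nan
    table["doublet_flag"] = False
    table["mito_fraction"] = np.nan
    table.loc[called_idx, "doublet_score"] = dbl["doublet_score"].to_numpy()
    table.loc[called_idx, "doublet_flag"] = dbl["doublet_flag"].to_numpy()
    table.loc[called_idx, "mito_fraction"] = mito["mito_fraction"].to_numpy()
    mito_kept = np.zeros(raw.n_cells, dtype=bool)
    mito_kept[called_idx] = mito["kept"].to_numpy()
    table["kept"] = (
        table["called_cell"] & ~table["doublet_flag"] & mito_kept
    )
    n_called = int(table["called_cell"].sum())
    n_dbl = int((table["called_cell"] & table["doublet_flag"]).sum())
    n_mito = int(
        (table["called_cell"] & ~table["doublet_flag"] & ~mito_kept).sum()
    )
    summary = {
        "n_barcodes": raw.n_cells,
        "called": n_called,
        "doublets_removed": n_dbl,
        "mito_removed": n_mito,
        "kept": n_called - n_dbl - n_mito,
    }
    return QCReport(table=table, summary=summary)
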