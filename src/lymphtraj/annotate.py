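"""Reference-based per-cell annotation and consensus labeling.

Each cell receives a call from several independent annotators — rank
(Spearman) correlation against labeled reference panels, plus a kNN label
transfer in the corrected embedding — harmonized to a common subtype
vocabulary.  The consensus label is the modal harmonized call when the
agreement fraction strictly exceeds 0.80 (so 5 of 6 annotators assign,
4 of 6 or 4 of 5 do not); otherwise the cell is "unassigned" and excluded
downstream.  Only lymphoid lineages (B, CD4 T, CD8 T, other T, NK) are
retained for the composition and expression analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthdata import LINEAGE_OF, ReferencePanel

__all__ = [
    "AnnotationResult",
    "annotate_correlation",
    "annotate_knn",
    "consensus",
    "subset_lymphoid",
    "LYMPHOID_LINEAGES",
]

LYMPHOID_LINEAGES = ("B", "CD4 T", "CD8 T", "other T", "NK")

UNASSIGNED = "unassigned"


@dataclass
class AnnotationResult:
    """Per cell x annotator labels plus the consensus call."""

    per_annotator: pd.DataFrame  # columns: one per annotator, harmonized labels
    scores: pd.DataFrame
    consensus_label: pd.Series
    agreement: pd.Series


def _pair_markers(profiles: pd.DataFrame, top_n: int) -> np.ndarray:
    """Union of top-N genes by profile difference over ordered label pairs."""
    labels = list(profiles.index)
    marker_idx: set[int] = set()
    P = profiles.to_numpy()
    for i in range(len(labels)):
        for j in range(len(labels)):
            if i == j:
                continue
            diff = P[i] - P[j]
            marker_idx.update(np.argsort(diff)[::-1][:top_n].tolist())
    return np.array(sorted(marker_idx))


def _spearman_scores(cells: np.ndarray, panel: ReferencePanel, genes_idx,
                     labels, quantile: float) -> np.ndarray:
    """Per-cell score for each label: the given quantile of Spearman
    correlations with the label's sample profiles over marker genes."""
    Xm = cells[:, genes_idx]
    r_cells = rankdata(Xm, axis=1)
    r_cells = (r_cells - r_cells.mean(axis=1, keepdims=True))
    norms = np.linalg.norm(r_cells, axis=1)
    norms[norms == 0] = 1.0
    r_cells /= norms[:, None]
    scores = np.empty((cells.shape[0], len(labels)))
    for li, lab in enumerate(labels):
        if panel.sample_profiles is not None and lab in panel.sample_profiles:
            refs = panel.sample_profiles[lab][:, genes_idx]
        else:
            refs = panel.profiles.loc[[lab]].to_numpy()[:, genes_idx]
        r_ref = rankdata(refs, axis=1)
        r_ref = r_ref - r_ref.mean(axis=1, keepdims=True)
        nr = np.linalg.norm(r_ref, axis=1)
        nr[nr == 0] = 1.0
        r_ref /= nr[:, None]
        corr = r_cells @ r_ref.T  # cells x samples
        scores[:, li] = np.quantile(corr, quantile, axis=1)
    return scores


def annotate_correlation(
    cells: np.ndarray,
    gene_ids,
    ref: ReferencePanel,
    quantile: float = 0.8,
    fine_tune_rounds: int = 2,
    fine_tune_margin: float = 0.05,
    top_n_markers: int = 30,
    min_gene_overlap: int = 50,
) -> pd.DataFrame:
    """Label cells by rank correlation with reference profiles.

    Marker genes are the union of top-N profile-difference genes over every
    ordered label pair; each cell is scored against every label by the
    ``quantile`` of its Spearman correlations with the label's sample
    profiles over those markers.  Labels within ``fine_tune_margin`` of the
    top are re-scored on markers recomputed for that label subset
    (``fine_tune_rounds`` times).  Returns per-cell label (panel
    vocabulary), harmonized label and score.
    """
    gene_ids = np.asarray(gene_ids)
    cells = np.asarray(cells, dtype=float)
    common = [g for g in ref.profiles.columns if g in set(gene_ids)]
    if len(common) < min_gene_overlap:
        raise ValueError(
            f"insufficient feature overlap: {len(common)} < {min_gene_overlap}"
        )
    gpos = {g: i for i, g in enumerate(gene_ids)}
    cells = cells[:, [gpos[g] for g in common]]
    profiles = ref.profiles[common]
    labels = list(profiles.index)

    # initial scoring over all labels
    markers = _pair_markers(profiles, top_n_markers)
    # align sample profiles to the common gene order
    panel_common = ReferencePanel(
        name=ref.name, labels=labels, profiles=profiles,
        harmonization=dict(ref.harmonization),
        sample_profiles=None if ref.sample_profiles is None else {
            l: pd.DataFrame(ref.sample_profiles[l], columns=ref.profiles.columns)[common].to_numpy()
            for l in labels
        },
    )
    scores = _spearman_scores(cells, panel_common, markers, labels, quantile)

    best = np.argmax(scores, axis=1)
    best_score = scores[np.arange(len(cells)), best]

    for _ in range(fine_tune_rounds):
        changed = False
        candidate_sets: dict[tuple, list[int]] = {}
        for ci in range(len(cells)):
            cand = tuple(
                sorted(
                    li for li in range(len(labels))
                    if scores[ci, li] >= best_score[ci] - fine_tune_margin
                )
            )
            if len(cand) > 1 and len(cand) < len(labels):
                candidate_sets.setdefault(cand, []).append(ci)
        for cand, cell_list in candidate_sets.items():
            sub_labels = [labels[li] for li in cand]
            sub_prof = profiles.loc[sub_labels]
            mk = _pair_markers(sub_prof, top_n_markers)
            sub_scores = _spearman_scores(
                cells[cell_list], panel_common, mk, sub_labels, quantile
            )
            for row, ci in enumerate(cell_list):
                li_local = int(np.argmax(sub_scores[row]))
                li = cand[li_local]
                if li != best[ci]:
                    changed = True
                best[ci] = li
                best_score[ci] = sub_scores[row, li_local]
                for lj, sc in zip(cand, sub_scores[row]):
                    scores[ci, lj] = sc
        if not changed:
            break

    out_labels = np.array([labels[b] for b in best], dtype=object)
    harmonized = np.array([ref.harmonization[l] for l in out_labels], dtype=object)
    return pd.DataFrame(
        {"label": out_labels, "harmonized": harmonized, "score": best_score}
    )


def annotate_knn(cells_coords: np.ndarray, anchor_coords: np.ndarray,
                 anchor_labels, k: int = 15,
                 harmonization: dict[str, str] | None = None) -> pd.DataFrame:
    """Majority label among the k nearest anchors in a shared embedding."""
    from sklearn.neighbors import NearestNeighbors

    anchor_labels = np.asarray(anchor_labels, dtype=object)
    if len(anchor_labels) == 0:
        raise ValueError("anchors must be nonempty")
    if k > len(anchor_labels):
        raise ValueError("k exceeds the number of anchors")
    nn = NearestNeighbors(n_neighbors=k).fit(np.asarray(anchor_coords, dtype=float))
    _, idx = nn.kneighbors(np.asarray(cells_coords, dtype=float))
    labels_out, scores = [], []
    for row in idx:
        votes = pd.Series(anchor_labels[row]).value_counts()
        labels_out.append(votes.index[0])
        scores.append(votes.iloc[0] / k)
    labels_out = np.array(labels_out, dtype=object)
    harmonized = (
        np.array([harmonization.get(l, l) for l in labels_out], dtype=object)
        if harmonization
        else labels_out.copy()
    )
    return pd.DataFrame({"label": labels_out, "harmonized": harmonized, "score": scores})


def consensus(per_annotator: pd.DataFrame, threshold: float = 0.80) -> AnnotationResult:
    """Modal harmonized label when the vote fraction strictly exceeds
    ``threshold``; ties and sub-threshold fractions give "unassigned".

    ``per_annotator`` holds one column of harmonized labels per annotator;
    NaN means the annotator made no call for that cell.
    """
    labels_out, agreement = [], []
    arr = per_annotator.to_numpy(dtype=object)
    for row in arr:
        calls = [c for c in row if isinstance(c, str) and c]
        if not calls:
            labels_out.append(UNASSIGNED)
            agreement.append(0.0)
            continue
        counts = pd.Series(calls).value_counts()
        top = counts.iloc[0]
        frac = top / len(calls)
        tie = (counts == top).sum() > 1
        if frac > threshold and not tie:
            labels_out.append(counts.index[0])
        else:
            labels_out.append(UNASSIGNED)
        agreement.append(float(frac))
    return AnnotationResult(
        per_annotator=per_annotator,
        scores=pd.DataFrame(index=per_annotator.index),
        consensus_label=pd.Series(labels_out, index=per_annotator.index, name="consensus"),
        agreement=pd.Series(agreement, index=per_annotator.index, name="agreement"),
    )


def subset_lymphoid(meta: pd.DataFrame, label_col: str = "consensus",
                    lineage_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Keep cells whose consensus lineage is lymphoid; idempotent.

    Unassigned cells are dropped; a consensus label with unknown lineage is
    an error naming the label.  The result carries per-lineage counts in
    ``.attrs['lineage_counts']``.
    """
    lineage_of = dict(LINEAGE_OF if lineage_of is None else lineage_of)
    for lin in LYMPHOID_LINEAGES:
        lineage_of.setdefault(lin, lin)
    labels = meta[label_col]
    keep = np.zeros(len(meta), dtype=bool)
    lineages = []
    for i, lab in enumerate(labels):
        if lab == UNASSIGNED:
            lineages.append(None)
            continue
        if lab not in lineage_of:
            raise ValueError(f"unknown lineage for label {lab!r}")
        lin = lineage_of[lab]
        lineages.append(lin)
        keep[i] = lin in LYMPHOID_LINEAGES
    out = meta.loc[keep].copy()
    out["lineage"] = [lineages[i] for i in np.flatnonzero(keep)]
    out.attrs["lineage_counts"] = out["lineage"].value_counts().to_dict()
    return out
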