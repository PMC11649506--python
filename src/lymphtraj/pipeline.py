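"""End-to-end orchestration: simulate -> qc -> cluster -> annotate ->
compose -> de -> score -> enrich, with a JSON run manifest.

Each stage reads the previous stage's declared outputs and writes delimited
text (CSV/TSV, MatrixMarket for sparse counts); the manifest records the
seed, per-stage cell/gene counts and output file hashes so a run is
auditable and byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import composition as comp
from . import embed_cluster as emb
from . import enrich as enr
from . import exhaustion as exh
from . import mixedde as de
from . import qc as qcmod
from . import synthdata as syn
from .containers import CountMatrix, write_10x_triplet

__all__ = ["RunConfig", "run", "table2_report"]

STAGES = ["simulate", "qc", "cluster", "annotate", "compose", "de", "score", "enrich"]


@dataclass
class RunConfig:
    """Pipeline configuration: stage toggles and per-stage parameters."""

    outdir: str = "lymphtraj_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    qc: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    score: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in
                ("outdir", "seed", "stages", "sim", "qc", "cluster",
                 "annotate", "de", "score", "enrich")}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} requires missing input {path}; run its upstream stage first"
        )
    return path


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in fixed order; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    manifest: dict = {"seed": seed, "stages": {}, "outputs": {}}
    enabled = [s for s in STAGES if s in config.stages]

    m: CountMatrix | None = None
    meta: pd.DataFrame | None = None
    Xn = None
    coords = None
    clusters = None
    panels = None
    de_tables: dict[str, pd.DataFrame] = {}

    if "simulate" in enabled:
        cfg = syn.SimConfig(seed=seed, **config.sim)
        m, meta, truth = syn.simulate_cohort(cfg)
        write_10x_triplet(m, out / "counts")
        meta.to_csv(out / "cells.csv", index=False)
        truth.cells.to_csv(out / "ground_truth_cells.csv", index=False)
        truth.beta.to_csv(out / "ground_truth_beta.csv", index=False)
        meta[["barcode", "donor", "cohort"]].to_csv(out / "sample_sheet.csv", index=False)
        panels = syn.build_reference_panels(
            syn.SimConfig(seed=seed, **{**config.sim, "n_empty_droplets": 0}),
            n_panels=6,
        )
        manifest["stages"]["simulate"] = {
            "n_barcodes": m.n_cells, "n_genes": m.n_genes,
        }

    if "qc" in enabled:
        if m is None:
            _require(out / "counts" / "matrix.mtx", "qc")
            from .containers import read_10x_triplet
            m = read_10x_triplet(out / "counts")
            meta = pd.read_csv(_require(out / "cells.csv", "qc"))
        report = qcmod.run_qc(
            m, [g for g in syn.MITO_GENES if g in set(m.gene_ids)],
            seed=seed, **config.qc,
        )
        report.table.to_csv(out / "qc_report.csv", index=False)
        kept = report.table["kept"].to_numpy()
        m = m.subset_cells(np.flatnonzero(kept), note="qc kept")
        meta = meta.loc[kept].reset_index(drop=True)
        manifest["stages"]["qc"] = dict(report.summary)

    if "cluster" in enabled:
        if m is None:
            raise FileNotFoundError("stage 'cluster' requires in-memory counts; enable qc")
        params = dict(config.cluster)
        norm_method = params.pop("norm", "libsize")
        n_pcs = params.pop("pcs", 50)
        k = params.pop("k_neighbors", 100)
        resolution = params.pop("resolution", 0.1)
        batch_key = params.pop("batch_key", "donor")
        Xn = emb.lognormalize(m, method=norm_method)
        e = emb.pca(Xn, n=min(n_pcs, min(Xn.shape) - 1), seed=seed,
                    cell_ids=m.barcodes)
        e = emb.integrate(e, meta[batch_key].to_numpy(), seed=seed)
        coords = e.coords
        clusters = emb.louvain(e, k_neighbors=min(k, len(coords) - 1),
                               resolution=resolution, seed=seed)
        meta = meta.assign(cluster=clusters)
        df = pd.DataFrame(coords, index=m.barcodes)
        df.insert(0, "cluster", clusters)
        df.to_csv(out / "embedding.csv")
        manifest["stages"]["cluster"] = {
            "n_cells": len(coords), "n_clusters": int(len(np.unique(clusters))),
        }

    if "annotate" in enabled:
        if Xn is None or panels is None:
            raise FileNotFoundError("stage 'annotate' requires cluster outputs and panels")
        calls = {}
        for p in panels[:-1]:
            res = ann.annotate_correlation(Xn, m.gene_ids, p, **config.annotate)
            calls[p.name] = res["harmonized"]
        anchor_X, anchor_lab = panels[-1].anchor_cells
        joint = np.vstack([Xn, anchor_X])
        ej = emb.pca(joint, n=min(50, min(joint.shape) - 1), seed=seed)
        res_knn = ann.annotate_knn(
            ej.coords[: len(Xn)], ej.coords[len(Xn):], anchor_lab, k=15
        )
        calls["knn"] = res_knn["harmonized"]
        per = pd.DataFrame(calls)
        cons = ann.consensus(per)
        meta = meta.assign(
            consensus=cons.consensus_label.to_numpy(),
            agreement=cons.agreement.to_numpy(),
        )
        ann_out = per.copy()
        ann_out.insert(0, "barcode", m.barcodes)
        ann_out["consensus"] = cons.consensus_label.to_numpy()
        ann_out["agreement"] = cons.agreement.to_numpy()
        ann_out.to_csv(out / "annotations.csv", index=False)
        lymph = ann.subset_lymphoid(meta)
        keep_mask = meta.index.isin(lymph.index)
        Xn = Xn[keep_mask]
        m = m.subset_cells(np.flatnonzero(keep_mask), note="lymphoid subset")
        meta = lymph.reset_index(drop=True)
        manifest["stages"]["annotate"] = {
            "assigned": int((cons.consensus_label != ann.UNASSIGNED).sum()),
            "lymphoid": len(meta),
        }

    if "compose" in enabled:
        if meta is None or "consensus" not in meta:
            raise FileNotFoundError("stage 'compose' requires annotate outputs")
        table = comp.crosstab(meta)
        table.to_csv(out / "composition.csv")
        fr = comp.subject_proportions(meta)
        fr.to_csv(out / "subject_fractions.csv")
        try:
            stats_df = comp.composition_anova(fr)
            stats_df.to_csv(out / "composition_anova.csv", index=False)
        except ValueError as err:
            warnings.warn(f"composition ANOVA skipped: {err}")
        manifest["stages"]["compose"] = {"grand_total": table.grand_total}

    if "de" in enabled:
        if Xn is None or meta is None or "consensus" not in meta.columns:
            raise FileNotFoundError("stage 'de' requires annotate outputs")
        params = dict(config.de)
        cell_types = params.pop("cell_types", None)
        if cell_types is None:
            vc = meta.loc[meta.cohort.isin(["RAP", "CCI"]), "consensus"].value_counts()
            cell_types = [t for t, c in vc.items() if c >= 40]
        for t in cell_types:
            try:
                tab = de.de_celltype(
                    Xn, m.gene_ids, meta, t, lineage_of=syn.LINEAGE_OF, **params
                )
            except ValueError as err:
                warnings.warn(f"DE skipped for {t!r}: {err}")
                continue
            de_tables[t] = tab
            tab.to_csv(out / f"de_{t.replace(' ', '_')}.csv", index=False)
        manifest["stages"]["de"] = {
            t: int(tab["significant"].sum()) for t, tab in de_tables.items()
        }

    if "score" in enabled:
        if Xn is None:
            raise FileNotFoundError("stage 'score' requires cluster outputs")
        results = []
        for panel in (exh.CD8_TEM_EXHAUSTION_PANEL, exh.NK_EXHAUSTION_PANEL):
            try:
                ms = exh.module_score(Xn, m.gene_ids, panel, seed=seed, **config.score)
            except ValueError as err:
                warnings.warn(f"scoring skipped for {panel.name}: {err}")
                continue
            pd.DataFrame(
                {"barcode": m.barcodes, "score": ms.scores}
            ).to_csv(out / f"scores_{panel.name}.csv", index=False)
            targets = [
                t for t in panel.target_cell_types
                if t in set(meta.get("consensus", []))
            ]
            if targets and {"RAP", "CCI"} <= set(meta["cohort"]):
                try:
                    res = exh.exhaustion_test(ms, meta, cell_types=tuple(targets))
                    res.insert(0, "panel", panel.name)
                    results.append(res)
                except ValueError as err:
                    warnings.warn(f"exhaustion test skipped for {panel.name}: {err}")
        if results:
            pd.concat(results, ignore_index=True).to_csv(
                out / "exhaustion_tests.csv", index=False
            )
        manifest["stages"]["score"] = {"panels": 2}

    if "enrich" in enabled:
        if not de_tables:
            raise FileNotFoundError("stage 'enrich' requires de outputs")
        gmt_path = config.enrich.get("gmt")
        alpha = config.enrich.get("alpha", 0.05)
        frames = []
        for t, tab in de_tables.items():
            universe = tab["gene"].tolist()
            sig = tab.loc[tab["significant"], "gene"].tolist()
            if not sig:
                continue
            if gmt_path:
                coll = enr.read_gmt(gmt_path)
            else:
                coll = _truth_collection(out, universe, seed)
            res = enr.fisher_enrich(sig, universe, coll, p_adj_threshold=alpha)
            res.insert(0, "cell_type", t)
            frames.append(res)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / "enrichment.csv", index=False
            )
        manifest["stages"]["enrich"] = {"tables": len(frames)}

    for p in sorted(out.rglob("*.csv")):
        manifest["outputs"][str(p.relative_to(out))] = _hash(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _truth_collection(out: Path, universe, seed: int) -> enr.GeneSetCollection:
    """Synthetic gene-set collection: the planted condition-effect genes of
    each affected cell type plus seeded random background sets."""
    beta_path = out / "ground_truth_beta.csv"
    sets: dict[str, list[str]] = {}
    if beta_path.exists():
        beta = pd.read_csv(beta_path)
        for t, grp in beta.groupby("cell_type"):
            genes = [g for g in grp["gene"].str.upper() if g in {u.upper() for u in universe}]
            if genes:
                sets[f"planted_{t.replace(' ', '_')}"] = genes
    rng = np.random.default_rng([seed, 977])
    uni = sorted({str(g).upper() for g in universe})
    for i in range(5):
        size = int(rng.integers(10, 40))
        sets[f"random_{i}"] = list(rng.choice(uni, size=min(size, len(uni)), replace=False))
    return enr.GeneSetCollection(source="synthetic-truth", sets=sets)


def table2_report(meta: pd.DataFrame, outpath=None) -> comp.CompositionTable:
    """Cohort x subtype cross-tab plus per-lineage totals in the fixed
    lineage-grouped row order."""
    table = comp.crosstab(meta)
    if outpath is not None:
        table.to_csv(outpath)
    lineage_totals = {}
    for lin, subs in syn.TABLE2_SUBTYPES.items():
        present = [s for s in subs if s in table.counts.index]
        lineage_totals[lin] = int(table.counts.loc[present].to_numpy().sum())
    table.counts.attrs["lineage_totals"] = lineage_totals
    return table
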