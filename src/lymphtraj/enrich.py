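"""Gene-set over-representation analysis of DE gene lists.

Fisher's exact (one-sided hypergeometric) test of each gene set against the
DE list within a stated universe, BH-corrected across sets within a
collection, kept at adjusted p < 0.05.  The universe defaults to the genes
actually tested in the DE stratum (post expression filter), not the whole
genome.  Collections load from GMT files; no databases are bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .mixedde import bh_adjust

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "fisher_enrich"]


@dataclass
class GeneSetCollection:
    source: str
    sets: dict[str, list[str]]  # preserves insertion order; genes deduplicated

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set {name!r}")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (set name, description, genes; tab-delimited)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-delimited fields")
            name = fields[0].strip()
            genes, seen = [], set()
            for g in fields[2:]:
                g = g.strip().upper()
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(source=str(path), sets=sets)


def write_gmt(collection: GeneSetCollection, path, descriptions=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in collection.sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


def fisher_enrich(
    de_genes,
    universe,
    collection: GeneSetCollection,
    p_adj_threshold: float = 0.05,
    depletion: bool = False,
) -> pd.DataFrame:
    """One-sided enrichment test of each set against the DE list.

    For a set S, the 2x2 table is (DE&S, DE\\S, S\\DE, rest) over the
    universe; p is the hypergeometric upper tail P(overlap >= observed).
    BH correction is applied across the sets of the collection; ``kept``
    flags sets with adjusted p below the threshold.
    """
    universe = {str(g).upper() for g in universe}
    de = {str(g).upper() for g in de_genes}
    if not universe:
        raise ValueError("empty universe")
    if not de:
        raise ValueError("empty DE gene list")
    stray = de - universe
    if stray:
        raise ValueError(f"DE genes outside the universe: {sorted(stray)[:5]} ...")
    N, K = len(universe), len(de)
    rows = []
    for name, genes in collection.sets.items():
        S = set(genes) & universe
        n = len(S)
        k = len(S & de)
        if n == 0:
            continue
        if depletion:
            p = float(stats.hypergeom.cdf(k, N, K, n))
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b = k, K - k
        c, d = n - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((name, k, n, odds, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "odds_ratio", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["kept"] = out["p_adj"] < p_adj_threshold
    else:
        out["p_adj"] = []
        out["kept"] = []
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def fisher_enrich_directional(
    de_table: pd.DataFrame,
    universe,
    collection: GeneSetCollection,
    p_adj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Run enrichment separately on up- and down-regulated DE genes."""
    frames = []
    for direction in ("up", "down"):
        genes = de_table.loc[
            de_table["significant"] & (de_table["direction"] == direction), "gene"
        ]
        if len(genes) == 0:
            continue
        res = fisher_enrich(genes, universe, collection, p_adj_threshold)
        res.insert(0, "direction", direction)
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["direction", "set", "overlap", "set_size", "odds_ratio", "p", "p_adj", "kept"]
        )
    return pd.concat(frames, ignore_index=True)
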