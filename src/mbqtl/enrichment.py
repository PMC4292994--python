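"""Pathway-level enrichment of host gene-microbiome association signal.

Two complementary procedures:

* a rank-product test — a pathway's gene-taxon association tests are ranked
  among all tests, the pathway statistic is the mean log-rank (the log of
  the geometric-mean rank, strictly monotone in the classical rank product
  but overflow-free and normalized for pathway size), and its significance
  is judged empirically against size-matched gene sets drawn from the null
  (non-disease-associated) variant pool;
* a hypergeometric over-representation test of a hit-gene list against
  functional categories, BH-corrected across categories.

Redundant pathway definitions (>75% overlap) are binned beforehand, keeping
the largest constituent as representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "bin_pathways",
    "rank_test_table",
    "rank_product_stat",
    "null_rank_products",
    "rank_product_screen",
    "hypergeom_enrich",
    "RankProductResult",
]


def bin_pathways(sets: GeneSetCollection, overlap: float = 0.75
                 ) -> GeneSetCollection:
    """Greedy largest-first binning of redundant pathways.

    Pathway B is absorbed into representative A when
    |A & B| / min(|A|, |B|) strictly exceeds ``overlap``; ties in size are
    broken by set id, so the result is deterministic.
    """
    order = sorted(sets.sets, key=lambda k: (-len(sets.sets[k]), k))
    reps: list[str] = []
    merged: dict[str, list] = {}
    for name in order:
        genes = sets.sets[name]
        target = None
        for rep in reps:
            inter = len(genes & sets.sets[rep])
            if inter / min(len(genes), len(sets.sets[rep])) > overlap:
                target = rep
                break
        if target is None:
            reps.append(name)
            merged[name] = [name]
        else:
            merged[target].append(name)
    out = {rep: set(sets.sets[rep]) for rep in reps}
    for rep, absorbed in merged.items():
        if len(absorbed) > 1:
            logger.info("bin_pathways: %s represents %s", rep, absorbed[1:])
    return GeneSetCollection(out, source=sets.source,
                             descriptions={r: sets.descriptions.get(r, "")
                                           for r in reps})


def rank_test_table(pvalues: pd.DataFrame) -> pd.DataFrame:
    """Rank all gene-taxon tests ascending by p (ties -> average rank).

    ``pvalues`` is a long frame with columns gene, p (one row per
    gene-taxon test).  Adds a ``rank`` column; missing p-values are dropped.
    """
    out = pvalues.dropna(subset=["p"]).copy()
    out["rank"] = stats.rankdata(out["p"].to_numpy(), method="average")
    return out


def rank_product_stat(pathway_genes, ranked: pd.DataFrame,
                      per_gene: str = "all") -> float:
    """Mean log-rank over the pathway genes' tests (smaller = more enriched).

    ``per_gene='all'`` pools every taxon test of every pathway gene;
    ``per_gene='best'`` uses only each gene's best-ranked test.
    """
    genes = set(pathway_genes)
    sub = ranked.loc[ranked["gene"].isin(genes)]
    if sub.empty:
        raise ValueError("pathway has no tested genes")
    if per_gene == "best":
        ranks = sub.groupby("gene")["rank"].min().to_numpy()
    elif per_gene == "all":
        ranks = sub["rank"].to_numpy()
    else:
        raise ValueError(f"unknown per_gene mode {per_gene!r}")
    return float(np.mean(np.log(ranks)))


def _gene_rank_summaries(ranked: pd.DataFrame, per_gene: str):
    """Per-gene (sum of log ranks, test count) for fast null draws."""
    if per_gene == "best":
        best = np.log(ranked.groupby("gene")["rank"].min())
        return best.to_numpy(), np.ones(len(best)), list(best.index)
    grp = ranked.assign(logrank=np.log(ranked["rank"])).groupby("gene")
    sums = grp["logrank"].sum()
    counts = grp["logrank"].size().astype(float)
    return sums.to_numpy(), counts.to_numpy(), list(sums.index)


def null_rank_products(size: int, null_pool, ranked: pd.DataFrame,
                       n_null: int = 100_000, seed: int = 0,
                       per_gene: str = "all") -> np.ndarray:
    """Null distribution of the statistic for random size-matched gene sets.

    Draws ``n_null`` sets of ``size`` genes without replacement from the
    null pool (genes mapped from non-disease-associated variants) and
    computes the mean log-rank of each.
    """
    sums, counts, genes = _gene_rank_summaries(
        ranked.loc[ranked["gene"].isin(set(null_pool))], per_gene)
    if len(genes) < size:
        raise ValueError(f"null pool has {len(genes)} tested genes < "
                         f"pathway size {size}")
    rng = np.random.default_rng(seed)
    out = np.empty(n_null)
    n_genes = len(genes)
    for i in range(n_null):
        idx = rng.choice(n_genes, size=size, replace=False)
        out[i] = sums[idx].sum() / counts[idx].sum()
    return out


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Left-tail empirical p with add-one smoothing (never exactly 0)."""
    return float((1 + (null <= observed).sum()) / (1 + null.size))


@dataclass(frozen=True)
class RankProductResult:
    pathway_id: str
    size: int
    statistic: float
    null_mean: float
    null_sd: float
    p: float


def rank_product_screen(sets: GeneSetCollection, pvalues: pd.DataFrame,
                        null_pool, n_null: int = 100_000, seed: int = 0,
                        per_gene: str = "all") -> pd.DataFrame:
    """Rank-product enrichment of every pathway against size-matched nulls.

    Pathways with no tested genes are skipped (logged).  Returns a frame
    with pathway, size (tested genes), statistic, p and BH q.
    """
    ranked = rank_test_table(pvalues)
    tested_genes = set(ranked["gene"])
    rows = []
    rng = np.random.default_rng(seed)
    for name in sorted(sets.sets):
        genes = sets.sets[name] & tested_genes
        if not genes:
            logger.info("rank_product_screen: skipping %s (no tested genes)",
                        name)
            continue
        obs = rank_product_stat(genes, ranked, per_gene=per_gene)
        null = null_rank_products(len(genes), null_pool, ranked,
                                  n_null=n_null,
                                  seed=int(rng.integers(2**31)),
                                  per_gene=per_gene)
        rows.append(RankProductResult(name, len(genes), obs,
                                      float(null.mean()), float(null.std()),
                                      empirical_p(obs, null)))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if not out.empty:
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def hypergeom_enrich(hits, categories: GeneSetCollection, universe
                     ) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of hits per category.

    ``hits`` and every category are intersected with the universe before
    testing; q is BH across categories.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    rows = []
    for name in sorted(categories.sets):
        cat = categories.sets[name] & universe
        k = len(hits & cat)
        p = stats.hypergeom.sf(k - 1, len(universe), len(cat), len(hits))
        rows.append({"category": name, "category_size": len(cat),
                     "n_hits": len(hits), "overlap": k, "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
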