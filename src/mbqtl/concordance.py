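"""Cross-cohort reproducibility of SNP-taxon effect directionality.

Effect magnitudes are not comparable between cohorts (a coefficient scales
with the taxon's mean abundance), so reproducibility is judged on signs
alone: for each SNP and each cohort pair, the SNP-taxon coefficient signs
in one cohort are cross-tabulated against the signs in the other over the
taxa that reached nominal significance (p < 0.05) in at least one of the
two cohorts, and summarized by the Matthews correlation coefficient (phi).
A per-SNP significance test (Fisher exact by default, sign-permutation as
an alternative) is corrected across genes by Benjamini-Hochberg at
FDR 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "SignTable",
    "select_pairs",
    "sign_table",
    "mcc",
    "mcc_test",
    "concordance_screen",
]


@dataclass(frozen=True)
class SignTable:
    """2x2 sign-agreement counts: a=(+,+), b=(+,-), c=(-,+), d=(-,-)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("sign counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self):
        t = self
        return (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)

    def transpose(self) -> "SignTable":
        return SignTable(self.a, self.c, self.b, self.d)


def select_pairs(res_a: pd.DataFrame, res_b: pd.DataFrame,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Merge two cohorts' results and keep pairs nominally significant in
    at least one cohort (strict p < alpha).

    Input frames need columns snp_id, taxon_id, beta, p.  Pairs with a beta
    of exactly zero in either cohort are dropped (sign undefined) and
    logged.  Returns columns snp_id, taxon_id, sign_a, sign_b.
    """
    cols = ["snp_id", "taxon_id", "beta", "p"]
    merged = res_a[cols].merge(res_b[cols], on=["snp_id", "taxon_id"],
                               suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["beta_a", "beta_b", "p_a", "p_b"])
    keep = (merged["p_a"] < alpha) | (merged["p_b"] < alpha)
    merged = merged.loc[keep]
    zero = (merged["beta_a"] == 0) | (merged["beta_b"] == 0)
    if zero.any():
        logger.info("select_pairs: dropping %d pairs with zero coefficient",
                    int(zero.sum()))
        merged = merged.loc[~zero]
    out = merged[["snp_id", "taxon_id"]].copy()
    out["sign_a"] = np.sign(merged["beta_a"]).astype(int)
    out["sign_b"] = np.sign(merged["beta_b"]).astype(int)
    return out.reset_index(drop=True)


def sign_table(signs_a, signs_b) -> SignTable:
    sa = np.asarray(signs_a)
    sb = np.asarray(signs_b)
    if sa.shape != sb.shape:
        raise ValueError("sign vectors must have equal length")
    return SignTable(
        int(((sa > 0) & (sb > 0)).sum()),
        int(((sa > 0) & (sb < 0)).sum()),
        int(((sa < 0) & (sb > 0)).sum()),
        int(((sa < 0) & (sb < 0)).sum()),
    )


def mcc(t: SignTable) -> float:
    """Matthews correlation (phi): (ad - bc) / sqrt of margin products.

    Returns NaN when any margin is zero (the coefficient is undefined and
    the SNP should be skipped).
    """
    m = t.margins()
    if 0 in m:
        return float("nan")
    num = t.a * t.d - t.b * t.c
    den = np.sqrt(np.prod(np.asarray(m, dtype=float)))
    return float(num / den)


def mcc_test(t_or_signs, signs_b=None, method: str = "fisher",
             n_perm: int = 999, seed: int = 0,
             tie_rule: str = "conservative") -> float:
    """Two-sided p-value for sign concordance of a 2x2 table.

    ``method='fisher'`` applies the Fisher exact test to the table;
    ``method='permutation'`` permutes the second cohort's sign labels and
    compares |MCC| (requires the raw sign vectors, not just the table).

    The MCC lattice on a small table is coarse, so permutation ties are
    common.  ``tie_rule='conservative'`` (default) counts ties fully and
    is guaranteed valid but superuniform under the null;
    ``tie_rule='midp'`` counts half of each tie, giving approximately
    uniform null p-values for calibration studies.
    """
    if method == "fisher":
        t = t_or_signs if isinstance(t_or_signs, SignTable) \
            else sign_table(t_or_signs, signs_b)
        if 0 in t.margins():
            return float("nan")
        _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]],
                                  alternative="two-sided")
        return float(p)
    if method == "permutation":
        if signs_b is None:
            raise ValueError("permutation test needs both sign vectors")
        sa = np.asarray(t_or_signs)
        sb = np.asarray(signs_b)
        obs = mcc(sign_table(sa, sb))
        if not np.isfinite(obs):
            return float("nan")
        if tie_rule not in ("conservative", "midp"):
            raise ValueError(f"unknown tie_rule {tie_rule!r}")
        rng = np.random.default_rng(seed)
        greater = ties = 0
        for _ in range(n_perm):
            perm = rng.permutation(sb)
            m = mcc(sign_table(sa, perm))
            if not np.isfinite(m):
                ties += 1  # degenerate permutation: counted against us
            elif abs(m) > abs(obs) + 1e-12:
                greater += 1
            elif abs(m) >= abs(obs) - 1e-12:
                ties += 1
        if tie_rule == "midp":
            return (0.5 + greater + 0.5 * ties) / (1 + n_perm)
        return (1 + greater + ties) / (1 + n_perm)
    raise ValueError(f"unknown method {method!r}")


def _gene_of(snp, gene_map):
    if gene_map is None:
        return snp
    return gene_map.get(snp, snp)


def concordance_screen(results_by_cohort: dict, alpha: float = 0.05,
                       fdr: float = 0.25, min_pairs: int = 3,
                       gene_map: dict | None = None,
                       gene_rule: str = "most_pairs",
                       method: str = "fisher", n_perm: int = 999,
                       seed: int = 0) -> pd.DataFrame:
    """Run the sign-concordance screen over every cohort pair.

    For each SNP and cohort pair: select nominally significant pairs, build
    the sign table, compute MCC and its p-value; skip SNPs with fewer than
    ``min_pairs`` included taxa or a degenerate margin.  One test per gene
    is kept (``gene_rule``: the SNP with most included pairs, or 'best_p'),
    then BH-corrected across genes within each cohort pair; ``significant``
    marks q < fdr.  A SNP significant in at least one pair counts as
    conserved across cohorts.
    """
    if len(results_by_cohort) < 2:
        raise ValueError("concordance screen needs at least 2 cohorts")
    cohorts = sorted(results_by_cohort)
    rows = []
    for i, ca in enumerate(cohorts):
        for cb in cohorts[i + 1:]:
            pairs = select_pairs(results_by_cohort[ca],
                                 results_by_cohort[cb], alpha=alpha)
            for snp, grp in pairs.groupby("snp_id", sort=True):
                if len(grp) < min_pairs:
                    continue
                t = sign_table(grp["sign_a"], grp["sign_b"])
                m = mcc(t)
                if not np.isfinite(m):
                    logger.info("concordance: skipping %s (%s vs %s): "
                                "degenerate margin", snp, ca, cb)
                    continue
                if method == "permutation":
                    p = mcc_test(grp["sign_a"].to_numpy(),
                                 grp["sign_b"].to_numpy(),
                                 method="permutation", n_perm=n_perm,
                                 seed=seed)
                else:
                    p = mcc_test(t, method="fisher")
                rows.append({"gene": _gene_of(snp, gene_map), "snp_id": snp,
                             "cohort_pair": f"{ca}|{cb}", "mcc": m, "p": p,
                             "n_pairs": int(len(grp))})
    res = pd.DataFrame(rows, columns=["gene", "snp_id", "cohort_pair",
                                      "mcc", "p", "n_pairs"])
    if res.empty:
        res["q"] = []
        res["significant"] = []
        return res
    # one MCC test per gene within each cohort pair
    keep_idx = []
    for (_, _), grp in res.groupby(["cohort_pair", "gene"], sort=True):
        if gene_rule == "best_p":
            keep_idx.append(grp["p"].idxmin())
        else:
            keep_idx.append(grp.sort_values(["n_pairs", "p"],
                                            ascending=[False, True]).index[0])
    res = res.loc[sorted(keep_idx)].reset_index(drop=True)
    res["q"] = np.nan
    for pair, grp in res.groupby("cohort_pair"):
        res.loc[grp.index, "q"] = bh_fdr(grp["p"].to_numpy())
    res["significant"] = res["q"] < fdr
    return res


def conserved_genes(screen: pd.DataFrame) -> list:
    """Genes significant in at least one cohort pair."""
    if screen.empty:
        return []
    return sorted(screen.loc[screen["significant"], "gene"].unique())
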