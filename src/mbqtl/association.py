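"""Covariate-adjusted SNP-taxon association tests and the power analysis.

The central operation regresses a taxon's arcsine-sqrt-transformed relative
abundance on a SNP's risk-allele dosage while adjusting for the ten clinical
covariates (dummy-coded against declared reference levels), cohort
membership and the first three genotype principal components.  Taxa below
the prevalence threshold fall back to presence/absence logistic regression.
A multi-variant locus (the NOD2 prototype) is tested through the simple sum
of risk-allele dosages across its variants.

The linear engine is a direct least-squares solve (QR), cheap enough to run
the full SNP x taxon x cohort screen in seconds; it is held to statsmodels
OLS in the test suite.  Logistic tests use statsmodels' ML logit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io import GenotypeTable, MetadataTable, CATEGORICAL_LEVELS
from .preprocess import outlier_mask

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "build_design",
    "linear_test",
    "logistic_test",
    "aggregate_dosage",
    "axis_association",
    "association_screen",
    "required_sample_size",
    "linear_model_power",
    "bh_fdr",
    "bonferroni_threshold",
    "PowerSpec",
]

CONTINUOUS_COVARIATES = ("age", "years_since_diagnosis")
DOSAGE_COLUMN = "dosage"


@dataclass(frozen=True)
class AssociationResult:
    """One SNP-taxon (or locus-axis) test: slope, SE, two-sided p, n used."""

    snp_id: str
    taxon_id: str
    beta: float
    se: float
    p: float
    n_used: int
    family: str
    cohort_id: str = ""
    flag: str = ""

    def __post_init__(self):
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def build_design(meta: MetadataTable, pcs: pd.DataFrame | None = None,
                 dosage: pd.Series | None = None) -> pd.DataFrame:
    """Assemble the covariate design matrix with deterministic column order.

    Columns: intercept, dosage (if given), dummy columns for each
    categorical covariate against its declared reference level, cohort
    dummies, continuous covariates, genotype PCs.  Constant (aliased)
    columns are dropped and logged; the returned matrix has full column
    rank.
    """
    df = meta.data
    cols = {"const": pd.Series(1.0, index=df.index)}
    if dosage is not None:
        cols[DOSAGE_COLUMN] = pd.Series(dosage, index=df.index).astype(float)
    for cov, levels in CATEGORICAL_LEVELS.items():
        observed = set(df[cov].dropna())
        unseen = observed - set(levels)
        if unseen:
            raise ValueError(f"unseen level(s) {sorted(unseen)} in {cov!r}")
        for level in levels[1:]:
            cols[f"{cov}[{level}]"] = (df[cov] == level).astype(float)
    cohorts = sorted(df["cohort"].unique())
    for c in cohorts[1:]:
        cols[f"cohort[{c}]"] = (df["cohort"] == c).astype(float)
    for cov in CONTINUOUS_COVARIATES:
        cols[cov] = pd.to_numeric(df[cov]).astype(float)
    if pcs is not None:
        for c in pcs.columns:
            cols[str(c)] = pcs[c].reindex(df.index).astype(float)
    X = pd.DataFrame(cols, index=df.index)
    constant = [c for c in X.columns
                if c != "const" and X[c].nunique(dropna=False) <= 1]
    if constant:
        logger.info("build_design: dropping constant columns %s", constant)
        X = X.drop(columns=constant)
    # drop exactly collinear columns (keep earliest) to guarantee full rank
    arr = X.to_numpy(dtype=float)
    _, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    aliased = [X.columns[i] for i in range(arr.shape[1]) if diag[i] <= tol]
    if aliased:
        logger.info("build_design: dropping aliased columns %s", aliased)
        X = X.drop(columns=aliased)
    return X


def _ols(y: np.ndarray, X: np.ndarray):
    """Least-squares fit returning (beta_hat, se, df_resid)."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - rank
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    return beta, se, df


def linear_test(y, X: pd.DataFrame, term: str = DOSAGE_COLUMN,
                snp_id: str = "", taxon_id: str = "", cohort_id: str = "",
                apply_outlier_mask: bool = False) -> AssociationResult:
    """OLS of (transformed) abundance on the design; t-test on ``term``.

    ``y`` should already be outlier-masked (or pass
    ``apply_outlier_mask=True`` to apply the 3xIQR rule here); rows with
    missing values are dropped and the model refitted on the reduced set,
    with ``n_used`` recorded.
    """
    yv = pd.Series(y, index=X.index).astype(float)
    keep = yv.notna() & X.notna().all(axis=1)
    if apply_outlier_mask:
        keep &= pd.Series(outlier_mask(yv.to_numpy()), index=X.index)
    Xk = X.loc[keep]
    # re-drop columns made constant by row exclusion (e.g. a rare level)
    drop = [c for c in Xk.columns
            if c not in ("const", term) and Xk[c].nunique() <= 1]
    Xk = Xk.drop(columns=drop)
    n, k = Xk.shape
    if term not in Xk.columns or Xk[term].nunique() <= 1:
        return AssociationResult(snp_id, taxon_id, np.nan, np.nan, np.nan,
                                 int(n), "linear", cohort_id,
                                 flag="constant_dosage")
    if n <= k + 2:
        return AssociationResult(snp_id, taxon_id, np.nan, np.nan, np.nan,
                                 int(n), "linear", cohort_id,
                                 flag="insufficient_n")
    beta, se, df = _ols(yv.loc[keep].to_numpy(), Xk.to_numpy(dtype=float))
    j = list(Xk.columns).index(term)
    if se[j] == 0:
        p = 0.0 if beta[j] != 0 else 1.0
    else:
        p = 2.0 * stats.t.sf(abs(beta[j] / se[j]), df)
    return AssociationResult(snp_id, taxon_id, float(beta[j]), float(se[j]),
                             float(p), int(n), "linear", cohort_id)


def logistic_test(presence, X: pd.DataFrame, term: str = DOSAGE_COLUMN,
                  snp_id: str = "", taxon_id: str = "", cohort_id: str = ""
                  ) -> AssociationResult:
    """ML logistic regression of presence/absence; Wald p for ``term``.

    Complete separation or non-convergence is flagged and the p-value set
    missing rather than reported.
    """
    yv = pd.Series(presence, index=X.index).astype(float)
    keep = yv.notna() & X.notna().all(axis=1)
    Xk = X.loc[keep]
    drop = [c for c in Xk.columns
            if c not in ("const", term) and Xk[c].nunique() <= 1]
    Xk = Xk.drop(columns=drop)
    yk = yv.loc[keep]
    n = len(yk)
    if yk.nunique() < 2:
        return AssociationResult(snp_id, taxon_id, np.nan, np.nan, np.nan,
                                 n, "logistic", cohort_id, flag="one_class")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(yk, Xk.astype(float)).fit(disp=0, maxiter=100)
        converged = bool(fit.mle_retvals.get("converged", False))
        se = float(fit.bse[term])
        if not converged or not np.isfinite(se) or se > 1e3:
            raise PerfectSeparationError("separation suspected")
        return AssociationResult(snp_id, taxon_id, float(fit.params[term]),
                                 se, float(fit.pvalues[term]), n,
                                 "logistic", cohort_id)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return AssociationResult(snp_id, taxon_id, np.nan, np.nan, np.nan,
                                 n, "logistic", cohort_id, flag="separation")


def aggregate_dosage(g: GenotypeTable, variant_ids) -> pd.Series:
    """Summed risk-allele dosage across a locus's variants (uncapped).

    Missing per-variant dosages are imputed to the per-SNP mean; variants
    absent from the table are an error only if none are present.
    """
    present = [v for v in variant_ids if v in g.snp_ids]
    if not present:
        raise KeyError("no aggregate-locus variant present in genotype table")
    missing = sorted(set(variant_ids) - set(present))
    if missing:
        logger.warning("aggregate_dosage: variants missing from table: %s",
                       missing)
    block = g.data[present].astype(float)
    block = block.fillna(block.mean(axis=0))
    return block.sum(axis=1)


def axis_association(coords: pd.DataFrame, dosage: pd.Series,
                     X: pd.DataFrame, locus_id: str = "locus",
                     cohort_id: str = "") -> pd.DataFrame:
    """Linear test of dosage against each ordination axis, BH across axes."""
    Xd = X.copy()
    Xd[DOSAGE_COLUMN] = pd.Series(dosage, index=X.index).astype(float)
    rows = []
    for axis in coords.columns:
        res = linear_test(coords[axis], Xd, snp_id=locus_id,
                          taxon_id=str(axis), cohort_id=cohort_id)
        rows.append({"axis": axis, "beta": res.beta, "se": res.se,
                     "p": res.p, "n_used": res.n_used})
    out = pd.DataFrame(rows).set_index("axis")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def association_screen(genotypes: GenotypeTable, transformed: pd.DataFrame,
                       X_base: pd.DataFrame, snp_ids=None, feature_ids=None,
                       cohort_id: str = "", family: str = "linear",
                       apply_outlier_mask: bool = True) -> pd.DataFrame:
    """All SNP x feature linear tests for one cohort.

    ``transformed`` holds the (already transformed) feature values; the
    3xIQR outlier rule is applied per feature by default, and the model is
    refitted on the reduced subject set.  Returns a long DataFrame with one
    row per (snp, feature).
    """
    snp_ids = list(snp_ids if snp_ids is not None else genotypes.snp_ids)
    feature_ids = list(feature_ids if feature_ids is not None
                       else transformed.columns)
    dosages = genotypes.data[snp_ids].astype(float)
    dosages = dosages.fillna(dosages.mean(axis=0))
    rows = []
    for feat in feature_ids:
        y = transformed[feat]
        mask = (pd.Series(outlier_mask(y.to_numpy()), index=y.index)
                if apply_outlier_mask else y.notna())
        for snp in snp_ids:
            Xd = X_base.copy()
            Xd[DOSAGE_COLUMN] = dosages[snp]
            res = linear_test(y.where(mask), Xd, snp_id=snp, taxon_id=feat,
                              cohort_id=cohort_id)
            rows.append(res)
    out = pd.DataFrame([r.__dict__ for r in rows])
    return out


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerSpec:
    """Linear-model F-test power parameters (Cohen's f2 formulation)."""

    f2: float
    u: int
    alpha: float
    power: float

    def __post_init__(self):
        if self.f2 <= 0:
            raise ValueError("f2 must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.u < 1:
            raise ValueError("u must be a positive integer")


def linear_model_power(n: float, spec: PowerSpec) -> float:
    """Power of the overall F test at total sample size n.

    Noncentral F with df1 = u, df2 = n - u - 1 and noncentrality
    lambda = f2 * n (the R 'pwr' convention with n = u + v + 1).
    """
    v = n - spec.u - 1
    if v <= 0:
        return 0.0
    lam = spec.f2 * (spec.u + v + 1)
    crit = stats.f.ppf(1 - spec.alpha, spec.u, v)
    return float(stats.ncf.sf(crit, spec.u, v, lam))


def required_sample_size(spec: PowerSpec) -> int:
    """Smallest integer n = u + v + 1 reaching the target power.

    Root-finds the continuous noncentral-F power curve in v, then takes the
    ceiling and adjusts to the exact smallest integer.
    """
    f = lambda n: linear_model_power(n, spec) - spec.power
    lo = spec.u + 2
    if f(lo) >= 0:
        return lo
    hi = lo * 2
    while f(hi) < 0:
        hi *= 2
        if hi > 1e9:
            raise ValueError("requested power unattainable")
    n_cont = optimize.brentq(f, lo, hi, xtol=1e-6)
    n = int(math.ceil(n_cont))
    while linear_model_power(n, spec) < spec.power:
        n += 1
    while n - 1 > lo and linear_model_power(n - 1, spec) >= spec.power:
        n -= 1
    return n


def monte_carlo_power(n: int, spec: PowerSpec, n_reps: int = 500,
                      seed: int = 0) -> float:
    """Monte-Carlo check of the F-test power at sample size n.

    Simulates a design of u standard-normal predictors with the signal in
    the first column rescaled so the sample noncentrality is exactly
    f2 * n in every replicate, then counts overall-F rejections at level
    alpha.
    """
    rng = np.random.default_rng(seed)
    b = math.sqrt(spec.f2)
    hits = 0
    for _ in range(n_reps):
        X = rng.standard_normal((n, spec.u))
        x1 = X[:, 0] - X[:, 0].mean()
        X[:, 0] = x1 * math.sqrt(n / (x1 @ x1))
        y = b * X[:, 0] + rng.standard_normal(n)
        Xc = np.column_stack([np.ones(n), X])
        beta, _, _, _ = np.linalg.lstsq(Xc, y, rcond=None)
        resid = y - Xc @ beta
        rss = resid @ resid
        tss = ((y - y.mean()) ** 2).sum()
        fstat = ((tss - rss) / spec.u) / (rss / (n - spec.u - 1))
        p = stats.f.sf(fstat, spec.u, n - spec.u - 1)
        hits += p < spec.alpha
    return hits / n_reps


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; missing p propagate as missing."""
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    if ((arr[ok] < 0) | (arr[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        _, q, _, _ = multipletests(arr[ok], method="fdr_bh")
        out[ok] = q
    return out


def bonferroni_threshold(n_snps: int = 163, n_taxa: int = 22,
                         alpha: float = 0.05):
    """Bookkeeping for the full-screen Bonferroni bound.

    Returns (number of tests, per-test significance threshold); the study
    design's 163 loci x 22 dominant taxa gives 3,586 tests and a threshold
    of 1.39e-5.
    """
    n_tests = int(n_snps) * int(n_taxa)
    return n_tests, alpha / n_tests
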