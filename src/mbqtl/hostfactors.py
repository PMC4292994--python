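"""Non-genetic host-factor analysis: covariate clustering, the host-factor
to taxon association network, and the microbial dysbiosis index (MDI).

Clinical covariates are often redundant (e.g. diagnosis and disease
location); their shared information is quantified by the max-symmetrized
uncertainty coefficient and redundant groups are found by complete-linkage
clustering, which guarantees every within-cluster pair shares at least the
threshold fraction of information.  Host factors (including an aggregate
risk-locus dosage such as NOD2) are then regressed jointly against each
taxon; the significant edges form a factor-taxon network whose edge weight
is |coefficient| / mean taxon abundance, making effects comparable across
taxa of very different abundance.

The MDI is the log-ratio of summed disease-associated to summed
health-associated taxon abundances; its association with recent antibiotic
use is tested controlling for the aggregate locus dosage.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import complete, fcluster
from scipy.spatial.distance import squareform

from .association import DOSAGE_COLUMN, bh_fdr, linear_test
from .io import MetadataTable, TaxaTable, CATEGORICAL_LEVELS
from .preprocess import outlier_mask, transform_arcsine_sqrt

logger = logging.getLogger(__name__)

__all__ = [
    "uncertainty_coefficient",
    "CovariateClustering",
    "cluster_covariates",
    "NetworkEdge",
    "host_network",
    "MdiSpec",
    "load_default_mdi_spec",
    "mdi_score",
    "mdi_antibiotics_test",
]


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def discretize(x, bins: int = 4) -> np.ndarray:
    """Equal-frequency binning of a continuous covariate."""
    s = pd.Series(x)
    return pd.qcut(s, q=bins, labels=False, duplicates="drop").to_numpy()


def uncertainty_coefficient(x, y, symmetrize: str = "max") -> float:
    """Theil's uncertainty coefficient U(x|y), max-symmetrized by default.

    U(x|y) = (H(x) - H(x|y)) / H(x) is the fraction of x's entropy explained
    by y (natural log; the base cancels).  A constant variable carries no
    information: U is defined as 0 and logged.
    """
    xa = pd.Series(x).astype(str).to_numpy()
    ya = pd.Series(y).astype(str).to_numpy()
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    tab = pd.crosstab(pd.Series(xa), pd.Series(ya)).to_numpy(dtype=float)
    hx = _entropy(tab.sum(axis=1))
    hy = _entropy(tab.sum(axis=0))
    hxy = _entropy(tab.ravel())
    mi = hx + hy - hxy

    def u(h):
        if h == 0:
            logger.info("uncertainty_coefficient: constant variable, U := 0")
            return 0.0
        return mi / h

    if symmetrize == "max":
        return float(max(u(hx), u(hy)))
    if symmetrize == "none":
        return float(u(hx))
    raise ValueError(f"unknown symmetrize mode {symmetrize!r}")


@dataclass
class CovariateClustering:
    """Partition of covariates with the pairwise max-U matrix behind it."""

    assignments: pd.Series
    max_uncertainty: pd.DataFrame
    height: float

    def clusters(self) -> dict:
        out = {}
        for cov, cid in self.assignments.items():
            out.setdefault(int(cid), []).append(cov)
        return out


def cluster_covariates(meta: MetadataTable, threshold: float = 0.5,
                       covariates=None, bins: int = 4
                       ) -> CovariateClustering:
    """Complete-linkage clustering of covariates on distance 1 - maxU.

    Cutting the dendrogram at height 1 - threshold yields clusters in which
    every covariate shares at least ``threshold`` of its information with
    every other member (a complete-linkage guarantee).  Continuous
    covariates are discretized into equal-frequency bins first.
    """
    df = meta.data
    if covariates is None:
        covariates = [c for c in df.columns if c != "cohort"]
    if len(covariates) < 2:
        raise ValueError("need at least 2 covariates to cluster")
    coded = {}
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            coded[cov] = discretize(col, bins=bins)
        else:
            coded[cov] = col.astype(str).to_numpy()
    k = len(covariates)
    U = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            U[i, j] = U[j, i] = uncertainty_coefficient(
                coded[covariates[i]], coded[covariates[j]])
    dist = 1.0 - U
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = complete(squareform(dist, checks=False))
    labels = fcluster(Z, t=1.0 - threshold, criterion="distance")
    return CovariateClustering(
        pd.Series(labels, index=covariates, name="cluster"),
        pd.DataFrame(U, index=covariates, columns=covariates),
        1.0 - threshold,
    )


@dataclass(frozen=True)
class NetworkEdge:
    """One significant host-factor to taxon association."""

    factor: str
    taxon: str
    sign: int
    weight: float
    beta: float
    q: float

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("edge weight must be non-negative")


def _joint_factor_design(meta: MetadataTable,
                         extra: pd.DataFrame | None) -> pd.DataFrame:
    """Jointly coded host-factor design: dummies, continuous, extras."""
    df = meta.data
    cols = {"const": pd.Series(1.0, index=df.index)}
    for cov, levels in CATEGORICAL_LEVELS.items():
        for level in levels[1:]:
            cols[f"{cov}[{level}]"] = (df[cov] == level).astype(float)
    cohorts = sorted(df["cohort"].unique())
    for c in cohorts[1:]:
        cols[f"cohort[{c}]"] = (df["cohort"] == c).astype(float)
    for cov in ("age", "years_since_diagnosis"):
        cols[cov] = pd.to_numeric(df[cov]).astype(float)
    X = pd.DataFrame(cols, index=df.index)
    if extra is not None:
        for c in extra.columns:
            X[str(c)] = extra[c].reindex(df.index).astype(float)
    X = X.loc[:, [c for c in X.columns
                  if c == "const" or X[c].nunique(dropna=False) > 1]]
    arr = X.to_numpy(dtype=float)
    _, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    aliased = [X.columns[i] for i in range(arr.shape[1]) if diag[i] <= tol]
    if aliased:
        logger.info("host_network: dropping aliased factors %s", aliased)
        X = X.drop(columns=aliased)
    return X


def host_network(taxa: TaxaTable, meta: MetadataTable,
                 extra_factors: pd.DataFrame | None = None,
                 fdr: float = 0.05, min_per_taxon: int = 4,
                 apply_outlier_mask: bool = True) -> list:
    """Joint multiple regression of every taxon on all host factors.

    For each taxon, one multiple linear regression of the transformed
    relative abundance on the jointly coded factors gives per-factor
    p-values; BH FDR runs over all factor-taxon tests; edges with q < fdr
    are kept, and only taxa with at least ``min_per_taxon`` significant
    edges enter the network.  Edge weight = |beta| / mean relative
    abundance of the taxon.
    """
    X = _joint_factor_design(meta, extra_factors)
    rel = taxa.relative_abundance()
    factors = [c for c in X.columns if c != "const"]
    rows = []
    for taxon in rel.columns:
        y = transform_arcsine_sqrt(rel[taxon].to_numpy())
        y = pd.Series(y, index=rel.index)
        if apply_outlier_mask:
            y = y.where(pd.Series(outlier_mask(y.to_numpy()), index=y.index))
        mean_ab = float(rel[taxon].mean())
        for factor in factors:
            res = linear_test(y, X, term=factor, taxon_id=taxon)
            rows.append({"factor": factor, "taxon": taxon, "beta": res.beta,
                         "p": res.p, "mean_abundance": mean_ab})
    frame = pd.DataFrame(rows)
    frame["q"] = bh_fdr(frame["p"].to_numpy())
    sig = frame.loc[frame["q"] < fdr].copy()
    taxon_counts = sig["taxon"].value_counts()
    keep_taxa = set(taxon_counts[taxon_counts >= min_per_taxon].index)
    sig = sig.loc[sig["taxon"].isin(keep_taxa)]
    edges = [NetworkEdge(r.factor, r.taxon, int(np.sign(r.beta)),
                         abs(r.beta) / r.mean_abundance if r.mean_abundance
                         else np.inf, r.beta, r.q)
             for r in sig.itertuples()]
    return edges


def edges_to_frame(edges) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in edges],
                        columns=["factor", "taxon", "sign", "weight",
                                 "beta", "q"])


# ---------------------------------------------------------------------------
# microbial dysbiosis index
# ---------------------------------------------------------------------------


@dataclass
class MdiSpec:
    """Disease- and health-associated taxon sets defining the MDI."""

    disease_taxa: set
    health_taxa: set
    pseudocount: float | None = None

    def __post_init__(self):
        self.disease_taxa = set(self.disease_taxa)
        self.health_taxa = set(self.health_taxa)
        if not self.disease_taxa or not self.health_taxa:
            raise ValueError("MDI taxon sets must be non-empty")
        if self.disease_taxa & self.health_taxa:
            raise ValueError("MDI taxon sets must be disjoint")


def load_default_mdi_spec() -> MdiSpec:
    """MDI taxon lists from the package's editable config file."""
    ref = importlib.resources.files("mbqtl.data") / "mdi_taxa.yaml"
    cfg = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return MdiSpec(set(cfg["disease_taxa"]), set(cfg["health_taxa"]),
                   cfg.get("pseudocount"))


def _match_taxa(columns, wanted) -> list:
    """Match MDI taxon names against feature ids or lineage substrings."""
    cols = list(columns)
    out = []
    for w in wanted:
        if w in cols:
            out.append(w)
        else:
            out.extend(c for c in cols if w in str(c))
    return sorted(set(out))


def mdi_score(rel_abundance: pd.DataFrame, spec: MdiSpec,
              log: bool = True) -> pd.Series:
    """Per-subject MDI: log((sum disease + pc) / (sum health + pc)).

    Taxa absent from the table contribute zero abundance.  The pseudocount
    defaults to half the smallest nonzero relative abundance in the table;
    ``log=False`` returns the raw ratio instead of the log-ratio.
    """
    d_cols = _match_taxa(rel_abundance.columns, spec.disease_taxa)
    h_cols = _match_taxa(rel_abundance.columns, spec.health_taxa)
    # a family-level disease match outranks an order-level health match
    h_cols = [c for c in h_cols if c not in set(d_cols)]
    pc = spec.pseudocount
    if pc is None:
        nonzero = rel_abundance.to_numpy()
        nonzero = nonzero[nonzero > 0]
        pc = float(nonzero.min() / 2) if nonzero.size else 1e-6
    disease = rel_abundance[d_cols].sum(axis=1) if d_cols \
        else pd.Series(0.0, index=rel_abundance.index)
    health = rel_abundance[h_cols].sum(axis=1) if h_cols \
        else pd.Series(0.0, index=rel_abundance.index)
    ratio = (disease + pc) / (health + pc)
    return np.log(ratio) if log else ratio


def mdi_antibiotics_test(mdi: pd.Series, antibiotics, locus_dosage=None):
    """MDI ~ antibiotics + aggregate locus dosage; t-test on antibiotics.

    Returns (beta, p) for the antibiotics coefficient.  The locus dosage
    column controls for host-genetic dysbiosis; if constant it is dropped
    and the test reduces to a simple regression.
    """
    mdi = pd.Series(mdi).astype(float)
    if len(mdi) < 10:
        raise ValueError("MDI-antibiotics test needs at least 10 subjects")
    abx = pd.Series(antibiotics, index=mdi.index)
    if not pd.api.types.is_numeric_dtype(abx):
        abx = (abx.astype(str) == "yes").astype(float)
    if abx.nunique() < 2:
        raise ValueError("antibiotics flag is constant")
    X = pd.DataFrame({"const": 1.0, DOSAGE_COLUMN: abx}, index=mdi.index)
    if locus_dosage is not None:
        X["locus"] = pd.Series(locus_dosage, index=mdi.index).astype(float)
        if X["locus"].nunique() <= 1:
            logger.info("mdi_antibiotics_test: constant locus dosage dropped")
            X = X.drop(columns=["locus"])
    res = linear_test(mdi, X)
    return res.beta, res.p
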