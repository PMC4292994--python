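"""Beta-diversity distances, ordination and matrix correlation.

Thin, validated wrappers over scipy/scikit-bio: Bray-Curtis and
Jensen-Shannon distances on taxon profiles, Manhattan distance on dosage
matrices, unweighted and (normalized) weighted UniFrac against a feature
tree, classical PCoA, and the Mantel test used to correlate genome-wide
genetic distance with microbiome distance.

Every returned :class:`DistanceMatrix` is checked for symmetry and a zero
diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.distance import jensenshannon
import skbio
from skbio.diversity import beta_diversity
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import TaxaTable

__all__ = [
    "DistanceMatrix",
    "bray_curtis",
    "jensen_shannon",
    "manhattan",
    "unifrac",
    "pcoa",
    "mantel",
]


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    data: pd.DataFrame
    metric: str = ""

    def __post_init__(self):
        arr = self.data.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not (self.data.index == self.data.columns).all():
            raise ValueError("row and column labels must match")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (arr < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    def condensed(self) -> np.ndarray:
        return squareform(self.data.to_numpy(dtype=float), checks=False)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="subject")


def _wrap(matrix: np.ndarray, ids, metric: str) -> DistanceMatrix:
    matrix = np.asarray(matrix, dtype=float)
    matrix = (matrix + matrix.T) / 2.0
    np.fill_diagonal(matrix, 0.0)
    df = pd.DataFrame(matrix, index=ids, columns=ids)
    return DistanceMatrix(df, metric)


def _rel_abundance(t: TaxaTable) -> np.ndarray:
    rel = t.relative_abundance().to_numpy(dtype=float)
    return rel


def bray_curtis(t: TaxaTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances."""
    rel = _rel_abundance(t)
    return _wrap(squareform(pdist(rel, metric="braycurtis")),
                 t.subject_ids, "braycurtis")


def jensen_shannon(t: TaxaTable) -> DistanceMatrix:
    """Jensen-Shannon distance (sqrt of base-2 JS divergence) on profiles."""
    rel = _rel_abundance(t)
    return _wrap(squareform(pdist(rel, metric=lambda u, v:
                                  jensenshannon(u, v, base=2))),
                 t.subject_ids, "jensenshannon")


def manhattan(m) -> DistanceMatrix:
    """Manhattan (city-block) distance between subject rows of a matrix."""
    if isinstance(m, pd.DataFrame):
        ids, arr = m.index, m.to_numpy(dtype=float)
    else:
        arr = np.asarray(m, dtype=float)
        ids = pd.RangeIndex(arr.shape[0])
    if not np.isfinite(arr).all():
        raise ValueError("Manhattan distance requires finite values "
                         "(impute missing dosages first)")
    return _wrap(squareform(pdist(arr, metric="cityblock")), ids, "manhattan")


def unifrac(t: TaxaTable, tree: "skbio.TreeNode", weighted: bool = False
            ) -> DistanceMatrix:
    """UniFrac distance between samples over a feature tree.

    Unweighted UniFrac is the fraction of branch length unique to one
    sample's taxa among branch length covered by either; weighted UniFrac is
    the branch-length-weighted abundance-difference sum, normalized to
    [0, 1].  All table features must be tree tips.
    """
    tip_names = {tip.name for tip in tree.tips()}
    missing = [f for f in t.feature_ids if f not in tip_names]
    if missing:
        raise ValueError(f"features absent from tree: {missing[:10]}")
    if len(tree.children) > 2:
        # root polytomy (e.g. a star tree): binarize with zero-length
        # internal branches, which leave all UniFrac values unchanged
        tree = tree.copy()
        while len(tree.children) > 2:
            a = tree.children[-1]
            b = tree.children[-2]
            tree.remove(a)
            tree.remove(b)
            joint = tree.__class__(length=0.0, children=[a, b])
            tree.append(joint)
    counts = t.data.to_numpy(dtype=float)
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": True} if weighted else {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dm = beta_diversity(metric, counts, ids=list(t.subject_ids),
                            taxa=list(t.feature_ids), tree=tree,
                            validate=True, **kwargs)
    return _wrap(dm.data, t.subject_ids,
                 "weighted_unifrac" if weighted else "unweighted_unifrac")


def pcoa(d: DistanceMatrix, k: int = 3):
    """Classical metric scaling of a distance matrix.

    Returns (coordinates DataFrame n x k_eff, eigenvalues array).  Axes are
    ordered by decreasing eigenvalue and axes with non-positive eigenvalues
    are discarded; if fewer than ``k`` positive axes exist the result is
    truncated with a warning.
    """
    if d.data.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 subjects")
    sk_dm = skbio.DistanceMatrix(d.data.to_numpy(dtype=float),
                                 ids=list(d.subject_ids))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(sk_dm, method="eigh")
    eig = np.asarray(res.eigvals, dtype=float)
    pos = eig > max(eig.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive PCoA axes available "
                      f"(requested {k})", stacklevel=2)
    k_eff = min(k, n_pos)
    coords = res.samples.iloc[:, :k_eff].copy()
    coords.index = d.subject_ids
    coords.columns = [f"Axis{i+1}" for i in range(k_eff)]
    return coords, eig[:k_eff]


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0):
    """Two-sided Mantel test: Pearson r of upper triangles, permutation p.

    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), permuting the subject
    labels of the second matrix.
    """
    if list(d1.subject_ids) != list(d2.subject_ids):
        if set(d1.subject_ids) != set(d2.subject_ids):
            raise ValueError("Mantel requires matching subject sets")
        d2 = DistanceMatrix(d2.data.loc[d1.subject_ids, d1.subject_ids],
                            d2.metric)
    m1 = skbio.DistanceMatrix(d1.data.to_numpy(dtype=float),
                              ids=list(d1.subject_ids))
    m2 = skbio.DistanceMatrix(d2.data.to_numpy(dtype=float),
                              ids=list(d2.subject_ids))
    r, p, _ = _skbio_mantel(m1, m2, method="pearson", permutations=n_perm,
                            alternative="two-sided", seed=seed)
    return float(r), float(p)
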