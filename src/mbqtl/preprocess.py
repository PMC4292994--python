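"""Filtering and normalization rules applied before association testing.

Mirrors the preprocessing conventions of mucosal 16S genotype-association
studies: rarefaction to an even depth of 2,000 reads per sample, taxonomy
binning from phylum to genus, collapsing of redundant (r > 0.95) features,
MAF and call-rate SNP filters, arcsine-square-root transformation of
relative abundances, per-feature 3xIQR outlier exclusion, and the 75%
prevalence split between linear and presence/absence testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeTable, TaxaTable, parse_lineage, RANK_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "rarefy",
    "detection_probability",
    "bin_taxonomy",
    "collapse_correlated",
    "CollapseMap",
    "maf_filter",
    "callrate_filter",
    "transform_arcsine_sqrt",
    "inverse_arcsine_sqrt",
    "power_transform",
    "outlier_mask",
    "prevalence_split",
    "FeatureSetSplit",
    "genotype_pcs",
    "impute_dosages",
]

BINNING_RANKS = ("phylum", "class", "order", "family", "genus")


def rarefy(table: TaxaTable, depth: int = 2000, seed: int = 0) -> TaxaTable:
    """Subsample each sample without replacement to an even depth.

    Samples whose total is below ``depth`` are dropped (and logged), never
    upsampled.  Subsampling is multivariate-hypergeometric: reads are drawn
    without replacement from the sample's observed reads.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    counts = table.data.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("rarefaction requires integer counts")
        counts = np.round(counts).astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = list(table.subject_ids[~keep])
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped[:10])
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    for row, i in enumerate(np.flatnonzero(keep)):
        if totals[i] == depth:
            out[row] = counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(counts[i], depth)
    data = pd.DataFrame(out, index=table.subject_ids[keep],
                        columns=table.feature_ids)
    return table.with_data(data)


def detection_probability(depth: int, rel_abundance: float) -> float:
    """P(taxon observed at least once) = 1 - (1 - f)^depth.

    At depth 2,000 this gives >= 95% detection for relative abundance 0.15%,
    the design bound motivating the rarefaction depth.
    """
    if not 0 <= rel_abundance <= 1:
        raise ValueError("relative abundance must lie in [0, 1]")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return 1.0 - (1.0 - rel_abundance) ** depth


def bin_taxonomy(table: TaxaTable, ranks=BINNING_RANKS) -> TaxaTable:
    """Sum OTU counts upward into one feature per (rank, lineage prefix).

    Features lacking a name at some rank are binned under
    ``unclassified <parent>`` so that per-rank column sums conserve each
    sample's total.
    """
    parsed = {f: dict(parse_lineage(table.lineages[f]))
              for f in table.feature_ids}
    blocks, lineage_out, rank_out = [], {}, {}
    for rank in ranks:
        depth_i = RANK_NAMES.index(rank)
        groups = {}
        for f in table.feature_ids:
            names = []
            for r in RANK_NAMES[: depth_i + 1]:
                nm = parsed[f].get(r, "")
                names.append(nm if nm else f"unclassified {names[-1] if names else 'root'}")
            key = ";".join(names)
            groups.setdefault(key, []).append(f)
        cols = {}
        for key, members in groups.items():
            fid = f"{rank}:{key}"
            cols[fid] = table.data[members].sum(axis=1)
            lineage_out[fid] = key
            rank_out[fid] = rank
        blocks.append(pd.DataFrame(cols, index=table.subject_ids))
    data = pd.concat(blocks, axis=1)
    return TaxaTable(data, pd.Series(lineage_out), pd.Series(rank_out))


@dataclass
class CollapseMap:
    """cluster id -> member feature ids, with a representative per cluster."""

    members: dict
    representative: dict

    def __post_init__(self):
        seen = [f for mem in self.members.values() for f in mem]
        if len(seen) != len(set(seen)):
            raise ValueError("collapse clusters overlap")

    def to_frame(self) -> pd.DataFrame:
        rows = [(cid, self.representative[cid], m)
                for cid, mem in self.members.items() for m in mem]
        return pd.DataFrame(rows, columns=["cluster", "representative",
                                           "member"])


def collapse_correlated(table: TaxaTable, r_threshold: float = 0.95):
    """Greedily merge features correlated above ``r_threshold`` (strict >).

    Features are visited in order of decreasing mean abundance; each joins
    the first existing cluster whose representative correlates with it at
    Pearson r strictly above the threshold, else founds its own cluster.
    The output keeps the representative's abundances.  Zero-variance
    features stay singletons (their correlation is undefined).
    """
    if table.data.shape[0] < 3:
        raise ValueError("collapse requires at least 3 subjects")
    X = table.data.to_numpy(dtype=float)
    order = np.argsort(-X.mean(axis=0), kind="stable")
    feats = list(table.feature_ids)
    reps: list[int] = []
    members: dict[str, list] = {}
    representative: dict[str, str] = {}
    sd = X.std(axis=0)
    for j in order:
        joined = False
        if sd[j] > 0:
            for rep in reps:
                if sd[rep] == 0:
                    continue
                r = np.corrcoef(X[:, rep], X[:, j])[0, 1]
                if r > r_threshold:
                    cid = f"cluster_{feats[rep]}"
                    members[cid].append(feats[j])
                    joined = True
                    break
        if not joined:
            cid = f"cluster_{feats[j]}"
            reps.append(j)
            members[cid] = [feats[j]]
            representative[cid] = feats[j]
    rep_feats = [representative[cid] for cid in members]
    collapsed = table.with_data(table.data[rep_feats])
    return collapsed, CollapseMap(members, representative)


def _empirical_maf(dosage: np.ndarray) -> float:
    d = dosage[np.isfinite(dosage)]
    if d.size == 0:
        return np.nan
    freq = d.mean() / 2.0
    return min(freq, 1.0 - freq)


def maf_filter(g: GenotypeTable, floor: float = 0.1) -> GenotypeTable:
    """Keep SNPs with empirical minor allele frequency strictly above floor.

    MAF at or below the floor is excluded ("0.1 or below"), computed on
    non-missing dosages.
    """
    mafs = g.data.apply(lambda col: _empirical_maf(col.to_numpy(dtype=float)))
    keep = g.data.columns[(mafs > floor).fillna(False)]
    dropped = sorted(set(g.data.columns) - set(keep))
    if dropped:
        logger.info("maf_filter: dropped %d SNPs: %s", len(dropped),
                    dropped[:10])
    return GenotypeTable(g.data[keep], g.annotations.loc[keep])


def callrate_filter(g: GenotypeTable, min_callrate: float = 0.95
                    ) -> GenotypeTable:
    """Keep SNPs whose fraction of non-missing dosages is >= min_callrate."""
    callrate = g.data.notna().mean(axis=0)
    keep = g.data.columns[callrate >= min_callrate]
    dropped = sorted(set(g.data.columns) - set(keep))
    if dropped:
        logger.info("callrate_filter: dropped %d SNPs: %s", len(dropped),
                    dropped[:10])
    return GenotypeTable(g.data[keep], g.annotations.loc[keep])


def transform_arcsine_sqrt(x):
    """Variance-stabilizing asin(sqrt(x)) for proportions in [0, 1]."""
    arr = np.asarray(x, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("arcsine-sqrt transform requires values in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return out if np.ndim(x) else float(out)


def inverse_arcsine_sqrt(y):
    arr = np.asarray(y, dtype=float)
    out = np.sin(arr) ** 2
    return out if np.ndim(y) else float(out)


def power_transform(x) -> np.ndarray:
    """Yeo-Johnson power transform (lambda by ML), standardized to mean 0.

    Used for bacterial functional-module abundances, whose heavy right tails
    the arcsine-sqrt transform does not stabilize.  Constant features are
    returned unchanged with a warning.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        if np.ptp(arr) == 0:
            warnings.warn("constant feature left untransformed", stacklevel=2)
            return arr.copy()
        out, _ = stats.yeojohnson(arr)
        return out - out.mean()
    return np.column_stack([power_transform(arr[:, j])
                            for j in range(arr.shape[1])])


def outlier_mask(x) -> np.ndarray:
    """Inclusion mask: subject kept unless |x - mean| > 3 * IQR.

    With IQR 0 (at least half the values tied) no subject is excluded.
    Missing values are excluded from the test of this feature.
    """
    arr = np.asarray(x, dtype=float)
    if arr[np.isfinite(arr)].size < 4:
        raise ValueError("outlier masking needs at least 4 finite values")
    finite = np.isfinite(arr)
    vals = arr[finite]
    iqr = np.subtract(*np.percentile(vals, [75, 25]))
    if iqr == 0:
        return finite
    keep = np.abs(arr - vals.mean()) <= 3.0 * iqr
    return keep & finite


@dataclass
class FeatureSetSplit:
    """Partition of features into linear-test and presence/absence sets."""

    linear_features: list
    logistic_features: list
    prevalence: pd.Series

    def __post_init__(self):
        overlap = set(self.linear_features) & set(self.logistic_features)
        if overlap:
            raise ValueError(f"split not disjoint: {sorted(overlap)[:5]}")


def prevalence_split(table: TaxaTable, threshold: float = 0.75
                     ) -> FeatureSetSplit:
    """Features with nonzero abundance in >= threshold of subjects are tested
    linearly; the rest fall back to presence/absence logistic testing."""
    prev = (table.data > 0).mean(axis=0)
    linear = list(table.feature_ids[prev >= threshold])
    logistic = list(table.feature_ids[prev < threshold])
    degenerate = list(table.feature_ids[prev == 0])
    if degenerate:
        logger.info("prevalence_split: %d all-zero features flagged: %s",
                    len(degenerate), degenerate[:10])
    return FeatureSetSplit(linear, logistic, prev)


def impute_dosages(g: GenotypeTable) -> GenotypeTable:
    """Replace missing dosages by the per-SNP mean of observed dosages."""
    data = g.data.astype(float)
    filled = data.fillna(data.mean(axis=0))
    out = GenotypeTable.__new__(GenotypeTable)
    out.data = filled
    out.annotations = g.annotations
    return out


def genotype_pcs(g: GenotypeTable, k: int = 3) -> pd.DataFrame:
    """Principal components of the column-centered dosage matrix.

    Missing dosages are mean-imputed first.  Returns subject scores for the
    top ``k`` components ordered by decreasing variance explained; if the
    matrix rank is below ``k`` the available components are returned with a
    warning.
    """
    X = impute_dosages(g).data.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s.max() * 1e-10).sum()) if s.size else 0
    if rank < k:
        warnings.warn(f"genotype matrix rank {rank} < requested {k} PCs",
                      stacklevel=2)
    k_eff = min(k, rank)
    scores = u[:, :k_eff] * s[:k_eff]
    return pd.DataFrame(scores, index=g.subject_ids,
                        columns=[f"PC{i+1}" for i in range(k_eff)])
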