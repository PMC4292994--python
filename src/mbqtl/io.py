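"""Readers, writers and cross-table validation for the pipeline's file formats.

The pipeline moves between four plain-text formats: tab-separated tables
(genotypes, taxon counts, metadata, distance matrices), dense BIOM 1.0 JSON
for taxon tables, GMT gene-set files, and Newick trees.  All tables are held
in thin wrappers around :class:`pandas.DataFrame` so that downstream modules
can rely on validated invariants (unique subject ids, non-negative counts,
dosages in {0, 1, 2} or missing).

Missing genotype dosages are kept as NaN at read time; imputation is the
association module's job, so a write/read round trip is lossless.
"""

from __future__ import annotations

import io as _stdio
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "GenotypeTable",
    "TaxaTable",
    "MetadataTable",
    "GeneSetCollection",
    "FormatError",
    "read_taxa_table",
    "read_genotypes",
    "read_metadata",
    "read_gmt",
    "read_newick",
    "align_subjects",
]

#: Clinical covariates every metadata table must carry, in canonical order.
METADATA_COLUMNS = (
    "antibiotics",
    "immunosuppressants",
    "inflammation",
    "age",
    "gender",
    "biopsy_location",
    "diagnosis",
    "disease_location",
    "years_since_diagnosis",
    "cohort",
)

#: Declared categorical levels (first level = reference for dummy coding).
CATEGORICAL_LEVELS = {
    "antibiotics": ("no", "yes"),
    "immunosuppressants": ("no", "yes"),
    "inflammation": ("no", "yes"),
    "gender": ("female", "male"),
    "biopsy_location": ("colon", "terminal_ileum", "prepouch_ileum"),
    "diagnosis": ("UC", "CD"),
    "disease_location": ("L1", "L2", "L3"),
}

GREENGENES_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Subjects x SNPs risk-allele dosage matrix with SNP annotations.

    ``data`` holds dosages as floats (0.0/1.0/2.0 or NaN for missing);
    ``annotations`` is indexed by SNP id with columns ``gene``, ``status``
    ("risk" or "null") and ``locus``.
    """

    data: pd.DataFrame
    annotations: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate subject ids in genotype table")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate SNP ids in genotype table")
        vals = self.data.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise FormatError("dosages must be 0, 1, 2 or missing")
        if self.annotations is None:
            self.annotations = pd.DataFrame(
                {"gene": self.data.columns, "status": "risk", "locus": ""},
                index=self.data.columns,
            )

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.data.columns

    def to_tsv(self, path, annotations_path=None) -> None:
        self.data.to_csv(path, sep="\t", index_label="subject", na_rep="NA")
        if annotations_path is not None:
            self.annotations.to_csv(annotations_path, sep="\t", index_label="snp")


@dataclass
class TaxaTable:
    """Subjects x features table of counts or relative abundances.

    ``lineages`` maps each feature to a Greengenes-style semicolon lineage
    string; ``ranks`` labels the taxonomic rank of each feature ("otu" for
    unbinned features).
    """

    data: pd.DataFrame
    lineages: pd.Series = None
    ranks: pd.Series = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate subject ids in taxa table")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate feature ids in taxa table")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise FormatError("negative abundance values")
        if self.lineages is None:
            self.lineages = pd.Series(self.data.columns, index=self.data.columns)
        else:
            self.lineages = self.lineages.reindex(self.data.columns)
        if self.ranks is None:
            self.ranks = pd.Series("otu", index=self.data.columns)
        else:
            self.ranks = self.ranks.reindex(self.data.columns).fillna("otu")

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            raise FormatError("cannot normalize samples with zero total")
        rel = self.data.div(totals, axis=0)
        return rel

    def with_data(self, data: pd.DataFrame) -> "TaxaTable":
        return TaxaTable(
            data,
            self.lineages.reindex(data.columns),
            self.ranks.reindex(data.columns),
        )

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.data.T.copy()
        out.insert(0, "lineage", self.lineages.reindex(out.index))
        out.insert(1, "rank", self.ranks.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="feature")

    def to_biom_json(self, path) -> None:
        """Write dense BIOM 1.0 JSON (rows = features, columns = subjects)."""
        obj = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "mbqtl",
            "matrix_type": "dense",
            "matrix_element_type": "float",
            "shape": [self.data.shape[1], self.data.shape[0]],
            "rows": [
                {"id": f, "metadata": {"taxonomy": self.lineages[f].split(";"),
                                       "rank": self.ranks[f]}}
                for f in self.data.columns
            ],
            "columns": [{"id": s, "metadata": None} for s in self.data.index],
            "data": self.data.T.to_numpy(dtype=float).tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)


@dataclass
class MetadataTable:
    """Per-subject clinical covariates plus cohort membership."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate subject ids in metadata table")
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"metadata table missing columns: {missing}")
        for col, levels in CATEGORICAL_LEVELS.items():
            bad = set(self.data[col].dropna()) - set(levels)
            if bad:
                raise FormatError(f"unknown levels {sorted(bad)} in column {col!r}")

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="subject")


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways), e.g. read from a GMT file."""

    sets: dict
    source: str = ""
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"empty gene set {name!r}")
            self.sets[name] = set(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name) -> set:
        return self.sets[name]

    def to_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_numeric_tsv(path, index_label) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"non-numeric value in column {col!r} of {path}"
            ) from exc
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    return df


def read_taxa_table(path, format: str = "tsv") -> TaxaTable:
    """Read a taxon table from TSV (features x subjects) or dense BIOM JSON."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "lineage" not in df.columns:
            raise FormatError("taxa TSV requires a 'lineage' column")
        lineages = df.pop("lineage").astype(str)
        ranks = df.pop("rank").astype(str) if "rank" in df.columns else None
        for col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise FormatError(f"non-numeric count in column {col!r}") from exc
        if df.index.has_duplicates:
            raise FormatError("duplicate feature ids")
        data = df.T
        data.index = pd.Index([str(i) for i in data.index])
        data.columns = pd.Index([str(c) for c in data.columns])
        lineages.index = data.columns
        if ranks is not None:
            ranks.index = data.columns
        return TaxaTable(data, lineages, ranks)
    if format == "biom":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        if obj.get("matrix_type") != "dense":
            raise FormatError("only dense BIOM JSON is supported")
        features = [r["id"] for r in obj["rows"]]
        subjects = [c["id"] for c in obj["columns"]]
        lineages = pd.Series(
            [";".join((r.get("metadata") or {}).get("taxonomy", [r["id"]]))
             for r in obj["rows"]],
            index=features,
        )
        ranks = pd.Series(
            [(r.get("metadata") or {}).get("rank", "otu") for r in obj["rows"]],
            index=features,
        )
        mat = np.asarray(obj["data"], dtype=float)
        if mat.shape != (len(features), len(subjects)):
            raise FormatError("BIOM shape does not match rows/columns")
        data = pd.DataFrame(mat.T, index=subjects, columns=features)
        return TaxaTable(data, lineages, ranks)
    raise ValueError(f"unknown taxa table format {format!r}")


def read_genotypes(path, annotations_path=None) -> GenotypeTable:
    """Read a subjects x SNPs dosage TSV ('NA' marks missing dosages)."""
    df = _read_numeric_tsv(path, "subject")
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
        ann.index = ann.index.astype(str)
    return GenotypeTable(df, ann)


def read_metadata(path) -> MetadataTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    for col in ("age", "years_since_diagnosis"):
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise FormatError(f"non-numeric value in column {col!r}") from exc
    return MetadataTable(df)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from GMT: <set name> <tab> <description> <tab> members..."""
    sets, descriptions = {}, {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise FormatError(f"duplicate gene set {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, source=str(path), descriptions=descriptions)


def read_newick(path) -> TreeNode:
    if hasattr(path, "read"):
        return TreeNode.read(path, format="newick")
    with open(path, encoding="utf-8") as fh:
        return TreeNode.read(fh, format="newick")


def read_newick_string(newick: str) -> TreeNode:
    return TreeNode.read(_stdio.StringIO(newick), format="newick")


# ---------------------------------------------------------------------------
# cross-table consistency
# ---------------------------------------------------------------------------


def align_subjects(genotypes: GenotypeTable, taxa: TaxaTable,
                   metadata: MetadataTable):
    """Intersect the three tables' subject sets and align row order.

    The shared subjects are kept in the genotype table's order, so alignment
    is order-stable and idempotent.  Subjects missing from any table are
    reported via a warning.  An empty intersection is a hard error.
    """
    shared = [s for s in genotypes.subject_ids
              if s in set(taxa.subject_ids) and s in set(metadata.subject_ids)]
    if not shared:
        raise FormatError("no subjects shared between genotype, taxa and metadata")
    n_all = {len(genotypes.subject_ids), len(taxa.subject_ids),
             len(metadata.subject_ids)}
    if n_all != {len(shared)}:
        dropped = (set(genotypes.subject_ids) | set(taxa.subject_ids)
                   | set(metadata.subject_ids)) - set(shared)
        warnings.warn(
            f"dropping {len(dropped)} subjects absent from at least one table",
            stacklevel=2,
        )
    g = GenotypeTable(genotypes.data.loc[shared], genotypes.annotations)
    t = taxa.with_data(taxa.data.loc[shared])
    m = MetadataTable(metadata.data.loc[shared])
    return g, t, m


def parse_lineage(lineage: str):
    """Split a Greengenes lineage into (rank, name) pairs, stripping prefixes."""
    out = []
    for part in str(lineage).split(";"):
        part = part.strip()
        if not part:
            continue
        for prefix, rank in zip(GREENGENES_PREFIXES, RANK_NAMES):
            if part.startswith(prefix):
                out.append((rank, part[len(prefix):]))
                break
        else:
            out.append((None, part))
    return out
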