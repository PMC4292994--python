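"""Synthetic paired genotype + microbiome + metadata cohorts with planted truth.

The generator emulates the study design this pipeline targets: three IBD
cohorts of ~150 mucosal-biopsy subjects each, Immunochip-style risk-allele
dosages (independent loci in Hardy-Weinberg proportions, MAF > 0.1 for the
tested panel), a compositional taxon table dominated by ~22 abundant taxa
plus a rare tail, and the ten clinical covariates the analysis adjusts for.

SNP effects on taxa are planted on the arcsine-square-root scale — the scale
the association module tests on — so the linear model downstream is
correctly specified; a switch plants them on the raw relative-abundance
scale for robustness checks.  Counts are Dirichlet-multinomial around the
effect-shifted composition.  Cohort batch effects are additive offsets on
the transformed scale, matching the pipeline's treatment of cohort
membership as a covariate.

A six-variant aggregate locus mimicking NOD2 is supported: per-variant
frequencies default to values solving the two carrier-rate summaries the
study design calls for (6.3% of subjects carrying the lead variant, 21.8%
carrying at least one risk allele across all six).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .io import GenotypeTable, MetadataTable, TaxaTable, CATEGORICAL_LEVELS

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "PlantedEffect",
    "CovariateEffect",
    "AggregateLocusSpec",
    "nod2_like_locus",
    "study_specs",
    "simulate_genotypes",
    "simulate_metadata",
    "simulate_counts",
    "simulate_cohort",
    "simulate_study",
    "random_bifurcating_tree",
    "default_lineages",
    "write_cohort",
]

_PHYLA = (
    ("Firmicutes", "Clostridia", "Clostridiales",
     ("Ruminococcaceae", "Lachnospiraceae", "Veillonellaceae")),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales",
     ("Bacteroidaceae", "Prevotellaceae", "Rikenellaceae")),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales",
     ("Enterobacteriaceae", "Pasteurellaceae")),
    ("Actinobacteria", "Actinobacteria", "Bifidobacteriales",
     ("Bifidobacteriaceae", "Coriobacteriaceae")),
)


class InvalidSpecError(ValueError):
    """Raised when a simulation spec violates its invariants."""


def _default_prevalences() -> dict:
    return {
        "antibiotics": {"no": 0.9, "yes": 0.1},
        "immunosuppressants": {"no": 0.7, "yes": 0.3},
        "inflammation": {"no": 0.685, "yes": 0.315},
        "gender": {"female": 0.5, "male": 0.5},
        "diagnosis": {"UC": 0.375, "CD": 0.625},
        "biopsy_location": {"colon": 0.73, "terminal_ileum": 0.25,
                            "prepouch_ileum": 0.02},
        "disease_location": {"L1": 0.3, "L2": 0.3, "L3": 0.4},
    }


class CohortSpec:
    """Parameters of one simulated cohort.

    ``maf`` may be a scalar, a per-SNP array, or None (drawn uniformly
    from (0.15, 0.45) using ``seed``).  ``base_composition`` is the mean
    relative-abundance simplex over all taxa (dominant + rare); ``dispersion``
    is the Dirichlet concentration controlling biological overdispersion.
    """

    def __init__(self, cohort_id, n_subjects=150, maf=None, n_risk_snps=154,
                 n_null_snps=200, n_taxa=22, n_rare_taxa=18,
                 base_composition=None, dispersion=200.0,
                 sequencing_depth_range=(2000, 6000),
                 covariate_prevalences=None, age_range=(18.0, 75.0),
                 duration_range=(0.0, 30.0), cohort_offset_sd=0.0, seed=0,
                 allow_low_maf=False):
        self.cohort_id = str(cohort_id)
        self.n_subjects = int(n_subjects)
        self.n_risk_snps = int(n_risk_snps)
        self.n_null_snps = int(n_null_snps)
        self.n_taxa = int(n_taxa)
        self.n_rare_taxa = int(n_rare_taxa)
        self.dispersion = float(dispersion)
        self.sequencing_depth_range = (int(sequencing_depth_range[0]),
                                       int(sequencing_depth_range[1]))
        self.covariate_prevalences = (covariate_prevalences
                                      or _default_prevalences())
        self.age_range = tuple(age_range)
        self.duration_range = tuple(duration_range)
        self.cohort_offset_sd = float(cohort_offset_sd)
        self.seed = int(seed)
        self.allow_low_maf = bool(allow_low_maf)

        if self.n_subjects < 2:
            raise InvalidSpecError("n_subjects must be >= 2")
        if self.dispersion <= 0:
            raise InvalidSpecError("dispersion must be positive")
        lo, hi = self.sequencing_depth_range
        if not (0 < lo <= hi):
            raise InvalidSpecError("invalid sequencing depth range")

        rng = np.random.default_rng(self.seed)
        n_snps = self.n_risk_snps + self.n_null_snps
        if maf is None:
            maf = rng.uniform(0.15, 0.45, size=n_snps)
        maf = np.broadcast_to(np.atleast_1d(np.asarray(maf, dtype=float)),
                              (n_snps,)).copy()
        if not allow_low_maf and (maf <= 0.1).any():
            raise InvalidSpecError("all MAF must exceed 0.1 (risk-SNP filter)")
        if (maf < 0).any() or (maf > 0.5).any():
            raise InvalidSpecError("MAF must lie in [0, 0.5]")
        self.maf = maf

        total_taxa = self.n_taxa + self.n_rare_taxa
        if base_composition is None:
            base_composition = default_base_composition(
                self.n_taxa, self.n_rare_taxa)
        base_composition = np.asarray(base_composition, dtype=float)
        if base_composition.shape != (total_taxa,):
            raise InvalidSpecError("base_composition length != total taxa")
        if (base_composition <= 0).any():
            raise InvalidSpecError("base_composition must be positive")
        if abs(base_composition.sum() - 1.0) > 1e-9:
            raise InvalidSpecError("base_composition must sum to 1")
        self.base_composition = base_composition

        for cov, probs in self.covariate_prevalences.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise InvalidSpecError(
                    f"prevalences for {cov!r} do not sum to 1")

    # canonical id vectors -------------------------------------------------

    @property
    def snp_ids(self):
        risk = [f"rsR{i:04d}" for i in range(1, self.n_risk_snps + 1)]
        null = [f"rsN{i:04d}" for i in range(1, self.n_null_snps + 1)]
        return risk + null

    @property
    def snp_status(self):
        return ["risk"] * self.n_risk_snps + ["null"] * self.n_null_snps

    @property
    def taxon_ids(self):
        dom = [f"T{i:03d}" for i in range(1, self.n_taxa + 1)]
        rare = [f"R{i:03d}" for i in range(1, self.n_rare_taxa + 1)]
        return dom + rare

    @property
    def subject_ids(self):
        return [f"{self.cohort_id}_S{i:04d}"
                for i in range(1, self.n_subjects + 1)]


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth linear effect of one SNP (or aggregate locus) on one taxon.

    ``beta`` acts on the arcsine-sqrt-transformed relative abundance per risk
    allele (or on the raw scale when the generator is switched to
    ``effect_scale='raw'``).
    """

    snp_id: str
    taxon_id: str
    beta: float
    conserved_in: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise InvalidSpecError("planted beta must be finite")


@dataclass(frozen=True)
class CovariateEffect:
    """Additive shift of a taxon's transformed abundance for one covariate level."""

    covariate: str
    level: str
    taxon_id: str
    delta: float


@dataclass
class AggregateLocusSpec:
    """A multi-variant locus tested as a single summed risk-allele dosage."""

    locus_id: str
    variant_ids: tuple
    per_variant_maf: tuple

    def __post_init__(self):
        self.variant_ids = tuple(self.variant_ids)
        self.per_variant_maf = tuple(float(m) for m in self.per_variant_maf)
        if len(self.variant_ids) < 2:
            raise InvalidSpecError("aggregate locus needs >= 2 variants")
        if len(self.variant_ids) != len(self.per_variant_maf):
            raise InvalidSpecError("one MAF per variant required")
        if any(not (0 <= m <= 0.5) for m in self.per_variant_maf):
            raise InvalidSpecError("per-variant MAF must lie in [0, 0.5]")


def nod2_like_locus(locus_id: str = "NOD2like") -> AggregateLocusSpec:
    """Six-variant aggregate locus calibrated to the NOD2 carrier-rate contrast.

    Under Hardy-Weinberg and independent variants, the lead variant's MAF
    solves carrier rate 1-(1-m)^2 = 6.3% and the five secondary variants'
    shared MAF solves an aggregate (any-variant) carrier rate of 21.8%.
    """
    lead = 1.0 - np.sqrt(1.0 - 0.063)
    rest_carrier = 1.0 - ((1.0 - 0.218) / (1.0 - 0.063)) ** (1.0 / 5.0)
    rest = 1.0 - np.sqrt(1.0 - rest_carrier)
    variants = (f"{locus_id}_v1", f"{locus_id}_v2", f"{locus_id}_v3",
                f"{locus_id}_v4", f"{locus_id}_v5", f"{locus_id}_v6")
    return AggregateLocusSpec(locus_id, variants, (lead,) + (rest,) * 5)


def default_base_composition(n_taxa: int, n_rare_taxa: int) -> np.ndarray:
    """Geometric-decay composition: dominant taxa hold 98% of the mass."""
    dom = 0.7 ** np.arange(n_taxa)
    dom = 0.98 * dom / dom.sum() if n_rare_taxa else dom / dom.sum()
    if n_rare_taxa == 0:
        return dom
    rare = 0.8 ** np.arange(n_rare_taxa)
    rare = 0.02 * rare / rare.sum()
    return np.concatenate([dom, rare])


def default_lineages(taxon_ids) -> pd.Series:
    """Deterministic Greengenes-style lineage strings cycling over real clades."""
    out = {}
    fams = [(p, c, o, f) for (p, c, o, fs) in _PHYLA for f in fs]
    for i, tid in enumerate(taxon_ids):
        phylum, klass, order, family = fams[i % len(fams)]
        genus = f"{family[:-4]}g{i // len(fams) + 1}"
        out[tid] = (f"k__Bacteria;p__{phylum};c__{klass};o__{order};"
                    f"f__{family};g__{genus}")
    return pd.Series(out)


def study_specs(seed: int = 0, **overrides) -> list:
    """Three cohort specs mirroring the target study design.

    Cohorts of 152/160/162 subjects with CD fractions 62.5%/14.3%/63.5% and
    inflamed-biopsy fractions 31.5%/11.3%/53.1%; the second cohort is
    dominated by pre-pouch ileum biopsies.
    """
    layout = [
        ("boston", 152, 0.625, 0.315, {"colon": 0.73, "terminal_ileum": 0.26,
                                       "prepouch_ileum": 0.01}),
        ("toronto", 160, 0.143, 0.113, {"colon": 0.181, "terminal_ileum": 0.113,
                                        "prepouch_ileum": 0.706}),
        ("groningen", 162, 0.635, 0.531, {"colon": 0.87, "terminal_ileum": 0.12,
                                          "prepouch_ileum": 0.01}),
    ]
    specs = []
    for i, (name, n, cd, infl, biopsy) in enumerate(layout):
        prev = _default_prevalences()
        prev["diagnosis"] = {"UC": round(1 - cd, 3), "CD": cd}
        prev["inflammation"] = {"no": round(1 - infl, 3), "yes": infl}
        prev["biopsy_location"] = biopsy
        specs.append(CohortSpec(name, n_subjects=n, covariate_prevalences=prev,
                                seed=seed, **overrides))
    return specs


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_genotypes(spec: CohortSpec,
                       aggregate_locus: AggregateLocusSpec | None = None,
                       ) -> GenotypeTable:
    """Draw dosages Binomial(2, MAF) per SNP, independent across loci.

    Aggregate-locus variants are appended with their own (possibly rare)
    frequencies; they are annotated with the locus id and gene name equal to
    the locus id.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    snp_ids = list(spec.snp_ids)
    maf = np.asarray(spec.maf, dtype=float)
    status = list(spec.snp_status)
    genes = [f"GENE{i:04d}" for i in range(1, len(snp_ids) + 1)]
    loci = [""] * len(snp_ids)
    if aggregate_locus is not None:
        if set(aggregate_locus.variant_ids) & set(snp_ids):
            raise InvalidSpecError("aggregate variants collide with SNP ids")
        snp_ids += list(aggregate_locus.variant_ids)
        maf = np.concatenate([maf, aggregate_locus.per_variant_maf])
        status += ["risk"] * len(aggregate_locus.variant_ids)
        genes += [aggregate_locus.locus_id] * len(aggregate_locus.variant_ids)
        loci += [aggregate_locus.locus_id] * len(aggregate_locus.variant_ids)
    dosage = rng.binomial(2, maf, size=(spec.n_subjects, len(snp_ids)))
    data = pd.DataFrame(dosage.astype(float), index=spec.subject_ids,
                        columns=snp_ids)
    ann = pd.DataFrame({"gene": genes, "status": status, "locus": loci},
                       index=snp_ids)
    return GenotypeTable(data, ann)


def simulate_metadata(spec: CohortSpec) -> MetadataTable:
    """Draw the ten clinical covariates; age uniform on the adult range."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    n = spec.n_subjects
    cols = {}
    for cov, probs in spec.covariate_prevalences.items():
        levels = list(CATEGORICAL_LEVELS.get(cov, probs.keys()))
        p = np.array([probs.get(lv, 0.0) for lv in levels])
        cols[cov] = rng.choice(levels, size=n, p=p / p.sum())
    cols["age"] = np.round(rng.uniform(*spec.age_range, size=n), 1)
    cols["years_since_diagnosis"] = np.round(
        rng.uniform(*spec.duration_range, size=n), 1)
    cols["cohort"] = spec.cohort_id
    df = pd.DataFrame(cols, index=spec.subject_ids)
    order = ["antibiotics", "immunosuppressants", "inflammation", "age",
             "gender", "biopsy_location", "diagnosis", "disease_location",
             "years_since_diagnosis", "cohort"]
    return MetadataTable(df[order])


def _asin_sqrt(p):
    return np.arcsin(np.sqrt(p))


def simulate_counts(spec: CohortSpec, genotypes: GenotypeTable,
                    metadata: MetadataTable, effects=(),
                    covariate_effects=(), cohort_offsets=None,
                    effect_scale: str = "transformed") -> TaxaTable:
    """Dirichlet-multinomial counts around an effect-shifted composition.

    Per subject, the expected transformed abundance of taxon t is
    ``asin(sqrt(base_t)) + sum(beta * dosage) + covariate deltas + cohort
    offset``; the inverse transform maps back to proportions, which are
    clipped to [0, 1], renormalized, overdispersed by a Dirichlet draw with
    concentration ``spec.dispersion`` and finally sampled as multinomial
    counts at the subject's sequencing depth.
    """
    if effect_scale not in ("transformed", "raw"):
        raise ValueError("effect_scale must be 'transformed' or 'raw'")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    taxa = list(spec.taxon_ids)
    t_index = {t: i for i, t in enumerate(taxa)}
    n = spec.n_subjects
    base = spec.base_composition

    shift = np.zeros((n, len(taxa)))
    for eff in effects:
        if eff.conserved_in and spec.cohort_id not in eff.conserved_in:
            continue
        if eff.taxon_id not in t_index:
            raise InvalidSpecError(f"unknown taxon {eff.taxon_id!r} in effect")
        if eff.snp_id not in genotypes.snp_ids:
            raise InvalidSpecError(f"unknown SNP {eff.snp_id!r} in effect")
        dosage = genotypes.data[eff.snp_id].to_numpy(dtype=float)
        dosage = np.nan_to_num(dosage, nan=np.nanmean(dosage))
        shift[:, t_index[eff.taxon_id]] += eff.beta * dosage
    for ceff in covariate_effects:
        if ceff.taxon_id not in t_index:
            raise InvalidSpecError(f"unknown taxon {ceff.taxon_id!r} in effect")
        flag = (metadata.data[ceff.covariate] == ceff.level).to_numpy()
        shift[:, t_index[ceff.taxon_id]] += ceff.delta * flag
    if cohort_offsets is not None:
        offs = np.asarray([cohort_offsets.get(t, 0.0) for t in taxa])
        shift = shift + offs
    elif spec.cohort_offset_sd > 0:
        off_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
        shift = shift + off_rng.normal(0, spec.cohort_offset_sd, len(taxa))

    if effect_scale == "transformed":
        transformed = _asin_sqrt(base)[None, :] + shift
        lo, hi = 0.0, np.pi / 2
        if (transformed < lo).any() or (transformed > hi).any():
            warnings.warn("planted effects pushed transformed abundance "
                          "outside [0, pi/2]; clipping", stacklevel=2)
            transformed = np.clip(transformed, lo, hi)
        expected = np.sin(transformed) ** 2
    else:
        expected = base[None, :] + shift
        if (expected < 0).any() or (expected > 1).any():
            warnings.warn("planted effects pushed expected abundance outside "
                          "[0, 1]; clipping", stacklevel=2)
            expected = np.clip(expected, 0.0, 1.0)
    rowsum = expected.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    expected = expected / rowsum

    lo_d, hi_d = spec.sequencing_depth_range
    depths = rng.integers(lo_d, hi_d + 1, size=n)
    counts = np.empty((n, len(taxa)), dtype=np.int64)
    conc = spec.dispersion
    for i in range(n):
        alpha = np.maximum(conc * expected[i], 1e-9)
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depths[i], p)
    data = pd.DataFrame(counts, index=spec.subject_ids, columns=taxa)
    return TaxaTable(data, default_lineages(taxa))


def simulate_cohort(spec: CohortSpec, effects=(), covariate_effects=(),
                    aggregate_locus=None, cohort_offsets=None,
                    effect_scale="transformed"):
    """Generate the (genotypes, metadata, taxa) triple for one cohort."""
    g = simulate_genotypes(spec, aggregate_locus=aggregate_locus)
    m = simulate_metadata(spec)
    t = simulate_counts(spec, g, m, effects=effects,
                        covariate_effects=covariate_effects,
                        cohort_offsets=cohort_offsets,
                        effect_scale=effect_scale)
    return g, m, t


def simulate_study(specs, effects=(), covariate_effects=(),
                   aggregate_locus=None, cohort_offset_sd=0.1,
                   seed: int = 0, effect_scale="transformed") -> dict:
    """Simulate several cohorts sharing planted effects and taxon universe.

    Cohort batch effects are drawn once per cohort as i.i.d. normal offsets
    (sd ``cohort_offset_sd``) on the transformed scale.  Each offset is
    truncated below at half the taxon's transformed baseline so a batch
    effect can shift but never annihilate a dominant taxon — the emulated
    design has the same dominant taxa present in every cohort, and planted
    effects must remain expressible (conserved) in all of them.
    """
    out = {}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    for spec in specs:
        taxa = spec.taxon_ids
        floor = -0.5 * _asin_sqrt(spec.base_composition)
        draws = np.maximum(rng.normal(0, cohort_offset_sd, len(taxa)), floor)
        offsets = dict(zip(taxa, draws))
        out[spec.cohort_id] = simulate_cohort(
            spec, effects=effects, covariate_effects=covariate_effects,
            aggregate_locus=aggregate_locus, cohort_offsets=offsets,
            effect_scale=effect_scale)
    return out


def random_bifurcating_tree(taxon_ids, seed: int = 0) -> str:
    """Newick for a random bifurcating tree over the taxa (exp branch lengths)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))

    def build(ids):
        if len(ids) == 1:
            return f"{ids[0]}:{rng.exponential(0.5):.4f}"
        k = int(rng.integers(1, len(ids)))
        left, right = ids[:k], ids[k:]
        return (f"({build(left)},{build(right)}):{rng.exponential(0.5):.4f}")

    ids = list(taxon_ids)
    rng.shuffle(ids)
    return f"({build(ids[: len(ids) // 2 or 1])},{build(ids[len(ids) // 2 or 1:])}):0.0;"


def calibrate_beta(spec: CohortSpec, taxon_id: str, f2: float,
                   maf: float = 0.3, n_pilot: int = 400,
                   seed: int = 12345) -> float:
    """Return the planted beta giving Cohen effect size ~f2 for one taxon.

    Runs a small null simulation to estimate the residual variance of the
    taxon's arcsine-sqrt-transformed relative abundance under the spec's
    noise model, then solves beta^2 * var(dosage) = f2 * var(residual) with
    var(dosage) = 2*maf*(1-maf).
    """
    pilot = CohortSpec(spec.cohort_id, n_subjects=n_pilot,
                       n_risk_snps=spec.n_risk_snps,
                       n_null_snps=spec.n_null_snps, n_taxa=spec.n_taxa,
                       n_rare_taxa=spec.n_rare_taxa,
                       base_composition=spec.base_composition,
                       dispersion=spec.dispersion,
                       sequencing_depth_range=spec.sequencing_depth_range,
                       covariate_prevalences=spec.covariate_prevalences,
                       seed=seed)
    g, m, t = simulate_cohort(pilot)
    rel = t.relative_abundance()[taxon_id].to_numpy()
    var_y = np.var(_asin_sqrt(rel), ddof=1)
    var_d = 2 * maf * (1 - maf)
    return float(np.sqrt(f2 * var_y / var_d))


def write_cohort(outdir, cohort_id, genotypes: GenotypeTable,
                 metadata: MetadataTable, taxa: TaxaTable, effects=(),
                 newick: str | None = None, manifest: dict | None = None):
    """Write one cohort's fixture files (TSV + BIOM JSON + truth + manifest)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes.to_tsv(outdir / f"{cohort_id}_genotypes.tsv",
                     outdir / f"{cohort_id}_snp_annotations.tsv")
    metadata.to_tsv(outdir / f"{cohort_id}_metadata.tsv")
    taxa.to_tsv(outdir / f"{cohort_id}_taxa.tsv")
    taxa.to_biom_json(outdir / f"{cohort_id}_taxa.biom.json")
    if effects:
        pd.DataFrame([{"snp": e.snp_id, "taxon": e.taxon_id, "beta": e.beta,
                       "conserved_in": ",".join(e.conserved_in)}
                      for e in effects]).to_csv(
            outdir / "truth_effects.tsv", sep="\t", index=False)
    if newick is not None:
        (outdir / "tree.nwk").write_text(newick, encoding="utf-8")
    if manifest is not None:
        with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
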