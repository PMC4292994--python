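# mbqtl

Cross-cohort host genotype–microbiome association testing for IBD-style
paired cohorts.

## The problem

Inflammatory bowel disease (IBD) has both host-genetic risk factors
(Immunochip loci such as *NOD2*) and a characteristic gut dysbiosis.
Testing every risk SNP against every bacterial taxon across modest clinical
cohorts is badly underpowered for effect-size replication, but the
*direction* of a SNP's effects on taxa is comparable across cohorts.  This
package implements that analysis end to end:

* **Covariate-adjusted SNP–taxon tests.**  For each SNP and taxon, the
  arcsine-square-root-transformed relative abundance `y = asin(sqrt(f))` is
  regressed on risk-allele dosage `g ∈ {0,1,2}`:

  `y = β·g + Xγ + ε`

  where `X` holds the ten clinical covariates (antibiotics < 1 month,
  immunosuppressants < 1 month, inflammation status, age, gender, biopsy
  location, CD/UC diagnosis, disease location, disease duration, cohort)
  dummy-coded plus the first three genotype principal components.  Taxa
  present in fewer than 75% of subjects fall back to presence/absence
  logistic regression.
* **Sign-concordance screening.**  For each SNP and cohort pair, the signs
  of its taxon coefficients (over taxa with nominal p < 0.05 in at least
  one cohort) are cross-tabulated and summarized by the Matthews
  correlation coefficient `MCC = (ad − bc)/√((a+b)(c+d)(a+c)(b+d))`,
  tested per gene and Benjamini–Hochberg corrected at FDR 0.25.
* **Multi-variant fine mapping.**  A locus with several causal variants
  (the *NOD2* prototype) is tested through the summed risk-allele dosage
  across its variants, including tests against PCoA axes of UniFrac /
  Bray-Curtis / Jensen-Shannon beta diversity and a Mantel correlation of
  genome-wide Manhattan distance with microbiome distance.
* **Pathway enrichment.**  Rank-product statistics (mean log-rank of a
  pathway's gene–taxon tests) judged against size-matched gene sets drawn
  from null Immunochip variants, plus hypergeometric over-representation.
* **Host-factor analysis.**  Uncertainty-coefficient clustering of
  redundant covariates, a host-factor ↔ taxon association network
  (edge weight = |β| / mean taxon abundance), and the microbial dysbiosis
  index `MDI = log(Σ disease taxa / Σ health taxa)` tested against recent
  antibiotic use while controlling for *NOD2* dosage.
* **A synthetic paired-cohort generator** (three cohorts, 474 subjects,
  planted SNP→taxon effects with known direction, covariate confounding,
  cohort batch effects, a six-variant aggregate locus) so every stage is
  verifiable against planted ground truth.

## Worked example

```python
import pandas as pd
from mbqtl import synthdata as sd, preprocess as pp
from mbqtl import association as assoc, concordance as cc

# three cohorts sharing one planted SNP effect (conserved direction)
beta = 0.013  # per-allele shift on the arcsine-sqrt scale (~f2 = 0.05)
effects = [sd.PlantedEffect("rsR0001", f"T{j:03d}", beta * (-1) ** j)
           for j in range(1, 13)]
specs = [sd.CohortSpec(c, n_subjects=150, n_risk_snps=8, n_null_snps=0,
                       n_taxa=22, n_rare_taxa=0, seed=i)
         for i, c in enumerate(["boston", "toronto", "groningen"])]
study = sd.simulate_study(specs, effects=effects, seed=0)

results = {}
for cid, (g, m, t) in study.items():
    rel = t.relative_abundance()
    y = pd.DataFrame(pp.transform_arcsine_sqrt(rel.to_numpy()),
                     index=rel.index, columns=rel.columns)
    X = assoc.build_design(m, pp.genotype_pcs(g, 3))
    results[cid] = assoc.association_screen(g, y, X, cohort_id=cid)

screen = cc.concordance_screen(results)
print(screen[screen.snp_id == "rsR0001"]
      [["cohort_pair", "mcc", "p", "q", "n_pairs"]].to_string(index=False))
```

Output:

```
      cohort_pair      mcc        p        q  n_pairs
 boston|groningen 1.000000 0.011905 0.071429        9
   boston|toronto 0.836660 0.010101 0.030303       12
groningen|toronto 0.843274 0.006993 0.048951       13
```

The planted SNP's effect directions replicate across all three cohort
pairs: 9–13 taxa pass the nominal-significance filter per pair, the sign
tables give MCC 0.84–1.0, and every pair stays significant after BH
correction at FDR 0.25.  Null SNPs (not shown) are either skipped for
having fewer than 3 eligible taxa or land at q ≈ 1.

The same pipeline is scriptable from a shell:

```sh
mbqtl all --config config.yaml     # simulate → preprocess → associate →
                                   # concord → hostnet → mdi
```

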