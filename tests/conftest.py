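import numpy as np
import pandas as pd
import pytest

from mbqtl import synthdata as sd
from mbqtl.io import MetadataTable, TaxaTable


@pytest.fixture(scope="session")
def small_spec():
    return sd.CohortSpec("c1", n_subjects=80, n_risk_snps=6, n_null_snps=6,
                         n_taxa=10, n_rare_taxa=4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """One simulated cohort with a planted effect and a NOD2-like locus."""
    effects = [sd.PlantedEffect("rsR0001", "T001", 0.08)]
    return sd.simulate_cohort(small_spec, effects=effects,
                              aggregate_locus=sd.nod2_like_locus())


@pytest.fixture()
def toy_taxa():
    data = pd.DataFrame(
        [[10, 5, 0, 5], [0, 10, 5, 5], [5, 5, 5, 5]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C", "D"],
    )
    lineages = pd.Series(
        {
            "A": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__Faecalibacterium",
            "B": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Roseburia",
            "C": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacteriales;f__Enterobacteriaceae;g__Escherichia",
            "D": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides",
        }
    )
    return TaxaTable(data, lineages)


def make_metadata(n, seed=0, cohort="c1", antibiotics_p=0.3):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "antibiotics": rng.choice(["no", "yes"], n,
                                      p=[1 - antibiotics_p, antibiotics_p]),
            "immunosuppressants": rng.choice(["no", "yes"], n),
            "inflammation": rng.choice(["no", "yes"], n),
            "age": rng.uniform(18, 75, n).round(1),
            "gender": rng.choice(["female", "male"], n),
            "biopsy_location": rng.choice(
                ["colon", "terminal_ileum", "prepouch_ileum"], n,
                p=[0.6, 0.3, 0.1]),
            "diagnosis": rng.choice(["UC", "CD"], n),
            "disease_location": rng.choice(["L1", "L2", "L3"], n),
            "years_since_diagnosis": rng.uniform(0, 30, n).round(1),
            "cohort": cohort,
        },
        index=[f"{cohort}_S{i:04d}" for i in range(1, n + 1)],
    )
    return MetadataTable(df)


@pytest.fixture()
def metadata_80():
    return make_metadata(80, seed=3)
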