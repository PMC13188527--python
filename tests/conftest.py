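import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")

from longisal import (
    OtuCountTable,
    StudyDesign,
    TruthConfig,
    generate_cohort,
)

BALANCED_ARMS = {("WT", "M"): 15, ("KO", "M"): 15, ("WT", "F"): 15, ("KO", "F"): 15}


@pytest.fixture(scope="session")
def small_table() -> OtuCountTable:
    """Tiny hand-built count table with known taxonomy and metadata."""
    counts = pd.DataFrame(
        {
            "Otu0001": [0, 3, 5, 10],
            "Otu0002": [4, 4, 4, 4],
            "Otu0003": [0, 0, 0, 6],
            "Otu0004": [2, 2, 8, 0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {
            "mouse_id": ["m1", "m1", "m2", "m2"],
            "genotype": ["WT", "WT", "KO", "KO"],
            "sex": ["F", "F", "M", "M"],
            "week": [0, 4, 0, 4],
            "diagnosis": ["ED/CIS", "ED/CIS", "OSCC", "OSCC"],
        },
        index=counts.index,
    )
    tax = pd.Series(
        {
            "Otu0001": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                        "Lachnospiraceae", "Blautia"),
            "Otu0002": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                        "Lachnospiraceae", "Roseburia"),
            "Otu0003": ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                        "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas"),
            "Otu0004": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                        "Streptococcaceae", "unclassified"),
        }
    )
    return OtuCountTable(counts=counts, sample_meta=meta, taxonomy=tax)


@pytest.fixture(scope="session")
def balanced_cohort():
    """Complete (no dropout) balanced synthetic cohort, no zero inflation."""
    design = StudyDesign(
        seed=42, n_otus=20, dropout_rate=0.0, n_mice=dict(BALANCED_ARMS)
    )
    cfg = TruthConfig(zero_inflation=0.0, sigma_b=0.5, sigma_e=1.0)
    table, truth = generate_cohort(design, cfg)
    return table, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Study-shaped cohort: 22/13/20/21 arms, dropout, zero inflation."""
    design = StudyDesign(seed=7, n_otus=60)
    table, truth = generate_cohort(design, TruthConfig(zero_inflation=0.25))
    return table, truth
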