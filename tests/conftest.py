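import numpy as np
import pandas as pd
import pytest

from admixscan import (
    AdmixtureModel,
    AncestralFrequencies,
    AncestryMatrix,
    DosageMatrix,
    PhenotypeModel,
    simulate_cohort,
)

PAPER_PROPORTIONS = (0.6486, 0.3190, 0.0324)
CAUSAL_FREQS = (0.52, 0.12, 0.20)


@pytest.fixture(scope="session")
def small_model():
    return AdmixtureModel(proportions=PAPER_PROPORTIONS, n_markers=20, chromosome_length=1.0)


@pytest.fixture(scope="session")
def small_cohort(small_model):
    """200-individual cohort with a planted causal variant at marker 10."""
    freqs = AncestralFrequencies.background(
        small_model.n_markers, causal_index=10, rng=np.random.default_rng(99)
    )
    pheno = PhenotypeModel(effect_per_allele=0.25, causal_index=10)
    ancestry, genotypes, phenotypes = simulate_cohort(small_model, freqs, pheno, 200, seed=7)
    return ancestry, genotypes, phenotypes


def make_ancestry(nam, positions=None, chrom="11", ids=None, **kw):
    """Hand-rolled AncestryMatrix from a plain NAM copy matrix."""
    nam = np.asarray(nam)
    n, M = nam.shape
    pos = positions if positions is not None else (np.arange(M) + 1) * 1000
    markers = pd.DataFrame(
        {"marker": [f"m{j}" for j in range(M)], "chrom": chrom, "pos": pos}
    )
    if ids is None:
        ids = np.array([f"i{k}" for k in range(n)])
    return AncestryMatrix(ids=ids, markers=markers, nam=nam, **kw)


def make_dosages(dosage, coded="A", other="G", ids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, M = dosage.shape
    markers = pd.DataFrame(
        {
            "marker": [f"v{j}" for j in range(M)],
            "chrom": "11",
            "pos": (np.arange(M) + 1) * 500,
            "coded": coded,
            "other": other,
        }
    )
    if ids is None:
        ids = np.array([f"i{k}" for k in range(n)])
    return DosageMatrix(ids=ids, markers=markers, dosage=dosage)
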