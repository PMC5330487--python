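"""Seeded synthetic three-way-admixed cohort generator.

Ancestry is simulated under a single-pulse admixture model: each haploid
chromosome is a piecewise-constant path whose crossover events form a
Poisson process (rate = generations since admixture, per Morgan) and
whose ancestry after each event is redrawn i.i.d. from the admixture
proportions. Genotypes are drawn Bernoulli from ancestry-specific allele
frequencies on each haplotype; phenotypes follow a linear model with a
sex/age/age^2/BMI covariate structure, a per-allele causal effect on the
standardized scale, Gaussian noise, and an invertible medication effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .ancestry import AncestryMatrix
from .assoc import DosageMatrix

#: Cohort-average admixture proportions used as simulator defaults
#: (NAM, EUR, AFR for a Mexico City-like cohort).
DEFAULT_PROPORTIONS = (0.6486, 0.3190, 0.0324)


@dataclass
class AdmixtureModel:
    """Single-pulse admixture model for one simulated chromosome."""

    proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    generations_since_admixture: float = 15.0
    chromosome_length: float = 1.0  # Morgans
    n_markers: int = 100
    marker_positions: np.ndarray | None = None  # genetic positions, Morgans
    chrom: str = "11"

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (3,):
            raise ValueError("proportions must be a (NAM, EUR, AFR) triple")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("each proportion must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"proportions must sum to 1 (got {p.sum()!r})")
        if self.generations_since_admixture <= 0:
            raise ValueError("generations_since_admixture must be positive")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        self.proportions = tuple(p)
        if self.marker_positions is None:
            # evenly spaced, avoiding the exact chromosome ends
            self.marker_positions = (
                (np.arange(self.n_markers) + 0.5) / self.n_markers * self.chromosome_length
            )
        self.marker_positions = np.asarray(self.marker_positions, dtype=float)
        self.n_markers = len(self.marker_positions)
        if self.n_markers < 1:
            raise ValueError("at least one marker position is required")
        if (np.diff(self.marker_positions) <= 0).any():
            raise ValueError("marker positions must be strictly increasing")
        if self.marker_positions[0] < 0 or self.marker_positions[-1] > self.chromosome_length:
            raise ValueError("marker positions must lie in [0, chromosome_length]")

    def marker_map(self) -> pd.DataFrame:
        """Marker map with base-pair positions at 1 cM/Mb (1 Morgan = 100 Mb)."""
        pos_bp = np.round(self.marker_positions * 100e6).astype(np.int64) + 1
        return pd.DataFrame(
            {
                "marker": [f"m{i:05d}" for i in range(self.n_markers)],
                "chrom": self.chrom,
                "pos": pos_bp,
                "cm": self.marker_positions * 100.0,
            }
        )


@dataclass
class AncestralFrequencies:
    """Per-marker coded-allele frequency in each parental population."""

    p_nam: np.ndarray
    p_eur: np.ndarray
    p_afr: np.ndarray

    def __post_init__(self) -> None:
        self.p_nam = np.atleast_1d(np.asarray(self.p_nam, dtype=float))
        self.p_eur = np.atleast_1d(np.asarray(self.p_eur, dtype=float))
        self.p_afr = np.atleast_1d(np.asarray(self.p_afr, dtype=float))
        if not (len(self.p_nam) == len(self.p_eur) == len(self.p_afr)):
            raise ValueError("frequency vectors must have equal length")
        for name, arr in (("p_nam", self.p_nam), ("p_eur", self.p_eur), ("p_afr", self.p_afr)):
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"{name} contains frequencies outside [0, 1]")

    @property
    def n_markers(self) -> int:
        return len(self.p_nam)

    def as_matrix(self) -> np.ndarray:
        """(3, M) matrix indexed by ancestry code (0=NAM, 1=EUR, 2=AFR)."""
        return np.vstack([self.p_nam, self.p_eur, self.p_afr])

    @classmethod
    def background(
        cls, n_markers: int, causal_index: int | None = None,
        causal: tuple[float, float, float] = (0.52, 0.12, 0.20),
        rng: np.random.Generator | None = None,
    ) -> "AncestralFrequencies":
        """Uniform(0.1, 0.9) background frequencies with an optional
        differentiated causal marker (defaults mirror a NAM-enriched
        triglyceride-raising allele: 0.52 / 0.12 / 0.20)."""
        rng = rng or np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, size=(3, n_markers))
        if causal_index is not None:
            p[:, causal_index] = causal
        return cls(p[0], p[1], p[2])


@dataclass
class PhenotypeModel:
    """Generative model for a triglyceride-like trait.

    The standardized trait is
    ``b_sex*(sex-1/2) + b_age*z_age + b_age2*(z_age^2-1) + b_bmi*z_bmi
    + effect*causal_dosage(centered) + N(0, resid_sd^2)``;
    the raw scale is an affine transform (``raw_mean``, ``raw_sd``).
    Medication lowers the raw value of treated individuals by
    ``med_offset`` so that an additive adjustment of +``med_offset``
    inverts it exactly.
    """

    effect_per_allele: float = 0.25
    causal_index: int = 0
    beta_sex: float = 0.20
    beta_age: float = 0.25
    beta_age2: float = 0.05
    beta_bmi: float = 0.30
    resid_sd: float = 0.60
    med_prob: float = 0.10
    med_offset: float = 20.0  # mg/dl lowered by treatment
    raw_mean: float = 174.99
    raw_sd: float = 113.39
    age_mean: float = 52.78
    age_sd: float = 10.12
    bmi_mean: float = 28.64
    bmi_sd: float = 4.91
    sex_prob: float = 0.499
    diabetes_prob: float = 0.5025
    trait: str = "TG"

    def __post_init__(self) -> None:
        if self.resid_sd <= 0:
            raise ValueError("residual standard deviation must be > 0")


def _simulate_paths(rng: np.random.Generator, model: AdmixtureModel, n_hap: int):
    """Draw ``n_hap`` haploid ancestry paths.

    Returns (positions, states, offsets, initial_states): concatenated
    sorted crossover positions per haplotype, the post-event states, the
    per-haplotype slice offsets into those arrays, and the state of the
    leading segment of each haplotype.
    """
    rate = model.generations_since_admixture
    L = model.chromosome_length
    counts = rng.poisson(rate * L, size=n_hap)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = int(offsets[-1])
    pos = rng.random(total) * L
    owner = np.repeat(np.arange(n_hap), counts)
    order = np.lexsort((pos, owner))
    pos = pos[order]
    p = np.asarray(model.proportions)
    initial = rng.choice(3, size=n_hap, p=p)
    states = rng.choice(3, size=total, p=p)
    return pos, states, offsets, initial


def simulate_local_ancestry(
    model: AdmixtureModel, n_individuals: int, seed: int
) -> AncestryMatrix:
    """Simulate diploid local-ancestry calls for ``n_individuals``.

    Two independent haploid paths are drawn per individual, evaluated at
    the marker positions, and summed into NAM copy counts; the full
    three-way haplotype truth is retained on the returned matrix. The
    number of *observed* ancestry switches per haploid path is stored in
    the ``n_switches`` attribute (shape ``(n, 2)``) for diagnostics.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = substream(seed, "ancestry")
    n_hap = 2 * n_individuals
    pos, states, offsets, initial = _simulate_paths(rng, model, n_hap)

    mpos = model.marker_positions
    M = len(mpos)
    hap_states = np.empty((n_hap, M), dtype=np.int8)
    n_switches = np.zeros(n_hap, dtype=np.int64)
    for h in range(n_hap):
        lo, hi = offsets[h], offsets[h + 1]
        seg_states = np.concatenate([[initial[h]], states[lo:hi]])
        idx = np.searchsorted(pos[lo:hi], mpos, side="right")
        hap_states[h] = seg_states[idx]
        if hi > lo:
            n_switches[h] = int(np.count_nonzero(np.diff(seg_states)))

    hap = hap_states.reshape(n_individuals, 2, M)
    nam = (hap == 0).sum(axis=1).astype(np.int8)
    eur = (hap == 1).sum(axis=1).astype(np.int8)
    afr = (hap == 2).sum(axis=1).astype(np.int8)
    am = AncestryMatrix(
        ids=np.array([f"ind{i:05d}" for i in range(n_individuals)]),
        markers=model.marker_map(),
        nam=nam,
        eur=eur,
        afr=afr,
        haplotypes=hap,
    )
    am.n_switches = n_switches.reshape(n_individuals, 2)
    return am


def simulate_genotypes(
    ancestry: AncestryMatrix, freqs: AncestralFrequencies, seed: int
) -> DosageMatrix:
    """Draw hard-call genotypes conditional on haplotype ancestry.

    Each haploid allele is Bernoulli with the frequency of the ancestry
    carried by that haplotype at that marker; the dosage is the sum over
    the two haplotypes (in {0, 1, 2}).
    """
    if ancestry.haplotypes is None:
        raise ValueError("ancestry matrix lacks haplotype truth; simulate it first")
    if freqs.n_markers != ancestry.n_markers:
        raise ValueError(
            f"frequency panel has {freqs.n_markers} markers but ancestry has "
            f"{ancestry.n_markers}"
        )
    rng = substream(seed, "genotypes")
    pmat = freqs.as_matrix()  # (3, M)
    hap = ancestry.haplotypes  # (n, 2, M)
    p_site = pmat[hap, np.arange(ancestry.n_markers)[None, None, :]]
    alleles = rng.random(hap.shape) < p_site
    dosage = alleles.sum(axis=1).astype(float)
    markers = ancestry.markers.copy()
    markers["coded"] = "A"
    markers["other"] = "G"
    return DosageMatrix(ids=ancestry.ids, markers=markers, dosage=dosage)


def simulate_phenotypes(
    genotypes: DosageMatrix,
    ancestry: AncestryMatrix,
    model: PhenotypeModel,
    seed: int,
) -> pd.DataFrame:
    """Simulate covariates and a trait with a planted causal dosage effect.

    Returns a phenotype table with columns ``iid``, ``sex``, ``age``,
    ``age2``, ``bmi``, ``diabetes``, ``trait_std`` (standardized trait,
    pre-medication), the raw trait (post-medication, e.g. ``TG``) and its
    medication flag ``TG_medication``. Ground truth (causal marker,
    effect, seed) is stored in ``DataFrame.attrs['truth']``.
    """
    if genotypes.n_individuals != ancestry.n_individuals:
        raise ValueError("genotype and ancestry matrices have different cohort sizes")
    model.__post_init__()  # re-validate in case fields were mutated
    rng = substream(seed, "phenotypes")
    n = genotypes.n_individuals
    sex = (rng.random(n) < model.sex_prob).astype(int)
    z_age = rng.standard_normal(n)
    age = model.age_mean + model.age_sd * z_age
    z_bmi = rng.standard_normal(n)
    bmi = model.bmi_mean + model.bmi_sd * z_bmi
    diabetes = (rng.random(n) < model.diabetes_prob).astype(int)

    dose = genotypes.dosage[:, model.causal_index]
    dose_c = dose - dose.mean()
    trait_std = (
        model.beta_sex * (sex - 0.5)
        + model.beta_age * z_age
        + model.beta_age2 * (z_age**2 - 1.0)
        + model.beta_bmi * z_bmi
        + model.effect_per_allele * dose_c
        + model.resid_sd * rng.standard_normal(n)
    )
    raw = model.raw_mean + model.raw_sd * trait_std
    treated = rng.random(n) < model.med_prob
    raw = np.where(treated, raw - model.med_offset, raw)

    table = pd.DataFrame(
        {
            "iid": genotypes.ids,
            "sex": sex,
            "age": age,
            "age2": age**2,
            "bmi": bmi,
            "diabetes": diabetes,
            "trait_std": trait_std,
            model.trait: raw,
            f"{model.trait}_medication": treated.astype(int),
        }
    )
    table.attrs["truth"] = {
        "causal_marker": str(genotypes.markers["marker"].iloc[model.causal_index]),
        "causal_index": int(model.causal_index),
        "effect_per_allele": float(model.effect_per_allele),
        "med_offset": float(model.med_offset),
        "seed": int(seed),
    }
    return table


def simulate_cohort(
    model: AdmixtureModel,
    freqs: AncestralFrequencies,
    phenotype_model: PhenotypeModel,
    n_individuals: int,
    seed: int,
) -> tuple[AncestryMatrix, DosageMatrix, pd.DataFrame]:
    """Convenience wrapper running all three simulation stages off one seed."""
    ancestry = simulate_local_ancestry(model, n_individuals, seed)
    genotypes = simulate_genotypes(ancestry, freqs, seed)
    phenotypes = simulate_phenotypes(genotypes, ancestry, phenotype_model, seed)
    return ancestry, genotypes, phenotypes
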