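"""Parental allele-frequency extrapolation from an admixed cohort.

Solves the mixture equation p_admixed = m_NAM*p_NAM + m_EUR*p_EUR +
m_AFR*p_AFR for the unknown Native American parental frequency, with a
delta-method standard error from the binomial sampling of the admixed
frequency (reference frequencies and admixture proportions are treated
as known).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ancestry import AncestryMatrix
from .assoc import DosageMatrix

logger = logging.getLogger("admixscan.parental")


@dataclass
class ParentalFreqProblem:
    p_adm: float
    p_eur: float
    p_afr: float
    m_nam: float
    m_eur: float
    m_afr: float
    n: int  # individuals behind p_adm (2n alleles)

    def __post_init__(self) -> None:
        for name in ("p_adm", "p_eur", "p_afr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.m_nam + self.m_eur + self.m_afr
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"admixture proportions must sum to 1 (got {total!r})")
        if self.n < 1:
            raise ValueError("sample size must be >= 1")


@dataclass
class ParentalFreqEstimate:
    estimate: float
    se: float
    raw_estimate: float
    clamped: bool


def estimate_parental_frequency(problem: ParentalFreqProblem) -> ParentalFreqEstimate:
    """Extrapolate the NAM parental frequency from the admixed frequency.

    p_hat = (p_adm - m_EUR*p_EUR - m_AFR*p_AFR) / m_NAM, clamped to
    [0, 1] with a warning flag when sampling noise pushes the raw
    estimate outside; SE = sqrt(p_adm*(1-p_adm)/(2n)) / m_NAM.
    """
    if problem.m_nam < 0.01:
        raise ValueError("target admixture proportion below 0.01: estimate unstable")
    raw = (problem.p_adm - problem.m_eur * problem.p_eur - problem.m_afr * problem.p_afr) / problem.m_nam
    clamped = not (0.0 <= raw <= 1.0)
    if clamped:
        logger.warning("parental frequency estimate %.4f outside [0, 1]; clamped", raw)
    estimate = float(np.clip(raw, 0.0, 1.0))
    var_adm = problem.p_adm * (1.0 - problem.p_adm) / (2.0 * problem.n)
    se = float(np.sqrt(var_adm) / problem.m_nam)
    return ParentalFreqEstimate(estimate=estimate, se=se, raw_estimate=float(raw), clamped=clamped)


def stratified_parental_frequency(
    genotypes: DosageMatrix, ancestry: AncestryMatrix, marker_index: int
) -> float:
    """Cross-check estimator: allele frequency on NAM-homozygous segments.

    Restricts to individuals carrying two NAM copies at the marker and
    takes their sample allele frequency, mirroring validation by direct
    genotyping of parental-population samples.
    """
    dose = genotypes.dosage[:, marker_index]
    nam2 = ancestry.nam[:, marker_index] == 2
    if nam2.sum() == 0:
        raise ValueError("no NAM-homozygous individuals at this marker")
    return float(np.nanmean(dose[nam2]) / 2.0)
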