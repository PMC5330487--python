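"""Marker quality control: MAF, Hardy-Weinberg exact test in controls,
per-group missingness, and strand-ambiguous (A/T, C/G) filters."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .assoc import DosageMatrix

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class QCConfig:
    """Marker-filter thresholds.

    A rule is disabled by setting its threshold to ``None``. The
    ``sample2`` preset raises the HWE floor to 0.01 and drops the
    missingness rule.
    """

    maf_floor: float | None = 0.01
    hwe_p_floor: float | None = 1e-4
    missingness_ceiling: float | None = 0.05
    drop_strand_ambiguous: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_floor", "hwe_p_floor", "missingness_ceiling"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")

    @classmethod
    def sample2(cls) -> "QCConfig":
        return cls(maf_floor=0.01, hwe_p_floor=0.01, missingness_ceiling=None)


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int, midp: bool = False) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Sums the probabilities of all heterozygote counts (with the observed
    allele counts fixed) no more likely than the observed one, following
    the standard exact-test construction. ``midp=True`` halves the
    probability of the observed configuration.
    """
    for v in (n_het, n_hom1, n_hom2):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het  # count of the rarer allele
    hets, logp = _hwe_log_probs(n, rare)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    tail = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    if midp:
        tail -= 0.5 * p_obs
    return float(min(tail, 1.0))


def _hwe_log_probs(n: int, rare: int) -> tuple[np.ndarray, np.ndarray]:
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    return hets, logp


def qc_filter_markers(
    genotypes: DosageMatrix,
    groups: np.ndarray | None,
    config: QCConfig,
) -> tuple[DosageMatrix, pd.DataFrame]:
    """Apply marker QC rules; return the surviving matrix and a report.

    ``groups`` is a per-individual case(1)/control(0) vector, required
    whenever the HWE (evaluated in controls) or per-group missingness
    rules are enabled. Genotypes must be hard calls for HWE. The report
    has one row per marker with a pass/fail column per rule and the
    final ``pass`` verdict; the surviving set is exactly the markers
    passing every enabled rule.
    """
    need_groups = config.hwe_p_floor is not None or config.missingness_ceiling is not None
    if need_groups and groups is None:
        raise ValueError("case/control labels required for HWE and missingness rules")
    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape[0] != genotypes.n_individuals:
            raise ValueError("group labels length does not match cohort size")

    dose = genotypes.dosage
    markers = genotypes.markers
    n_markers = genotypes.n_markers
    report = pd.DataFrame({"marker": markers["marker"].to_numpy()})

    freq = np.nanmean(dose, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    report["maf"] = maf
    report["pass_maf"] = True if config.maf_floor is None else maf >= config.maf_floor

    if config.drop_strand_ambiguous and {"coded", "other"}.issubset(markers.columns):
        pairs = list(zip(markers["coded"], markers["other"]))
        report["pass_strand"] = [p not in _AMBIGUOUS for p in pairs]
    else:
        report["pass_strand"] = True

    if config.hwe_p_floor is not None:
        controls = dose[groups == 0]
        hwe_p = np.empty(n_markers)
        for j in range(n_markers):
            g = controls[:, j]
            g = g[~np.isnan(g)]
            if not np.isin(g, [0, 1, 2]).all():
                raise ValueError("HWE test requires hard-call genotypes (0/1/2)")
            hwe_p[j] = hwe_exact_test(
                int((g == 1).sum()), int((g == 0).sum()), int((g == 2).sum())
            )
        report["hwe_p"] = hwe_p
        report["pass_hwe"] = hwe_p >= config.hwe_p_floor
    else:
        report["pass_hwe"] = True

    if config.missingness_ceiling is not None:
        miss_pass = np.ones(n_markers, dtype=bool)
        for label in np.unique(groups):
            rate = np.isnan(dose[groups == label]).mean(axis=0)
            miss_pass &= rate <= config.missingness_ceiling
        report["pass_missingness"] = miss_pass
    else:
        report["pass_missingness"] = True

    report["pass"] = (
        report["pass_maf"] & report["pass_strand"] & report["pass_hwe"] & report["pass_missingness"]
    )
    keep = report["pass"].to_numpy()
    filtered = DosageMatrix(
        ids=genotypes.ids,
        markers=markers.loc[keep].reset_index(drop=True),
        dosage=dose[:, keep],
    )
    return filtered, report
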