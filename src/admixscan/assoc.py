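"""Additive-dosage association scans and inverse-variance fixed-effects meta-analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("admixscan.assoc")

SUMMARY_COLUMNS = ["variant", "chrom", "pos", "coded", "other", "freq", "beta", "se", "p", "n", "cohort"]


@dataclass
class DosageMatrix:
    """Genotype dosages of the coded allele, real-valued in [0, 2].

    ``markers`` columns: marker, chrom, pos, and (for allele-aware
    operations) coded and other alleles.
    """

    ids: np.ndarray
    markers: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.ids)} ids and {len(self.markers)} markers"
            )
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and ((finite < 0).any() or (finite > 2).any()):
            raise ValueError("dosages must lie in [0, 2]")
        if {"coded", "other"}.issubset(self.markers.columns):
            same = self.markers["coded"] == self.markers["other"]
            if same.any():
                raise ValueError("coded and other alleles must differ")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def column(self, marker: str) -> np.ndarray:
        idx = self.markers.index[self.markers["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"marker {marker!r} not found")
        return self.dosage[:, int(idx[0])]

    def allele_frequency(self) -> np.ndarray:
        return np.nanmean(self.dosage, axis=0) / 2.0


def snp_association_scan(
    dosages: DosageMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    cohort: str = "cohort1",
) -> pd.DataFrame:
    """Additive OLS association of a transformed phenotype with each dosage.

    Fits phenotype ~ intercept + dosage (+ covariates) per marker by
    ordinary least squares on expected dosage (the score-test analogue
    for linear traits on complete data). Monomorphic or all-missing
    markers are flagged with NaN statistics. Returns a summary-statistic
    frame with columns marker/chrom/pos/coded/other/freq/beta/se/p/n/cohort
    plus a ``flag`` column.
    """
    y_all = np.asarray(phenotype, dtype=float)
    if y_all.shape[0] != dosages.n_individuals:
        raise ValueError("phenotype length does not match cohort size")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != dosages.n_individuals:
            raise ValueError("covariate rows do not match cohort size")

    rows = []
    for j in range(dosages.n_markers):
        x = dosages.dosage[:, j]
        mask = ~np.isnan(x) & ~np.isnan(y_all)
        if covariates is not None:
            mask &= ~np.isnan(covariates).any(axis=1)
        n = int(mask.sum())
        flag, beta, se, p, freq = "ok", np.nan, np.nan, np.nan, np.nan
        if n < 10:
            flag = "too_few_complete_cases" if n > 0 else "all_missing"
        else:
            xm, ym = x[mask], y_all[mask]
            freq = xm.mean() / 2.0
            if xm.var() <= 0:
                flag = "monomorphic"
            else:
                cols = [np.ones(n), xm]
                if covariates is not None:
                    cols.append(covariates[mask])
                design = np.column_stack(cols)
                coef, *_ = np.linalg.lstsq(design, ym, rcond=None)
                resid = ym - design @ coef
                dof = n - design.shape[1]
                sigma2 = resid @ resid / dof if dof > 0 else 0.0
                xtx_inv = np.linalg.inv(design.T @ design)
                beta = float(coef[1])
                se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
                if se > 0:
                    tstat = beta / se
                    p = float(2.0 * stats.t.sf(abs(tstat), dof))
                else:
                    p = float(np.finfo(float).tiny)  # noiseless fit: numerical floor
        m = dosages.markers.iloc[j]
        rows.append(
            {
                "variant": m["marker"],
                "chrom": m.get("chrom", "NA"),
                "pos": m.get("pos", -1),
                "coded": m.get("coded", "A"),
                "other": m.get("other", "B"),
                "freq": freq,
                "beta": beta,
                "se": se,
                "p": p,
                "n": n,
                "cohort": cohort,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def _harmonize(ref: pd.Series, row: pd.Series) -> float | None:
    """Return sign multiplier aligning ``row`` to the reference alleles.

    +1 for identical coding, -1 for a coded/other swap, None otherwise.
    """
    if row["coded"] == ref["coded"] and row["other"] == ref["other"]:
        return 1.0
    if row["coded"] == ref["other"] and row["other"] == ref["coded"]:
        return -1.0
    return None


def inverse_variance_meta(stats_list: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effects inverse-variance meta-analysis across cohorts.

    Cohort effects are aligned on variant id and coded allele (a
    coded/other swap flips the sign of beta and reflects the frequency);
    an allele mismatch that is not a swap drops the variant with a
    warning. Weights are 1/SE^2; the meta p-value is two-sided normal.
    Cochran's Q and its degrees of freedom are reported descriptively.
    """
    if not stats_list:
        raise ValueError("need at least one cohort")
    frames = [df[np.isfinite(df["beta"]) & np.isfinite(df["se"]) & (df["se"] > 0)] for df in stats_list]
    variants: dict[str, list[pd.Series]] = {}
    order: list[str] = []
    for df in frames:
        for _, row in df.iterrows():
            v = row["variant"]
            if v not in variants:
                variants[v] = []
                order.append(v)
            variants[v].append(row)

    rows = []
    for v in order:
        entries = variants[v]
        ref = entries[0]
        betas, ses, freqs, ns = [], [], [], []
        dropped = False
        for row in entries:
            sign = _harmonize(ref, row)
            if sign is None:
                logger.warning("variant %s dropped: allele mismatch that is not a flip", v)
                dropped = True
                break
            betas.append(sign * row["beta"])
            ses.append(row["se"])
            freqs.append(row["freq"] if sign > 0 else 1.0 - row["freq"])
            ns.append(row["n"])
        if dropped:
            continue
        w = 1.0 / np.asarray(ses) ** 2
        b = np.asarray(betas)
        beta_meta = float(np.sum(w * b) / np.sum(w))
        se_meta = float(np.sum(w) ** -0.5)
        z = beta_meta / se_meta
        p = float(2.0 * stats.norm.sf(abs(z)))
        q = float(np.sum(w * (b - beta_meta) ** 2))
        n_total = int(np.nansum(ns))
        freqs_arr = np.asarray(freqs, dtype=float)
        freq_meta = float(np.average(freqs_arr, weights=ns)) if np.isfinite(freqs_arr).all() else np.nan
        rows.append(
            {
                "variant": v,
                "chrom": ref["chrom"],
                "pos": ref["pos"],
                "coded": ref["coded"],
                "other": ref["other"],
                "freq": freq_meta,
                "beta": beta_meta,
                "se": se_meta,
                "p": p,
                "n": n_total,
                "cohort": "meta",
                "n_cohorts": len(betas),
                "cochran_q": q,
                "q_df": len(betas) - 1,
            }
        )
    return pd.DataFrame(rows)
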