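"""Phenotype preparation: medication adjustment, covariate residualization,
and the Blom rank-based inverse-normal transform."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("admixscan.phenotype")

#: Shipped additive adjustment defaults (mg/dl added back to treated values).
#: These are configurable placeholders documented in the run record, not
#: literature constants; HDL-lowering treatment is not adjusted.
DEFAULT_MEDICATION_ADJUSTMENT: dict[str, dict[str, float]] = {
    "TC": {"offset": 40.0},
    "LDL": {"offset": 30.0},
    "TG": {"offset": 20.0},
    "HDL": {"offset": 0.0},
}

DEFAULT_COVARIATES = ("sex", "age", "age2", "bmi")


def adjust_for_medication(
    table: pd.DataFrame,
    adjustment_config: dict[str, dict[str, float]] | None = None,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Undo the effect of lipid-lowering medication on raw trait values.

    For each trait named in ``adjustment_config``, treated individuals
    (per-trait flag column ``<trait>_medication``) have their raw value
    replaced by the configured rule output: an additive ``offset`` or a
    multiplicative ``factor``. The adjusted value is written to
    ``<trait>_adj`` and the rule that fired is recorded in
    ``<trait>_adj_rule``. Missing medication flags are treated as
    untreated, with the count logged.
    """
    explicit = adjustment_config is not None
    config = adjustment_config if explicit else DEFAULT_MEDICATION_ADJUSTMENT
    out = table.copy()
    for trait, rule in config.items():
        if traits is not None and trait not in traits:
            continue
        if trait not in out.columns:
            if not explicit and traits is None:
                continue  # shipped defaults cover traits not in this table
            raise KeyError(f"unknown trait {trait!r} in medication adjustment config")
        if not ({"offset", "factor"} & set(rule)):
            raise ValueError(f"rule for {trait!r} must define 'offset' or 'factor'")
        flag_col = f"{trait}_medication"
        if flag_col in out.columns:
            flags = out[flag_col]
            n_missing = int(flags.isna().sum())
            if n_missing:
                logger.warning(
                    "%d individuals have a missing %s flag; treated as untreated",
                    n_missing, flag_col,
                )
            treated = flags.fillna(0).astype(float).to_numpy() > 0
        else:
            treated = np.zeros(len(out), dtype=bool)
        values = out[trait].astype(float).to_numpy()
        if "offset" in rule:
            adjusted = np.where(treated, values + float(rule["offset"]), values)
            label = f"offset+{rule['offset']:g}"
        else:
            adjusted = np.where(treated, values * float(rule["factor"]), values)
            label = f"factor*{rule['factor']:g}"
        rule_made_negative = treated & ~np.isnan(values) & (values >= 0) & (adjusted < 0)
        if rule_made_negative.any():
            raise ValueError(f"medication adjustment produced a negative {trait} concentration")
        out[f"{trait}_adj"] = adjusted
        out[f"{trait}_adj_rule"] = np.where(treated, label, "none")
    if traits is not None:
        missing = [t for t in traits if t not in config]
        if missing:
            raise KeyError(f"traits {missing} absent from medication adjustment config")
    return out


def residualize_covariates(
    table: pd.DataFrame, trait: str, covariates: list[str] = list(DEFAULT_COVARIATES)
) -> pd.DataFrame:
    """Store OLS residuals of ``trait`` on intercept + ``covariates``.

    Individuals with any missing value among trait/covariates are
    excluded from the fit and flagged (residual NaN,
    ``<trait>_resid_excluded`` = 1). Zero-variance covariates are dropped
    (they are absorbed by the intercept); a genuinely rank-deficient
    design raises with the offending columns named.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not present in phenotype table")
    missing_cov = [c for c in covariates if c not in table.columns]
    if missing_cov:
        raise KeyError(f"covariates absent from table: {missing_cov}")

    y_all = table[trait].astype(float).to_numpy()
    X_cov = table[list(covariates)].astype(float).to_numpy() if covariates else np.empty((len(table), 0))
    complete = ~np.isnan(y_all)
    if X_cov.size:
        complete &= ~np.isnan(X_cov).any(axis=1)
    kept_cols = [c for c in covariates if np.nanstd(table[c].astype(float)) > 0]
    X = table[kept_cols].astype(float).to_numpy()[complete] if kept_cols else np.empty((complete.sum(), 0))
    y = y_all[complete]
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"only {n} complete cases for {k} covariates; need at least {k + 2}")

    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = _collinear_columns(design, ["(intercept)", *kept_cols])
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {collinear}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef

    out = table.copy()
    resid_full = np.full(len(table), np.nan)
    resid_full[complete] = resid
    out[f"{trait}_resid"] = resid_full
    out[f"{trait}_resid_excluded"] = (~complete).astype(int)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("residualize_covariates(%s): %d incomplete cases excluded", trait, n_excluded)
    return out


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    # Greedily identify columns that add no rank.
    bad, basis = [], np.empty((design.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([basis, design[:, j]])
        if np.linalg.matrix_rank(cand) == basis.shape[1]:
            bad.append(name)
        else:
            basis = cand
    return bad


def blom_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Blom rank-based inverse-normal transform.

    A non-missing value with (average, tie-aware) rank r among n maps to
    ``Phi^-1((r - 3/8) / (n + 1/4))``; missing values stay missing.
    Raises if fewer than 2 non-missing values remain or if all values
    are identical (a single tie block leaves the transform undefined).
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("Blom transform needs at least 2 non-missing values")
    obs = arr[mask]
    if np.all(obs == obs[0]):
        raise ValueError("all values identical: Blom transform undefined")
    ranks = stats.rankdata(obs, method="average")
    out[mask] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def prepare_trait(
    table: pd.DataFrame,
    trait: str,
    covariates: list[str] = list(DEFAULT_COVARIATES),
    adjustment_config: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Full preparation pipeline for one trait.

    Medication adjustment -> covariate residualization of the adjusted
    value -> Blom transform; the analysis-ready column is
    ``<trait>_blom``.
    """
    out = adjust_for_medication(table, adjustment_config, traits=[trait])
    out = residualize_covariates(out, f"{trait}_adj", covariates)
    out = out.rename(columns={f"{trait}_adj_resid": f"{trait}_resid",
                              f"{trait}_adj_resid_excluded": f"{trait}_resid_excluded"})
    out[f"{trait}_blom"] = blom_transform(out[f"{trait}_resid"])
    return out
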