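"""Approximate Bayes factors and 99% credible sets from regional summary statistics.

All Bayes-factor arithmetic is carried out in log space; posteriors are
normalized with log-sum-exp so regions with |z| of 40 or more remain
stable. Two ABF forms are provided: the default includes the square-root
shrinkage prefactor sqrt(V/(V+omega)); the alternative ``as_printed``
form uses the bare ratio V/(V+omega). Under equal V across variants the
two forms give identical rankings and credible sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

_LAMBDA_CAP = 1e300


def log_abf(
    beta: np.ndarray | float,
    variance: np.ndarray | float,
    omega: float = 0.04,
    form: str = "sqrt",
) -> np.ndarray | float:
    """Natural log of the approximate Bayes factor for an allelic effect.

    log L = c*log(V/(V+omega)) + omega*beta^2 / (2*V*(V+omega)),
    with c = 1/2 for ``form='sqrt'`` (default) and c = 1 for
    ``form='as_printed'``.
    """
    beta = np.asarray(beta, dtype=float)
    V = np.asarray(variance, dtype=float)
    if np.any(V <= 0):
        raise ValueError("variance must be positive")
    if omega <= 0:
        raise ValueError("omega must be positive")
    if form not in ("sqrt", "as_printed"):
        raise ValueError(f"unknown ABF form {form!r}; use 'sqrt' or 'as_printed'")
    c = 0.5 if form == "sqrt" else 1.0
    out = c * np.log(V / (V + omega)) + omega * beta**2 / (2.0 * V * (V + omega))
    return out if out.ndim else float(out)


def approximate_bayes_factor(
    beta: float, variance: float, omega: float = 0.04, form: str = "sqrt"
) -> float:
    """Approximate Bayes factor, capped at 1e300 on output.

    Use :func:`log_abf` directly when the magnitude matters.
    """
    with np.errstate(over="ignore"):
        return float(min(np.exp(log_abf(beta, variance, omega, form)), _LAMBDA_CAP))


@dataclass
class CredibleSet:
    """Ranked credible set: the minimal Bayes-factor-ordered prefix whose
    cumulative posterior strictly exceeds ``mass``."""

    variants: list[str]  # full ranking, descending Bayes factor
    posterior: np.ndarray  # aligned with `variants`
    cumulative: np.ndarray
    mass: float
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


def fine_map(
    stats: pd.DataFrame,
    omega: float = 0.04,
    mass: float = 0.99,
    form: str = "sqrt",
) -> tuple[pd.DataFrame, CredibleSet]:
    """Compute per-variant ABFs, posteriors, and the credible set.

    ``stats`` needs columns ``variant``, ``beta``, ``se`` (one region).
    Returns the annotated table (lambda, log_lambda, posterior,
    cumulative, rank, in_credible_set — in ranking order) and the
    :class:`CredibleSet`. Ties in the Bayes factor are broken
    lexicographically by variant id.
    """
    if len(stats) == 0:
        raise ValueError("empty region: nothing to fine-map")
    if stats["variant"].duplicated().any():
        raise ValueError("duplicate variant ids in region")
    se = stats["se"].to_numpy(dtype=float)
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("all standard errors must be positive and finite")
    beta = stats["beta"].to_numpy(dtype=float)
    V = se**2
    log_lam = np.asarray(log_abf(beta, V, omega, form), dtype=float).reshape(-1)
    log_post = log_lam - logsumexp(log_lam)
    posterior = np.exp(log_post)

    df = stats.copy().reset_index(drop=True)
    df["log_lambda"] = log_lam
    df["lambda"] = np.minimum(np.exp(np.minimum(log_lam, np.log(_LAMBDA_CAP))), _LAMBDA_CAP)
    df["posterior"] = posterior
    df = df.sort_values(
        ["log_lambda", "variant"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["cumulative"] = df["posterior"].cumsum()
    # minimal prefix whose cumulative mass strictly exceeds the threshold
    exceeding = np.flatnonzero(df["cumulative"].to_numpy() > mass)
    cut = int(exceeding[0]) + 1 if len(exceeding) else len(df)
    df["in_credible_set"] = df["rank"] <= cut
    cs = CredibleSet(
        variants=df["variant"].tolist(),
        posterior=df["posterior"].to_numpy(),
        cumulative=df["cumulative"].to_numpy(),
        mass=mass,
        members=df["variant"].iloc[:cut].tolist(),
    )
    return df, cs


def credible_set(stats: pd.DataFrame, omega: float = 0.04, mass: float = 0.99, form: str = "sqrt") -> CredibleSet:
    """Credible set only; see :func:`fine_map`."""
    return fine_map(stats, omega=omega, mass=mass, form=form)[1]
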