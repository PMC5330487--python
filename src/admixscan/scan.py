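"""Per-marker local-ancestry association scan with Max(T) permutation FWER.

The scan fits, marker by marker, OLS of the transformed trait on
intercept + NAM copies + global NAM + global AFR + diabetes
[+ conditioning genotype dosages]. Max(T) permutes the phenotype vector
as whole labels against the joint regressor rows; each permutation
records the maximum |t| over markers, and the empirical p-value of
marker j is (1 + #{permutations with max |t| >= |t_j|}) / (B + 1).

Implementation uses the Frisch-Waugh projection: shared covariates are
swept out of the phenotype and each marker column once, after which all
per-marker statistics (and all permutations) reduce to matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .ancestry import AncestryMatrix, GlobalAncestry

_VAR_FLOOR = 1e-12


@dataclass
class ScanResult:
    """Per-marker scan output plus run metadata.

    ``table`` columns: marker, chrom, pos, beta, se, t, p_asymptotic,
    p_empirical (NaN unless permutations were run), n_used, flag
    ("ok", "zero_variance", "collinear_with_conditioning").
    """

    table: pd.DataFrame
    n_permutations: int = 0
    seed: int | None = None
    covariates: tuple[str, ...] = ()
    condition_on: tuple[str, ...] = ()
    max_t_distribution: np.ndarray | None = field(default=None, repr=False)

    @property
    def min_empirical_p(self) -> float:
        return float(np.nanmin(self.table["p_empirical"].to_numpy()))

    @property
    def min_asymptotic_p(self) -> float:
        return float(np.nanmin(self.table["p_asymptotic"].to_numpy()))


def _build_design(
    ancestry: AncestryMatrix,
    phenotype: np.ndarray,
    global_ancestry: GlobalAncestry | None,
    diabetes: np.ndarray | None,
    condition_on: np.ndarray | None,
):
    y = np.asarray(phenotype, dtype=float)
    n = ancestry.n_individuals
    if y.shape[0] != n:
        raise ValueError("phenotype length does not match cohort size")
    cov_cols: list[np.ndarray] = [np.ones(n)]
    cov_names = ["intercept"]
    if global_ancestry is not None:
        if len(global_ancestry.m_nam) != n:
            raise ValueError("global ancestry length does not match cohort size")
        cov_cols += [global_ancestry.m_nam, global_ancestry.m_afr]
        cov_names += ["m_nam", "m_afr"]
    if diabetes is not None:
        diabetes = np.asarray(diabetes, dtype=float)
        if diabetes.shape[0] != n:
            raise ValueError("diabetes vector length does not match cohort size")
        cov_cols.append(diabetes)
        cov_names.append("diabetes")
    cond = None
    if condition_on is not None:
        cond = np.asarray(condition_on, dtype=float)
        if cond.ndim == 1:
            cond = cond[:, None]
        if cond.shape[0] != n:
            raise ValueError("conditioning dosage length does not match cohort size")
        for j in range(cond.shape[1]):
            cov_cols.append(cond[:, j])
            cov_names.append(f"condition_{j}")
    C = np.column_stack(cov_cols)
    # drop exactly-redundant covariate columns (e.g. an all-zero
    # conditioning column), so conditioning on zeros equals no conditioning
    keep = [0]
    for j in range(1, C.shape[1]):
        cand = C[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    C = C[:, keep]
    cov_names = [cov_names[j] for j in keep]

    mask = ~np.isnan(y)
    if C.size:
        mask &= ~np.isnan(C).any(axis=1)
    return y, C, cov_names, mask, cond


def _marker_stats(Xr, yr, sxx, df):
    """t statistics for residualized markers against one residualized y."""
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (Xr.T @ yr) / sxx
        rss = np.maximum(yr @ yr - beta**2 * sxx, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    # noiseless edge cases: a zero-signal fit has t = 0 (p = 1), an exact
    # fit reports t = +/-inf (p at the numerical floor)
    t = np.where((se == 0) & (beta == 0), 0.0, t)
    t = np.where((se == 0) & (beta != 0), np.sign(beta) * np.inf, t)
    return beta, se, t


def ancestry_regression_scan(
    ancestry: AncestryMatrix,
    phenotype: np.ndarray,
    global_ancestry: GlobalAncestry | None = None,
    diabetes: np.ndarray | None = None,
    condition_on: np.ndarray | None = None,
) -> ScanResult:
    """Asymptotic per-marker scan (no permutations).

    Markers whose NAM-dosage variance (raw, or after sweeping out the
    covariates) falls below 1e-12 are skipped and flagged rather than
    errored; a conditioning column perfectly collinear with the tested
    dosage flags the marker as ``collinear_with_conditioning``.
    """
    y, C, cov_names, mask, cond = _build_design(
        ancestry, phenotype, global_ancestry, diabetes, condition_on
    )
    X = ancestry.nam.astype(float)
    mask &= ~np.isnan(X).any(axis=1)
    n_used = int(mask.sum())
    p_cov = C.shape[1]
    if n_used < p_cov + 3:
        raise ValueError(f"only {n_used} complete cases for {p_cov} covariates; need {p_cov + 3}")
    y, C, X = y[mask], C[mask], X[mask]
    cond_m = cond[mask] if cond is not None else None

    Q, _ = np.linalg.qr(C)
    yr = y - Q @ (Q.T @ y)
    Xr = X - Q @ (Q.T @ X)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    raw_var = X.var(axis=0)
    df = n_used - p_cov - 1

    constant_y = float(np.var(y)) == 0.0

    flags = np.full(ancestry.n_markers, "ok", dtype=object)
    flags[raw_var < _VAR_FLOOR] = "zero_variance"
    # collinear with conditioning: raw variance fine but residual variance gone
    collinear = (raw_var >= _VAR_FLOOR) & (sxx < _VAR_FLOOR * n_used)
    if cond_m is not None:
        flags[collinear] = "collinear_with_conditioning"
    else:
        flags[collinear] = "zero_variance"
    ok = flags == "ok"

    if constant_y:
        # no signal is possible: report zero effects with p = 1
        beta = np.zeros(ancestry.n_markers)
        se = np.zeros(ancestry.n_markers)
        t = np.zeros(ancestry.n_markers)
        p_asym = np.ones(ancestry.n_markers)
    else:
        beta, se, t = _marker_stats(Xr, yr, sxx, df)
        p_asym = 2.0 * stats.t.sf(np.abs(t), df)
    for arr in (beta, se, t, p_asym):
        arr[~ok] = np.nan

    table = pd.DataFrame(
        {
            "marker": ancestry.markers["marker"].to_numpy(),
            "chrom": ancestry.markers["chrom"].to_numpy(),
            "pos": ancestry.markers["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "t": t,
            "p_asymptotic": p_asym,
            "p_empirical": np.nan,
            "n_used": n_used,
            "flag": flags,
        }
    )
    return ScanResult(table=table, covariates=tuple(cov_names[1:]))


def maxt_permutation(
    ancestry: AncestryMatrix,
    phenotype: np.ndarray,
    global_ancestry: GlobalAncestry | None = None,
    diabetes: np.ndarray | None = None,
    condition_on: np.ndarray | None = None,
    B: int = 10000,
    seed: int = 0,
) -> ScanResult:
    """Label-swapping Max(T) permutation scan.

    Runs the asymptotic scan, then permutes the phenotype vector B times
    against the joint regressor rows, recording per permutation the
    maximum |t| over non-flagged markers. Empirical p-values follow the
    (k+1)/(B+1) convention, so they are never below 1/(B+1).
    """
    if B < 1:
        raise ValueError("permutation count B must be >= 1")
    result = ancestry_regression_scan(ancestry, phenotype, global_ancestry, diabetes, condition_on)

    y, C, _, mask, cond = _build_design(
        ancestry, phenotype, global_ancestry, diabetes, condition_on
    )
    X = ancestry.nam.astype(float)
    mask &= ~np.isnan(X).any(axis=1)
    y, C, X = y[mask], C[mask], X[mask]
    n = len(y)
    Q, _ = np.linalg.qr(C)
    Xr = X - Q @ (Q.T @ X)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    df = n - C.shape[1] - 1
    ok = (result.table["flag"] == "ok").to_numpy()

    rng = substream(seed, "permutations")
    # permutations in blocks to bound memory at ~n x 512 doubles
    t_obs = np.abs(result.table["t"].to_numpy()[ok])
    Xr_ok, sxx_ok = Xr[:, ok], sxx[ok]
    max_t = np.empty(B)
    done = 0
    while done < B:
        b = min(512, B - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        Yp = y[idx].T  # (n, b)
        Yr = Yp - Q @ (Q.T @ Yp)
        num = Xr_ok.T @ Yr  # (M_ok, b)
        yy = np.einsum("ij,ij->j", Yr, Yr)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = np.maximum(yy[None, :] - num**2 / sxx_ok[:, None], 0.0)
            t2 = np.where(rss > 0, num**2 * df / (sxx_ok[:, None] * rss), np.inf)
        max_t[done : done + b] = np.sqrt(t2.max(axis=0))
        done += b

    exceed = (max_t[None, :] >= t_obs[:, None]).sum(axis=1)
    p_emp_ok = (1.0 + exceed) / (B + 1.0)
    p_emp = np.full(ancestry.n_markers, np.nan)
    p_emp[ok] = p_emp_ok
    table = result.table.copy()
    table["p_empirical"] = p_emp
    return ScanResult(
        table=table,
        n_permutations=B,
        seed=seed,
        covariates=result.covariates,
        condition_on=result.condition_on,
        max_t_distribution=max_t,
    )
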