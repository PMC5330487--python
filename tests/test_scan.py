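import itertools

import numpy as np
import pytest
from scipy import stats

from admixscan import (
    AdmixtureModel,
    AncestralFrequencies,
    PhenotypeModel,
    ancestry_regression_scan,
    global_ancestry_from_local,
    maxt_permutation,
    simulate_cohort,
    simulate_local_ancestry,
)

from conftest import CAUSAL_FREQS, PAPER_PROPORTIONS, make_ancestry


def seeded_scan_inputs(seed=13, n=200, M=20):
    model = AdmixtureModel(proportions=PAPER_PROPORTIONS, n_markers=M)
    am = simulate_local_ancestry(model, n, seed=seed)
    ga = global_ancestry_from_local(am)
    rng = np.random.default_rng(seed + 1)
    diabetes = rng.integers(0, 2, n)
    y = rng.standard_normal(n)
    return am, ga, diabetes, y


class TestAncestryRegressionScan:
    def test_constant_phenotype_no_signal(self):
        am, ga, diabetes, _ = seeded_scan_inputs()
        res = ancestry_regression_scan(am, np.full(200, 2.5), ga, diabetes)
        ok = res.table["flag"] == "ok"
        assert (res.table.loc[ok, "beta"] == 0).all()
        assert (res.table.loc[ok, "p_asymptotic"] == 1).all()

    def test_matches_normal_equations_oracle(self):
        am, ga, diabetes, y = seeded_scan_inputs()
        res = ancestry_regression_scan(am, y, ga, diabetes)
        for j in range(am.n_markers):
            if res.table["flag"].iloc[j] != "ok":
                continue
            # independent per-marker OLS oracle via the normal equations
            D = np.column_stack(
                [np.ones(200), am.nam[:, j].astype(float), ga.m_nam, ga.m_afr, diabetes]
            )
            DtD_inv = np.linalg.inv(D.T @ D)
            coef = DtD_inv @ (D.T @ y)
            resid = y - D @ coef
            dof = 200 - D.shape[1]
            se = np.sqrt(resid @ resid / dof * DtD_inv[1, 1])
            assert res.table["beta"].iloc[j] == pytest.approx(coef[1], rel=1e-10)
            assert res.table["se"].iloc[j] == pytest.approx(se, rel=1e-10)
            p = 2 * stats.t.sf(abs(coef[1] / se), dof)
            assert res.table["p_asymptotic"].iloc[j] == pytest.approx(p, rel=1e-8)

    def test_zero_variance_marker_flagged(self):
        nam = np.ones((30, 3), dtype=int)
        nam[:, 0] = np.repeat([0, 1, 2], 10)
        nam[:, 2] = np.tile([0, 1, 2], 10)
        am = make_ancestry(nam)
        rng = np.random.default_rng(0)
        res = ancestry_regression_scan(am, rng.standard_normal(30))
        assert res.table["flag"].iloc[1] == "zero_variance"
        assert np.isnan(res.table["beta"].iloc[1])
        assert (res.table["flag"].iloc[[0, 2]] == "ok").all()

    def test_collinear_conditioning_flagged(self):
        am, ga, diabetes, y = seeded_scan_inputs()
        cond = am.nam[:, 4].astype(float)
        res = ancestry_regression_scan(am, y, ga, diabetes, condition_on=cond)
        assert res.table["flag"].iloc[4] == "collinear_with_conditioning"
        assert np.isnan(res.table["beta"].iloc[4])

    def test_dimension_mismatch(self):
        am, ga, diabetes, y = seeded_scan_inputs()
        with pytest.raises(ValueError, match="phenotype length"):
            ancestry_regression_scan(am, y[:-1], ga, diabetes)

    def test_conditioning_on_zero_column_is_noop(self):
        am, ga, diabetes, y = seeded_scan_inputs()
        a = ancestry_regression_scan(am, y, ga, diabetes)
        b = ancestry_regression_scan(am, y, ga, diabetes, condition_on=np.zeros(200))
        np.testing.assert_array_equal(a.table["beta"], b.table["beta"])
        np.testing.assert_array_equal(a.table["p_asymptotic"], b.table["p_asymptotic"])

    def test_conditioning_attenuates_planted_signal(self):
        model = AdmixtureModel(proportions=PAPER_PROPORTIONS, n_markers=30)
        freqs = AncestralFrequencies.background(30, causal_index=15, causal=CAUSAL_FREQS)
        pm = PhenotypeModel(effect_per_allele=0.25, causal_index=15)
        wins = 0
        for seed in range(10):
            ancestry, genotypes, phenotypes = simulate_cohort(model, freqs, pm, 2000, seed=seed)
            ga = global_ancestry_from_local(ancestry)
            y = phenotypes["trait_std"].to_numpy()
            diabetes = phenotypes["diabetes"].to_numpy()
            plain = ancestry_regression_scan(ancestry, y, ga, diabetes)
            cond = ancestry_regression_scan(
                ancestry, y, ga, diabetes, condition_on=genotypes.dosage[:, 15]
            )
            wins += cond.min_asymptotic_p > plain.min_asymptotic_p
        assert wins >= 9


def exhaustive_maxt_oracle(X, y, C):
    """Exact Max(T) reference: enumerate every label permutation."""
    n, M = X.shape

    def tstats(yv):
        out = np.empty(M)
        for j in range(M):
            D = np.column_stack([C, X[:, j]])
            coef, *_ = np.linalg.lstsq(D, yv, rcond=None)
            resid = yv - D @ coef
            dof = n - D.shape[1]
            sigma2 = resid @ resid / dof
            cov = np.linalg.inv(D.T @ D) * sigma2
            out[j] = coef[-1] / np.sqrt(cov[-1, -1])
        return out

    t_obs = np.abs(tstats(y))
    maxima = []
    for perm in itertools.permutations(range(n)):
        maxima.append(np.abs(tstats(y[list(perm)])).max())
    maxima = np.asarray(maxima)
    # count exact ties as exceeding: many of the 720 permutations reproduce
    # the observed arrangement up to an ulp, and the Monte-Carlo estimator's
    # >= comparison counts them
    return t_obs, np.array([(maxima >= t - 1e-9).mean() for t in t_obs])


class TestMaxTPermutation:
    def test_empirical_p_floor_when_observed_dominates(self):
        # plant a noiseless signal: observed |t| is infinite, so no
        # permuted maximum can reach it
        am, ga, diabetes, _ = seeded_scan_inputs()
        y = am.nam[:, 3].astype(float)
        res = maxt_permutation(am, y, ga, diabetes, B=999, seed=5)
        assert res.table["p_empirical"].iloc[3] == pytest.approx(1 / 1000)

    def test_empirical_p_one_for_weakest_marker(self):
        am, ga, diabetes, y = seeded_scan_inputs(seed=29, n=300, M=50)
        res = maxt_permutation(am, y, ga, diabetes, B=200, seed=6)
        ok = res.table["flag"] == "ok"
        weakest = res.table.loc[ok, "t"].abs().idxmin()
        assert res.table["p_empirical"].loc[weakest] == 1.0

    def test_matches_exhaustive_enumeration(self):
        # n=6, 3 markers: Monte-Carlo empirical p within 0.02 of the
        # exact value over all 720 label permutations
        rng = np.random.default_rng(99)
        nam = np.array(
            [[0, 1, 2], [1, 0, 1], [2, 2, 0], [1, 1, 1], [0, 2, 2], [2, 0, 1]], dtype=int
        )
        nam[3] = [2, 1, 0]  # keep every marker polymorphic
        am = make_ancestry(nam)
        y = rng.standard_normal(6)
        res = maxt_permutation(am, y, B=10000, seed=1)
        C = np.ones((6, 1))
        _, p_exact = exhaustive_maxt_oracle(nam.astype(float), y, C)
        np.testing.assert_allclose(
            res.table["p_empirical"].to_numpy(), p_exact, atol=0.02
        )

    def test_deterministic_and_reorder_invariant(self):
        am, ga, diabetes, y = seeded_scan_inputs()
        a = maxt_permutation(am, y, ga, diabetes, B=100, seed=11)
        b = maxt_permutation(am, y, ga, diabetes, B=100, seed=11)
        np.testing.assert_array_equal(a.table["p_empirical"], b.table["p_empirical"])
        # reorder markers: per-marker results must follow the markers
        from admixscan import AncestryMatrix

        order = np.arange(am.n_markers)[::-1]
        markers_rev = am.markers.iloc[order].reset_index(drop=True)
        am_rev = AncestryMatrix(ids=am.ids, markers=markers_rev, nam=am.nam[:, order])
        c = maxt_permutation(am_rev, y, ga, diabetes, B=100, seed=11)
        np.testing.assert_array_equal(
            c.table["p_empirical"].to_numpy()[::-1], a.table["p_empirical"].to_numpy()
        )

    def test_empirical_p_bounds_and_monotone_in_t(self):
        am, ga, diabetes, y = seeded_scan_inputs(seed=3)
        res = maxt_permutation(am, y, ga, diabetes, B=99, seed=2)
        ok = res.table["flag"] == "ok"
        p = res.table.loc[ok, "p_empirical"]
        assert (p >= 1 / 100).all() and (p <= 1).all()
        tabs = res.table.loc[ok, "t"].abs()
        order = np.argsort(-tabs.to_numpy())
        assert (np.diff(p.to_numpy()[order]) >= 0).all()
        # the most significant marker has the smallest empirical p
        assert p.to_numpy()[order][0] == p.min()

    def test_invalid_b(self):
        am, ga, diabetes, y = seeded_scan_inputs()
        with pytest.raises(ValueError, match="B"):
            maxt_permutation(am, y, ga, diabetes, B=0, seed=1)
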