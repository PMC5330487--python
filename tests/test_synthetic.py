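import numpy as np
import pytest
from scipy import stats

from admixscan import (
    AdmixtureModel,
    AncestralFrequencies,
    PhenotypeModel,
    simulate_genotypes,
    simulate_local_ancestry,
    simulate_phenotypes,
)
from admixscan._rng import substream
from admixscan.synthetic import _simulate_paths

from conftest import CAUSAL_FREQS, PAPER_PROPORTIONS


class TestAdmixtureModel:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AdmixtureModel(proportions=(0.5, 0.4, 0.2))

    def test_positions_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AdmixtureModel(marker_positions=np.array([0.1, 0.1, 0.2]))

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            AdmixtureModel(proportions=(1.2, -0.2, 0.0))

    def test_default_positions_even(self):
        m = AdmixtureModel(n_markers=10, chromosome_length=2.0)
        assert len(m.marker_positions) == 10
        assert np.all(np.diff(m.marker_positions) > 0)
        assert m.marker_positions[-1] <= 2.0


class TestSimulateLocalAncestry:
    def test_single_ancestry_is_saturated(self):
        model = AdmixtureModel(proportions=(1.0, 0.0, 0.0), n_markers=15)
        am = simulate_local_ancestry(model, 10, seed=0)
        assert (am.nam == 2).all()
        assert (am.nam.mean(axis=1) / 2 == 1.0).all()

    def test_switch_rate_matches_analytic_expectation(self):
        # observed switch rate per haploid path is G*L*(1 - sum m_k^2)
        model = AdmixtureModel(proportions=PAPER_PROPORTIONS, generations_since_admixture=15.0,
                               chromosome_length=1.0, n_markers=10)
        am = simulate_local_ancestry(model, 2000, seed=11)
        switches = am.n_switches.ravel()
        m = np.asarray(PAPER_PROPORTIONS)
        expected = 15.0 * 1.0 * (1.0 - np.sum(m**2))
        se = switches.std(ddof=1) / np.sqrt(len(switches))
        assert abs(switches.mean() - expected) < 3 * se

    def test_cohort_global_ancestry_matches_proportions(self):
        model = AdmixtureModel(proportions=PAPER_PROPORTIONS, n_markers=50)
        am = simulate_local_ancestry(model, 2000, seed=5)
        m_nam = am.nam.mean(axis=1) / 2.0
        se = m_nam.std(ddof=1) / np.sqrt(len(m_nam))
        assert abs(m_nam.mean() - 0.6486) < 3 * se

    def test_dosages_in_support_and_companions_sum(self):
        model = AdmixtureModel(n_markers=30)
        am = simulate_local_ancestry(model, 100, seed=2)
        assert set(np.unique(am.nam)) <= {0, 1, 2}
        assert ((am.nam + am.eur + am.afr) == 2).all()

    def test_deterministic_given_seed(self):
        model = AdmixtureModel(n_markers=25)
        a = simulate_local_ancestry(model, 50, seed=123)
        b = simulate_local_ancestry(model, 50, seed=123)
        np.testing.assert_array_equal(a.nam, b.nam)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_different_seeds_differ(self):
        model = AdmixtureModel(n_markers=25)
        a = simulate_local_ancestry(model, 50, seed=1)
        b = simulate_local_ancestry(model, 50, seed=2)
        assert (a.nam != b.nam).any()

    def test_stationarity_chi2_across_runs(self):
        # marginal haplotype ancestry at one marker follows the model
        # proportions: at most 3/50 runs may reject at alpha=0.01
        model = AdmixtureModel(proportions=PAPER_PROPORTIONS, n_markers=5)
        expected = np.asarray(PAPER_PROPORTIONS) * 4000
        rejections = 0
        for seed in range(50):
            am = simulate_local_ancestry(model, 2000, seed=seed)
            states = am.haplotypes[:, :, 2].ravel()
            counts = np.bincount(states, minlength=3)
            p = stats.chisquare(counts, expected).pvalue
            rejections += p < 0.01
        assert rejections <= 3

    def test_mean_crossover_spacing_near_inverse_generations(self):
        model = AdmixtureModel(proportions=PAPER_PROPORTIONS, generations_since_admixture=15.0,
                               chromosome_length=50.0, n_markers=10,
                               marker_positions=np.linspace(1, 49, 10))
        rng = substream(0, "ancestry")
        pos, _, offsets, _ = _simulate_paths(rng, model, 40)
        gaps = np.concatenate([
            np.diff(pos[offsets[h]:offsets[h + 1]]) for h in range(40)
        ])
        se = gaps.std(ddof=1) / np.sqrt(len(gaps))
        assert abs(gaps.mean() - 1.0 / 15.0) < 3 * se

    def test_n_individuals_validated(self):
        with pytest.raises(ValueError, match="n_individuals"):
            simulate_local_ancestry(AdmixtureModel(), 0, seed=1)


class TestSimulateGenotypes:
    def test_fixed_allele_gives_dosage_two(self):
        model = AdmixtureModel(n_markers=5)
        am = simulate_local_ancestry(model, 30, seed=3)
        freqs = AncestralFrequencies(np.ones(5), np.ones(5), np.ones(5))
        g = simulate_genotypes(am, freqs, seed=3)
        assert (g.dosage == 2).all()

    def test_cohort_frequency_matches_mixture_expectation(self):
        model = AdmixtureModel(proportions=PAPER_PROPORTIONS, n_markers=3)
        am = simulate_local_ancestry(model, 2000, seed=21)
        p = CAUSAL_FREQS
        freqs = AncestralFrequencies(*(np.full(3, v) for v in p))
        g = simulate_genotypes(am, freqs, seed=21)
        expected = float(np.dot(PAPER_PROPORTIONS, p))  # ~0.382
        freq = g.dosage[:, 1].mean() / 2.0
        se = np.sqrt(expected * (1 - expected) / (2 * 2000))
        assert abs(freq - expected) < 3 * se

    def test_nam_homozygotes_show_parental_frequency(self):
        model = AdmixtureModel(proportions=PAPER_PROPORTIONS, n_markers=3)
        am = simulate_local_ancestry(model, 2000, seed=22)
        freqs = AncestralFrequencies(*(np.full(3, v) for v in CAUSAL_FREQS))
        g = simulate_genotypes(am, freqs, seed=22)
        nam2 = am.nam[:, 1] == 2
        obs = g.dosage[nam2, 1].mean() / 2.0
        se = np.sqrt(0.52 * 0.48 / (2 * nam2.sum()))
        assert abs(obs - 0.52) < 3 * se

    def test_frequency_bounds_enforced(self):
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            AncestralFrequencies(np.array([1.2]), np.array([0.5]), np.array([0.5]))

    def test_marker_count_mismatch(self):
        model = AdmixtureModel(n_markers=5)
        am = simulate_local_ancestry(model, 10, seed=1)
        freqs = AncestralFrequencies(np.full(4, 0.5), np.full(4, 0.5), np.full(4, 0.5))
        with pytest.raises(ValueError, match="markers"):
            simulate_genotypes(am, freqs, seed=1)


@pytest.fixture(scope="module")
def cohort():
    model = AdmixtureModel(proportions=PAPER_PROPORTIONS, n_markers=5)
    am = simulate_local_ancestry(model, 2000, seed=31)
    freqs = AncestralFrequencies.background(5, causal_index=2)
    g = simulate_genotypes(am, freqs, seed=31)
    return am, g


class TestSimulatePhenotypes:

    def test_null_effect_gives_null_slope(self, cohort):
        am, g = cohort
        pm = PhenotypeModel(effect_per_allele=0.0, causal_index=2)
        ph = simulate_phenotypes(g, am, pm, seed=1)
        res = stats.linregress(g.dosage[:, 2], ph["trait_std"])
        assert abs(res.slope) < 3 * res.stderr

    def test_effect_recovery_coverage(self, cohort):
        # OLS of trait on causal dosage recovers 0.25 within its 95% CI
        # in >= 90% of seeded replicates
        am, g = cohort
        pm = PhenotypeModel(effect_per_allele=0.25, causal_index=2)
        hits = 0
        for seed in range(100):
            ph = simulate_phenotypes(g, am, pm, seed=seed)
            res = stats.linregress(g.dosage[:, 2], ph["trait_std"])
            half = 1.96 * res.stderr
            hits += (res.slope - half) <= 0.25 <= (res.slope + half)
        assert hits >= 90

    def test_covariate_moments_match_defaults(self, cohort):
        am, g = cohort
        pm = PhenotypeModel(causal_index=2)
        ph = simulate_phenotypes(g, am, pm, seed=77)
        for col, mean, sd in (("age", 52.78, 10.12), ("bmi", 28.64, 4.91)):
            se = sd / np.sqrt(len(ph))
            assert abs(ph[col].mean() - mean) < 3 * se

    def test_medication_lowers_raw_value(self, cohort):
        am, g = cohort
        pm = PhenotypeModel(causal_index=2, med_prob=0.5, med_offset=30.0)
        ph = simulate_phenotypes(g, am, pm, seed=4)
        treated = ph["TG_medication"] == 1
        expected_raw = pm.raw_mean + pm.raw_sd * ph["trait_std"]
        np.testing.assert_allclose(ph.loc[treated, "TG"], expected_raw[treated] - 30.0)
        np.testing.assert_allclose(ph.loc[~treated, "TG"], expected_raw[~treated])

    def test_invalid_residual_sd(self, cohort):
        am, g = cohort
        with pytest.raises(ValueError, match="residual standard deviation"):
            simulate_phenotypes(g, am, PhenotypeModel(resid_sd=0.0), seed=1)

    def test_truth_record(self, cohort):
        am, g = cohort
        ph = simulate_phenotypes(g, am, PhenotypeModel(causal_index=2), seed=9)
        truth = ph.attrs["truth"]
        assert truth["causal_index"] == 2
        assert truth["effect_per_allele"] == 0.25
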