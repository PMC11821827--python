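"""ZOIB density, sampler correctness, diagnostics, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit

from benthovuln.trait_data import MortalityRecord, ValidationError
from benthovuln.zoib import (
    ChainPlan,
    SingleCategoryError,
    bayes_r2,
    fit_severity_model,
    fit_volume_model,
    split_rhat,
    zoib_logdensity,
    zoib_rvs,
)

from conftest import make_table, make_toy_schema

FAST_PLAN = ChainPlan(chains=2, draws=1200, warmup=500, sweeps=5)


class TestLogDensity:
    def test_uniform_beta_case(self):
        # mu=0.5, phi=2 is Beta(1,1); with no point mass the density is 1
        assert zoib_logdensity(0.5, mu=0.5, phi=2.0, p01=0.0, cond_one=0.0) == pytest.approx(0.0)

    def test_zero_mass(self):
        ld = zoib_logdensity(0.0, mu=0.5, phi=2.0, p01=0.3, cond_one=0.0)
        assert ld == pytest.approx(np.log(0.3))

    def test_one_mass(self):
        ld = zoib_logdensity(1.0, mu=0.5, phi=2.0, p01=0.4, cond_one=0.5)
        assert ld == pytest.approx(np.log(0.2))

    @pytest.mark.parametrize("mu,phi,p01,cond_one", [
        (0.5, 2.0, 0.2, 0.6),
        (0.3, 5.0, 0.0, 0.0),
        (0.8, 0.7, 0.45, 0.9),
    ])
    def test_total_mass_is_one(self, mu, phi, p01, cond_one):
        """Point masses plus the integrated continuous part sum to 1."""
        cont, _ = quad(
            lambda y: np.exp(zoib_logdensity(y, mu, phi, p01, cond_one)), 0, 1,
            epsabs=1e-12, limit=200,
        )
        mass0 = p01 * (1 - cond_one)
        mass1 = p01 * cond_one
        assert cont == pytest.approx(1 - p01, abs=1e-8)
        assert mass0 + mass1 + cont == pytest.approx(1.0, abs=1e-8)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            zoib_logdensity(0.5, mu=1.5, phi=2.0, p01=0.1, cond_one=0.1)
        with pytest.raises(ValidationError):
            zoib_logdensity(1.5, mu=0.5, phi=2.0, p01=0.1, cond_one=0.1)

    def test_rvs_moments_match_mixture(self, rng):
        mu, phi, p01, cond_one = 0.4, 6.0, 0.25, 0.8
        y = zoib_rvs(rng, np.full(200_000, mu), phi, p01, cond_one)
        expected_mean = p01 * cond_one + (1 - p01) * mu
        assert y.mean() == pytest.approx(expected_mean, abs=0.005)
        assert np.mean(y == 1.0) == pytest.approx(p01 * cond_one, abs=0.005)
        assert np.mean(y == 0.0) == pytest.approx(p01 * (1 - cond_one), abs=0.005)


class TestSplitRhat:
    def test_stationary_chains_near_one(self, rng):
        chains = rng.normal(size=(2, 4000))
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert split_rhat(chains) > 1.1

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValidationError):
            split_rhat(rng.normal(size=(1, 100)))

    def test_constant_chains_convention(self):
        with pytest.warns(UserWarning, match="constant"):
            assert split_rhat(np.ones((2, 100))) == 1.0


class TestBayesR2:
    def test_perfect_fit_approaches_one(self, rng):
        y = rng.uniform(size=50)
        assert bayes_r2(y[np.newaxis, :], y)["median"] == pytest.approx(1.0)

    def test_pure_noise_near_zero(self, rng):
        y = rng.uniform(size=2000)
        fitted = np.full((10, 2000), 0.5) + rng.normal(0, 0.01, size=(10, 2000))
        assert bayes_r2(fitted, y)["median"] < 0.05

    def test_zero_variance_fitted_rejected(self):
        with pytest.raises(ValidationError):
            bayes_r2(np.full((5, 20), 0.3), np.linspace(0.1, 0.9, 20))


def simulate_records(table, effects, rng, n=2000, baseline=-0.5, phi=8.0, p01=0.15, cone=0.6):
    """Records whose percent mortality is a discretized ZOIB draw."""
    species = table.species
    recs = []
    while len(recs) < n:
        sp = species[int(rng.integers(len(species)))]
        cat = table.signature(sp)[8]  # trait I of the toy schema
        mu = float(expit(baseline + effects.get(cat, 0.0)))
        y = float(zoib_rvs(rng, np.array(mu), phi, p01, cone, size=()))
        pct = int(round(y * 10) * 10)
        if pct < 10:
            continue
        recs.append(
            MortalityRecord(
                species=sp, phylum="Porifera", year=2000, longitude=5.0, latitude=40.0,
                depth_range="", habitat="", drivers=frozenset({"disease"}),
                percent_mortality=pct,
            )
        )
    return recs


@pytest.fixture(scope="module")
def two_category_table():
    schema = make_toy_schema()
    rows = {}
    rng = np.random.default_rng(4)
    for i in range(30):
        cat_i = "x" if i < 15 else "y"  # trait I (index 8) carries the signal
        sig = tuple(
            str(rng.choice(t.categories)) if j != 8 else cat_i
            for j, t in enumerate(schema)
        )
        rows[f"s{i:03d}"] = sig
    return make_table(rows, schema)


class TestSeverityModel:
    def test_recovers_known_category_effect(self, two_category_table):
        rng = np.random.default_rng(100)
        effects = {"x": 0.0, "y": 1.0}
        recs = simulate_records(two_category_table, effects, rng)
        post, rows = fit_severity_model(recs, two_category_table, "I", plan=FAST_PLAN, seed=8)
        assert max(post.rhat.values()) <= 1.01
        lo, hi = post.credible_interval("b[I:y]")
        assert lo < 1.0 < hi
        by_cat = {r.category: r for r in rows}
        assert by_cat["y"].mean_percent > by_cat["x"].mean_percent
        for r in rows:
            assert 0 <= r.ci_low <= r.mean_percent <= r.ci_high <= 100

    def test_null_effects_straddle_zero(self, two_category_table):
        rng = np.random.default_rng(200)
        recs = simulate_records(two_category_table, {}, rng, n=1500)
        post, _ = fit_severity_model(recs, two_category_table, "I", plan=FAST_PLAN, seed=9)
        lo, hi = post.credible_interval("b[I:y]")
        assert lo < 0.0 < hi

    def test_single_observed_category_reported(self, two_category_table):
        rng = np.random.default_rng(300)
        recs = [r for r in simulate_records(two_category_table, {}, rng, n=200)
                if two_category_table.signature(r.species)[8] == "x"]
        with pytest.raises(SingleCategoryError):
            fit_severity_model(recs, two_category_table, "I", plan=FAST_PLAN, seed=1)

    def test_identical_seed_identical_draws(self, two_category_table):
        rng = np.random.default_rng(400)
        recs = simulate_records(two_category_table, {"y": 0.5}, rng, n=600)
        p1, _ = fit_severity_model(recs, two_category_table, "I", plan=FAST_PLAN, seed=77)
        p2, _ = fit_severity_model(recs, two_category_table, "I", plan=FAST_PLAN, seed=77)
        for name in p1.draws:
            assert np.array_equal(p1.draws[name], p2.draws[name])

    def test_posterior_frequentist_calibration(self, two_category_table):
        """Rank of the true coefficient within the posterior draws is close
        to uniform over repeated simulations (flat priors make the posterior
        an approximate pivot at informative sample sizes)."""
        from scipy.stats import chisquare

        plan = ChainPlan(chains=2, draws=700, warmup=300, sweeps=4)
        true_b = 0.6
        ranks = []
        reps = 24
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            recs = simulate_records(two_category_table, {"y": true_b}, rng, n=400)
            # reduced chain plan: rhat noise at 400 kept draws/chain exceeds
            # the production gate, so relax it; mixing is not under test here
            post, _ = fit_severity_model(
                recs, two_category_table, "I", plan=plan, seed=rep, rhat_threshold=1.05
            )
            draws = post.flat("b[I:y]")
            ranks.append(np.mean(draws < true_b))
        counts, _ = np.histogram(ranks, bins=4, range=(0, 1))
        _, p = chisquare(counts)
        assert p > 0.001

    def test_bias_shrinks_with_sample_size(self, two_category_table):
        effects = {"y": 0.8}
        errs = {}
        for n in (200, 2000):
            errors = []
            for rep in range(3):
                rng = np.random.default_rng(7000 + rep)
                recs = simulate_records(two_category_table, effects, rng, n=n)
                post, _ = fit_severity_model(
                    recs, two_category_table, "I", plan=FAST_PLAN, seed=rep
                )
                errors.append(abs(post.flat("b[I:y]").mean() - 0.8))
            errs[n] = np.mean(errors)
        assert errs[2000] < errs[200]


class TestVolumeModel:
    def _simulate(self, rng, beta, n=35, intercept=-2.0, phi=30.0, p01=0.1, cone=0.2):
        X = rng.poisson(5.0, size=(n, 2)).astype(float)
        mu = expit(intercept + X @ beta)
        y = zoib_rvs(rng, mu, phi, p01, cone)
        return y, pd.DataFrame(X, columns=["disease", "storm"])

    def test_recovers_generating_coefficients(self, rng):
        beta = np.array([0.15, -0.1])
        y, X = self._simulate(rng, beta, n=120)
        plan = ChainPlan(chains=2, draws=1500, warmup=600, sweeps=15)
        post = fit_volume_model(y, X, plan=plan, seed=5)
        assert max(post.rhat.values()) <= 1.01
        for name, true in zip(["b[disease]", "b[storm]"], beta):
            lo, hi = post.credible_interval(name)
            assert lo < true < hi, (name, lo, true, hi)

    def test_zero_effect_interval_covers_zero(self, rng):
        y, X = self._simulate(rng, np.zeros(2), n=80)
        plan = ChainPlan(chains=2, draws=1200, warmup=500, sweeps=15)
        post = fit_volume_model(y, X, plan=plan, seed=6)
        for name in post.coef_names:
            lo, hi = post.credible_interval(name)
            assert lo < 0.0 < hi

    def test_requires_ten_observations(self, rng):
        y, X = self._simulate(rng, np.zeros(2), n=5)
        with pytest.raises(ValidationError):
            fit_volume_model(y, X)

    def test_all_zero_response_rejected(self):
        X = pd.DataFrame({"disease": np.arange(12, dtype=float)})
        with pytest.raises(ValidationError):
            fit_volume_model(np.zeros(12), X)
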