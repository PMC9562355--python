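"""Likelihood closed forms, standardization, R-hat and sampler behaviour."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coralfish.occupancy import (
    ModelConfig,
    PosteriorSamples,
    assemblage_mean,
    fit,
    rhat,
    site_marginal_likelihood,
    standardize,
)
from coralfish.data_io import filter_species
from coralfish.synthetic import (
    CommunityHyperparams,
    simulate_covariates,
    simulate_detection_history,
    simulate_species_params,
)


class TestStandardize:
    def test_two_points(self):
        z, (mean, sd) = standardize([0.0, 1.0])
        np.testing.assert_allclose(z, [-np.sqrt(0.5), np.sqrt(0.5)])
        assert (mean, sd) == (0.5, pytest.approx(np.sqrt(0.5)))

    def test_idempotent(self, rng):
        x = rng.normal(size=50)
        z, _ = standardize(x)
        z2, _ = standardize(z)
        np.testing.assert_allclose(z, z2, atol=1e-12)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1)

    def test_back_transform_scales_slope(self):
        # a slope of 1 per SD on a low-variance covariate is a steep
        # per-unit slope: beta_per_unit = beta_std / sd
        x = np.array([0.0, 0.1, 0.2, 0.05])  # coral-like, SD << 1%
        _, (_, sd) = standardize(x)
        assert 1.0 / sd > 10

    def test_zero_variance_names_covariate(self):
        with pytest.raises(ValueError, match="turf"):
            standardize([3.0, 3.0, 3.0], name="turf cover")


class TestSiteMarginalLikelihood:
    @pytest.mark.parametrize(
        "psi,p,y,expected",
        [
            (0.5, [0.5, 0.5], [0, 0], 0.625),
            (0.5, [0.5, 0.5], [1, 0], 0.125),
            (0.5, [0.0, 0.5], [1, 0], 0.0),
            (1.0, [0.3], [0], 0.7),
            (0.0, [0.3], [0], 1.0),
        ],
    )
    def test_closed_forms(self, psi, p, y, expected):
        assert site_marginal_likelihood(psi, p, y) == pytest.approx(expected)

    @pytest.mark.parametrize("J", [1, 2, 3, 4])
    def test_sums_to_one_over_all_histories(self, J, rng):
        # exhaustive enumeration: the 2^J histories partition probability
        for _ in range(5):
            psi = rng.random()
            p = rng.random(J)
            total = sum(
                site_marginal_likelihood(psi, p, y)
                for y in itertools.product([0, 1], repeat=J)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_rejects_invalid_probabilities(self):
        with pytest.raises(ValueError):
            site_marginal_likelihood(1.5, [0.5], [0])
        with pytest.raises(ValueError):
            site_marginal_likelihood(0.5, [1.5], [0])


class TestRhat:
    def test_identical_chains_near_one(self, rng):
        c = rng.normal(size=1000)
        assert rhat(np.stack([c, c])) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert rhat(chains) > 5

    def test_iid_draws_converge(self, rng):
        chains = rng.normal(size=(3, 5000))
        assert rhat(chains) < 1.01

    def test_constant_draws(self):
        assert rhat(np.ones((2, 100))) == 1.0

    def test_single_chain_warns(self, rng):
        with pytest.warns(UserWarning, match="single chain"):
            assert rhat(rng.normal(size=(1, 1000))) < 1.05

    def test_matches_arviz_split_rhat(self, rng):
        arviz = pytest.importorskip("arviz")
        draws = rng.normal(size=(4, 500)) + np.linspace(0, 1, 4)[:, None]
        ours = rhat(draws)
        theirs = float(arviz.rhat(draws[None].transpose(1, 2, 0)[..., 0],
                                  method="split"))
        assert ours == pytest.approx(theirs, rel=1e-6)


def _fake_posterior(beta1, beta2=None):
    """Posterior container with prescribed beta draws, (chains=1, draws, K)."""
    beta1 = np.asarray(beta1)[None]
    beta2 = beta1 if beta2 is None else np.asarray(beta2)[None]
    K = beta1.shape[2]
    return PosteriorSamples(
        species=[(f"sp{k}", "adult") for k in range(K)],
        params={"beta1": beta1, "beta2": beta2},
        config=ModelConfig(),
        coral_taxon="coral",
        covariate_scales={},
    )


class TestAssemblageMean:
    def test_identical_species_average_to_themselves(self, rng):
        d = rng.normal(size=(200, 1))
        ps = _fake_posterior(np.repeat(d, 4, axis=1))
        np.testing.assert_allclose(assemblage_mean(ps), d[:, 0])

    def test_symmetric_pair_cancels(self):
        d = np.stack([np.ones(100), -np.ones(100)], axis=1)
        ps = _fake_posterior(d)
        np.testing.assert_allclose(assemblage_mean(ps), 0.0)

    def test_linearity_of_expectation(self, rng):
        mus = np.array([-1.0, 0.0, 0.5, 2.0])
        d = rng.normal(mus, 0.5, size=(20000, 4))
        ps = _fake_posterior(d)
        assert assemblage_mean(ps).mean() == pytest.approx(mus.mean(), abs=0.02)

    def test_unknown_coefficient_rejected(self):
        with pytest.raises(ValueError):
            assemblage_mean(_fake_posterior(np.zeros((10, 2))), "gamma")


@pytest.fixture(scope="module")
def small_fit():
    hyper = CommunityHyperparams()
    cov = simulate_covariates(40, seed=101)
    sp = simulate_species_params(10, hyper, seed=102)
    dh, _ = simulate_detection_history(sp, cov, np.full(40, 4), hyper, seed=103)
    dh, _ = filter_species(dh)
    mc = ModelConfig(
        n_chains=2, n_saved_per_chain=200, warmup=400,
        compute_bpv=True, bpv_draws=100, seed=104,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps, diag = fit(dh, cov, mc)
    return dh, cov, mc, ps, diag


class TestFit:
    def test_shapes_and_counts(self, small_fit):
        dh, cov, mc, ps, diag = small_fit
        K = dh.n_species
        assert ps.params["beta1"].shape == (2, 200, K)
        assert ps.stacked("beta1").shape == (mc.n_total_draws, K)
        assert set(ps.params) >= {"alpha", "beta1", "beta2", "p_intercept",
                                  "delta_depth", "mu_beta1", "sd_beta1"}

    def test_diagnostics_populated(self, small_fit):
        *_, diag = small_fit
        assert diag.max_rhat >= 1.0 - 1e-6
        assert 0.0 <= diag.bpv <= 1.0

    def test_seed_reproducible(self, small_fit):
        import warnings

        dh, cov, mc, ps, _ = small_fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps2, _ = fit(dh, cov, mc)
        np.testing.assert_array_equal(ps.params["beta1"], ps2.params["beta1"])

    def test_summary_table(self, small_fit):
        dh, _, _, ps, _ = small_fit
        s = ps.summary(0.9)
        assert len(s) == dh.n_species
        assert (s["beta1_lo"] <= s["beta1_hi"]).all()

    def test_empty_history_rejected(self, small_fit):
        dh, cov, mc, *_ = small_fit
        empty = dh.subset_species([])
        with pytest.raises(ValueError):
            fit(empty, cov, mc)

    def test_undetected_species_rejected(self, small_fit):
        dh, cov, mc, *_ = small_fit
        bad = dh.subset_species(list(range(dh.n_species)))
        bad.y[:, :, 0] = np.where(np.isnan(bad.y[:, :, 0]), np.nan, 0.0)
        with pytest.raises(ValueError, match="at least one detection"):
            fit(bad, cov, mc)


def test_abundant_species_insensitive_to_hyperprior():
    """A species with plenty of detections is dominated by its own data:
    changing the hyper-SD prior scale moves its slope posterior by less
    than Monte-Carlo error allows."""
    import warnings

    from coralfish.occupancy import PriorConfig

    hyper = CommunityHyperparams(mu_alpha=1.0, mu_p=0.5)  # common, detectable
    cov = simulate_covariates(100, seed=401)
    sp = simulate_species_params(8, hyper, seed=402)
    dh, _ = simulate_detection_history(sp, cov, np.full(100, 5), hyper, seed=403)
    dh, _ = filter_species(dh)
    k = int(np.argmax(dh.detections_per_species()))
    means = []
    for scale in (0.5, 2.0):
        mc = ModelConfig(
            n_chains=2, n_saved_per_chain=400, warmup=800, compute_bpv=False,
            seed=404, priors=PriorConfig(hyper_sd_scale=scale),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps, _ = fit(dh, cov, mc)
        means.append(ps.species_draws("beta1", k).mean())
    assert abs(means[0] - means[1]) < 0.1


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    psi=st.floats(0.01, 0.99),
    p1=st.floats(0.0, 1.0),
    p2=st.floats(0.0, 1.0),
)
def test_marginal_likelihood_total_probability(psi, p1, p2):
    total = sum(
        site_marginal_likelihood(psi, [p1, p2], y)
        for y in itertools.product([0, 1], repeat=2)
    )
    assert total == pytest.approx(1.0, abs=1e-9)
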