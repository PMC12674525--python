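import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from isodiet.inference import (
    DietMixingModel,
    FitConfig,
    PosteriorDraws,
    UnsupportedReductionError,
    convergence_diagnostics,
    fit_mcmc,
    grid_posterior_oracle,
)
from isodiet.model import PriorConfig
from isodiet.records import ConsumerRecord, SourceSpec, StudyDataset
from isodiet.simulate import default_truth, generate_dataset


def reduced_sources(mu=(-12.0, -24.0), conc=(0.3, 0.3), with_samples=False):
    out = []
    for k, (m, c) in enumerate(zip(mu, conc)):
        samples = np.array([m - 0.5, m + 0.5]) if with_samples else np.empty(0)
        out.append(
            SourceSpec(
                name=f"s{k}", samples={"d13c": samples},
                tef={"d13c": (1.0, 0.0)}, conc={"C": c, "N": 0.1},
            )
        )
    return out


def reduced_dataset(y, sources):
    cons = [
        ConsumerRecord(individual_id=f"i{i}", subgroup="all", tissue="bone",
                       d13c=float(v), d15n=0.0)
        for i, v in enumerate(y)
    ]
    return StudyDataset(consumers=cons, sources=sources,
                        tracers=("d13c",), subgroups=("all",))


def reduced_prior(mu):
    return PriorConfig(
        alpha=np.ones(2), mu_loc=np.reshape(mu, (2, 1)),
        mu_scale=np.ones((2, 1)), tau_scale=np.ones((2, 1)),
        sigma_ind_scale=[1.0], sigma_samp_scale=[1.0],
    )


def fixed_nuisance(mu, sigma):
    return {
        "mu": np.reshape(mu, (2, 1)), "tau": np.ones((2, 1)),
        "sigma_ind": np.array([sigma]), "sigma_samp": np.array([sigma]),
    }


class TestGridOracle:
    def test_symmetric_sources_centered_datum(self):
        mu = (-6.0, 4.0)  # adjusted means ±5 after TEF +1
        post = grid_posterior_oracle([0.0], reduced_sources(mu=mu), sigma=2.0, mu=mu)
        assert post.mean == pytest.approx(0.5, abs=1e-9)
        assert post.quantile(0.5) == pytest.approx(0.5, abs=1e-4)

    def test_datum_at_source_concentrates(self):
        mu = (-12.0, -24.0)
        post = grid_posterior_oracle([-11.0], reduced_sources(mu=mu), sigma=0.05, mu=mu)
        assert post.mean > 0.95

    def test_sampleless_sources_need_explicit_means(self):
        with pytest.raises(ValueError, match="mu"):
            grid_posterior_oracle([0.0], reduced_sources(), sigma=1.0)

    def test_wrong_reduction_rejected(self):
        srcs = reduced_sources() + reduced_sources()[:1]
        with pytest.raises(UnsupportedReductionError):
            grid_posterior_oracle([0.0], srcs, sigma=1.0)


class TestFitMCMC:
    def test_same_seed_bit_identical(self):
        ds = generate_dataset(default_truth(3))
        cfg = FitConfig(chains=2, warmup=150, draws=100, seed=42)
        a = fit_mcmc(ds, config=cfg)
        b = fit_mcmc(ds, config=cfg)
        assert np.array_equal(a.p, b.p)
        assert np.array_equal(a.log_prob, b.log_prob)

    def test_signal_dominant_recovery(self):
        truth = default_truth(17)
        truth = dataclasses.replace(
            truth,
            subgroups=("all",),
            p_true=np.array([[0.85, 0.05, 0.05, 0.05]]),
            design={"all": (20, 0, 0)},
            sigma_ind=np.array([0.3, 0.3]),
            sigma_samp=np.array([0.2, 0.2]),
        )
        ds = generate_dataset(truth)
        draws = fit_mcmc(ds, config=FitConfig(chains=2, warmup=500, draws=300, seed=1))
        p1 = draws.p_marginal("all", "marine_fish")
        assert p1.mean() > 0.6

    def test_mcmc_agrees_with_grid_oracle(self):
        rng = np.random.default_rng(5)
        for case in range(2):
            mu = np.array([rng.uniform(-14, -10), rng.uniform(-26, -20)])
            sigma = rng.uniform(0.5, 1.2)
            conc = rng.uniform(0.1, 0.5, 2)
            srcs = reduced_sources(mu=mu, conc=conc)
            p1 = rng.uniform(0.2, 0.8)
            adj = mu + 1.0
            m = (p1 * conc[0] * adj[0] + (1 - p1) * conc[1] * adj[1]) / (
                p1 * conc[0] + (1 - p1) * conc[1]
            )
            y = m + sigma * rng.standard_normal(8)
            oracle = grid_posterior_oracle(y, srcs, sigma, mu=mu)
            draws = fit_mcmc(
                reduced_dataset(y, srcs), reduced_prior(mu),
                FitConfig(chains=2, warmup=400, draws=400, seed=30 + case),
                fixed=fixed_nuisance(mu, sigma),
            )
            x = draws.p_marginal("all", "s0")
            assert abs(x.mean() - oracle.mean) < 0.01

    def test_prior_recovery_beta_marginal(self):
        # no consumers, no source samples: p margins must follow Beta(1, K-1)
        srcs = [
            SourceSpec(
                name=f"s{k}", samples={"d13c": np.empty(0), "d15n": np.empty(0)},
                tef={"d13c": (1.0, 0.0), "d15n": (3.0, 0.0)},
                conc={"C": 0.45, "N": 0.13},
            )
            for k in range(4)
        ]
        ds = StudyDataset(consumers=[], sources=srcs, subgroups=("g",))
        prior = PriorConfig(
            alpha=np.ones(4), mu_loc=np.zeros((4, 2)), mu_scale=np.ones((4, 2)),
            tau_scale=np.ones((4, 2)), sigma_ind_scale=np.ones(2),
            sigma_samp_scale=np.ones(2),
        )
        draws = fit_mcmc(ds, prior, FitConfig(chains=2, warmup=1000, draws=3000, seed=8))
        x = draws.p_marginal("g", "s0")
        # subsample to roughly independent draws before the KS test
        sub = np.random.default_rng(0).choice(x, size=500, replace=False)
        ks = stats.kstest(sub, stats.beta(1, 3).cdf)
        assert ks.pvalue > 0.01


class TestDiagnostics:
    def _draws_from_mu(self, mu_series):
        C, N = mu_series.shape
        return PosteriorDraws(
            p=np.full((C, N, 1, 2), 0.5),
            mu=np.repeat(mu_series[:, :, None, None], 2, axis=2),
            tau=np.ones((C, N, 2, 1)),
            sigma_ind=np.ones((C, N, 1)),
            sigma_samp=np.ones((C, N, 1)),
            log_prob=np.zeros((C, N)),
            subgroups=("g",), source_names=("a", "b"), tracers=("d13c",),
        )

    def test_white_noise_chains_near_one(self):
        rng = np.random.default_rng(0)
        draws = self._draws_from_mu(rng.standard_normal((4, 500)))
        diag = convergence_diagnostics(draws)
        row = diag[diag.parameter == "mu[a,d13c]"].iloc[0]
        assert 0.99 <= row.rhat <= 1.01
        assert not row.flagged

    def test_shifted_chain_flagged(self):
        rng = np.random.default_rng(0)
        mu = rng.standard_normal((4, 500))
        mu[0] += 10.0
        diag = convergence_diagnostics(self._draws_from_mu(mu))
        row = diag[diag.parameter == "mu[a,d13c]"].iloc[0]
        assert row.rhat > 1.1
        assert row.flagged

    def test_constant_chain_flagged_minimal(self):
        diag = convergence_diagnostics(self._draws_from_mu(np.ones((2, 200))))
        row = diag[diag.parameter == "mu[a,d13c]"].iloc[0]
        assert row.flagged and row.ess_bulk <= 1.0

    def test_single_chain_warns(self):
        rng = np.random.default_rng(0)
        diag = convergence_diagnostics(self._draws_from_mu(rng.standard_normal((1, 400))))
        assert diag["single_chain"].all()
        assert np.isnan(diag[diag.parameter == "mu[a,d13c]"].iloc[0].rhat)

    def test_joint_fit_converges(self, default_dataset):
        draws = fit_mcmc(
            default_dataset, config=FitConfig(chains=4, warmup=4000, draws=2000, seed=2)
        )
        diag = convergence_diagnostics(draws)
        p_rows = diag[diag.parameter.str.startswith("p[")]
        assert p_rows["rhat"].max() < 1.01
        assert (p_rows["ess_bulk"] > 100).all()


class TestPersistence:
    def test_save_load_round_trip(self, small_fit, tmp_path):
        path = tmp_path / "draws.csv"
        small_fit.save(path)
        back = PosteriorDraws.load(path)
        assert back.subgroups == small_fit.subgroups
        assert back.source_names == small_fit.source_names
        np.testing.assert_allclose(back.p, small_fit.p, atol=1e-8)

    def test_inference_data_export(self, small_fit):
        idata = small_fit.to_inference_data()
        assert idata.posterior["p"].dims == ("chain", "draw", "subgroup", "source")


class TestEstimator:
    def test_param_plumbing(self):
        m = DietMixingModel(chains=2, warmup=50, draws=60, seed=4)
        params = m.get_params()
        m2 = DietMixingModel(**params)
        assert m2.get_params() == params
        m2.set_params(draws=70)
        assert m2.draws == 70
        with pytest.raises(ValueError):
            m2.set_params(bogus=1)

    def test_fit_sets_attributes(self, default_dataset):
        m = DietMixingModel(chains=2, warmup=200, draws=100, seed=4).fit(default_dataset)
        assert m.posterior_.p.shape[2:] == (3, 4)
        assert {"subgroup", "source", "median"} <= set(m.summary_.columns)
        med = m.predict()
        assert med.shape == (3, 4)
        assert np.allclose(med.sum(axis=1), 1.0, atol=0.2)
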