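import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isodiet.model import (
    DegenerateInputError,
    ModelParameters,
    PosteriorDensity,
    PriorConfig,
    _dirichlet_logpdf,
    consumer_loglik,
    log_posterior,
    log_prior,
    mixture_mean,
    source_loglik,
)
from isodiet.records import ConsumerRecord, SourceSpec, StudyDataset

from conftest import cs_loglik_quadrature

LOG_2PI = math.log(2 * math.pi)


def source(name, mean_c, conc_c=0.45, tef_c=1.0, mean_n=8.0, conc_n=0.13):
    return SourceSpec(
        name=name,
        samples={"d13c": np.array([mean_c] * 2), "d15n": np.array([mean_n] * 2)},
        tef={"d13c": (tef_c, 0.0), "d15n": (3.0, 0.0)},
        conc={"C": conc_c, "N": conc_n},
    )


class TestMixtureMean:
    def test_single_source_limit(self):
        srcs = [source(f"s{k}", -15.0 - k) for k in range(4)]
        m = mixture_mean(np.array([1.0, 0, 0, 0]), srcs, "d13c")
        assert m == pytest.approx(srcs[0].adjusted_mean("d13c"), abs=1e-12)

    def test_equal_weights_arithmetic_mean(self):
        # adjusted means (-12, -20, -24, -27) with equal concentrations
        srcs = [source(f"s{k}", m - 1.0) for k, m in enumerate([-12, -20, -24, -27])]
        m = mixture_mean(np.full(4, 0.25), srcs, "d13c")
        assert m == pytest.approx(-20.75, abs=1e-12)

    def test_concentration_weighting_two_sources(self):
        # p=(0.5,0.5), c=(0.10,0.40), adjusted means (0,10): weights 0.2/0.8
        srcs = [
            source("a", -1.0, conc_c=0.10),
            source("b", 9.0, conc_c=0.40),
        ]
        m = mixture_mean(np.array([0.5, 0.5]), srcs, "d13c")
        assert m == pytest.approx(8.0, abs=1e-12)

    def test_degenerate_denominator(self):
        srcs = [source("a", -12.0, conc_c=1e-300), source("b", -20.0)]
        with pytest.raises(DegenerateInputError):
            mixture_mean(np.array([1.0, 0.0]), srcs, "d13c")

    @given(st.lists(st.floats(0.01, 10.0), min_size=4, max_size=4),
           st.integers(0, 10**6))
    def test_convexity_and_equal_conc_reduction(self, raw, seed):
        p = np.asarray(raw) / np.sum(raw)
        rng = np.random.default_rng(seed)
        means = rng.uniform(-30, -5, 4)
        concs = rng.uniform(0.05, 0.6, 4)
        srcs = [source(f"s{k}", means[k], conc_c=concs[k]) for k in range(4)]
        adj = np.array([s.adjusted_mean("d13c") for s in srcs])
        m = mixture_mean(p, srcs, "d13c")
        assert adj.min() - 1e-9 <= m <= adj.max() + 1e-9
        eq = [source(f"e{k}", means[k], conc_c=0.3) for k in range(4)]
        m_eq = mixture_mean(p, eq, "d13c")
        assert m_eq == pytest.approx(float(p @ adj), abs=1e-9)


def toy_params(p=(0.5, 0.5), s_ind=0.6, s_samp=0.4, tracers=("d13c",)):
    K = len(p)
    T = len(tracers)
    return ModelParameters(
        p=np.array([list(p)]),
        mu_source=np.tile(np.array([[-13.0], [-21.0]])[:K], (1, T)),
        tau_source=np.ones((K, T)),
        sigma_ind=np.full(T, s_ind),
        sigma_samp=np.full(T, s_samp),
        subgroups=("all",),
        tracers=tracers,
    )


class TestConsumerLoglik:
    def _mean(self, params, srcs):
        return mixture_mean(params.p[0], srcs, "d13c", mu=params.mu_source[:, 0])

    def test_bone_at_mean_is_standard_normal_peak(self):
        srcs = [source("a", -13.0), source("b", -21.0)]
        params = toy_params(s_ind=1.0)
        m = self._mean(params, srcs)
        ll = consumer_loglik({"d13c": [m]}, "bone", params, "all", srcs)
        assert ll == pytest.approx(-0.5 * LOG_2PI, abs=1e-12)

    def test_dentine_two_slices_matches_quadrature(self):
        srcs = [source("a", -13.0), source("b", -21.0)]
        params = toy_params(s_ind=0.6, s_samp=0.4)
        m = self._mean(params, srcs)
        y = np.array([m + 0.2, m - 0.1])
        ll = consumer_loglik({"d13c": y}, "dentine", params, "all", srcs)
        oracle = cs_loglik_quadrature(y, m, 0.6**2, 0.4**2)
        assert ll == pytest.approx(oracle, abs=1e-8)

    @given(st.integers(0, 10**6))
    def test_marginalization_identity_randomized(self, seed):
        rng = np.random.default_rng(seed)
        s_ind = rng.uniform(0.2, 1.5)
        s_samp = rng.uniform(0.2, 1.5)
        J = int(rng.integers(1, 7))
        srcs = [source("a", -13.0), source("b", -21.0)]
        params = toy_params(s_ind=s_ind, s_samp=s_samp)
        m = self._mean(params, srcs)
        y = m + rng.normal(0, 1.0, J)
        ll = consumer_loglik({"d13c": y}, "dentine", params, "all", srcs)
        oracle = cs_loglik_quadrature(y, m, s_ind**2, s_samp**2)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_vanishing_sample_noise_limit(self):
        srcs = [source("a", -13.0), source("b", -21.0)]
        params = toy_params(s_ind=0.6, s_samp=1e-6)
        m = self._mean(params, srcs)
        y = np.array([m + 0.3, m + 0.3])
        ll = consumer_loglik({"d13c": y}, "dentine", params, "all", srcs)
        oracle = cs_loglik_quadrature(y, m, 0.36, 1e-12, nodes=200)
        assert ll == pytest.approx(oracle, rel=1e-6)

    def test_zero_variances_off_mean_is_neg_inf(self):
        srcs = [source("a", -13.0), source("b", -21.0)]
        params = toy_params(s_ind=0.0, s_samp=0.0)
        ll = consumer_loglik({"d13c": [-14.0]}, "bone", params, "all", srcs)
        assert ll == -math.inf

    def test_bone_requires_single_value(self):
        srcs = [source("a", -13.0), source("b", -21.0)]
        with pytest.raises(ValueError):
            consumer_loglik({"d13c": [-14.0, -14.2]}, "bone", toy_params(), "all", srcs)


class TestSourceLoglik:
    def test_single_sample_at_mean(self):
        srcs = [
            SourceSpec(
                name="a", samples={"d13c": np.array([-13.0])},
                tef={"d13c": (1.0, 0.0)}, conc={"C": 0.45, "N": 0.13},
            )
        ]
        params = ModelParameters(
            p=np.array([[1.0]]), mu_source=np.array([[-13.0]]),
            tau_source=np.array([[1.0]]), sigma_ind=[1.0], sigma_samp=[1.0],
            tracers=("d13c",),
        )
        assert source_loglik(srcs, params) == pytest.approx(-0.5 * LOG_2PI, abs=1e-12)

    def test_two_symmetric_samples(self):
        srcs = [
            SourceSpec(
                name="a", samples={"d13c": np.array([-12.0, -14.0])},
                tef={"d13c": (1.0, 0.0)}, conc={"C": 0.45, "N": 0.13},
            )
        ]
        params = ModelParameters(
            p=np.array([[1.0]]), mu_source=np.array([[-13.0]]),
            tau_source=np.array([[1.0]]), sigma_ind=[1.0], sigma_samp=[1.0],
            tracers=("d13c",),
        )
        assert source_loglik(srcs, params) == pytest.approx(-LOG_2PI - 1.0, abs=1e-12)

    def test_empty_samples_rejected(self):
        srcs = [
            SourceSpec(
                name="a", samples={"d13c": np.array([])},
                tef={"d13c": (1.0, 0.0)}, conc={"C": 0.45, "N": 0.13},
            )
        ]
        params = ModelParameters(
            p=np.array([[1.0]]), mu_source=np.array([[-13.0]]),
            tau_source=np.array([[1.0]]), sigma_ind=[1.0], sigma_samp=[1.0],
            tracers=("d13c",),
        )
        with pytest.raises(ValueError):
            source_loglik(srcs, params)


class TestPriorAndPosterior:
    def test_flat_dirichlet_is_log6_and_constant(self):
        alpha = np.ones(4)
        p1 = np.array([0.25, 0.25, 0.25, 0.25])
        p2 = np.array([0.6, 0.2, 0.1, 0.1])
        assert _dirichlet_logpdf(p1, alpha) == pytest.approx(math.log(6), abs=1e-12)
        assert _dirichlet_logpdf(p1, alpha) == pytest.approx(
            _dirichlet_logpdf(p2, alpha), abs=1e-12
        )

    def test_dirichlet_marginal_is_beta_1_3(self):
        rng = np.random.default_rng(0)
        draws = rng.dirichlet(np.ones(4), size=200_000)[:, 0]
        from scipy import stats

        ks = stats.kstest(draws, stats.beta(1, 3).cdf)
        assert ks.statistic < 0.005

    def test_log_posterior_decomposition(self, default_dataset):
        ds = default_dataset
        prior = PriorConfig.from_dataset(ds)
        G, K, T = len(ds.subgroups), len(ds.sources), len(ds.tracers)
        params = ModelParameters(
            p=np.full((G, K), 1.0 / K),
            mu_source=prior.mu_loc.copy(),
            tau_source=np.full((K, T), 1.5),
            sigma_ind=np.array([0.7, 0.8]),
            sigma_samp=np.array([0.4, 0.5]),
            subgroups=ds.subgroups,
            tracers=ds.tracers,
        )
        total = log_posterior(ds, params, prior)
        parts = log_prior(params, prior) + source_loglik(ds.sources, params)
        for (ind, tissue), recs in ds.individuals().items():
            values = {
                tr: np.array([getattr(r, tr) for r in recs]) for tr in ds.tracers
            }
            parts += consumer_loglik(values, tissue, params, recs[0].subgroup, ds.sources)
        assert total == pytest.approx(parts, abs=1e-12)

    def test_source_permutation_invariance(self, default_dataset):
        ds = default_dataset
        prior = PriorConfig.from_dataset(ds)
        G, K, T = len(ds.subgroups), len(ds.sources), len(ds.tracers)
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(K), size=G)
        params = ModelParameters(
            p=p, mu_source=prior.mu_loc.copy(), tau_source=np.full((K, T), 1.5),
            sigma_ind=np.array([0.7, 0.8]), sigma_samp=np.array([0.4, 0.5]),
            subgroups=ds.subgroups, tracers=ds.tracers,
        )
        base = log_posterior(ds, params, prior)
        perm = np.array([2, 0, 3, 1])
        ds_perm = StudyDataset(
            consumers=ds.consumers,
            sources=[ds.sources[i] for i in perm],
            tracers=ds.tracers,
            subgroups=ds.subgroups,
        )
        prior_perm = PriorConfig.from_dataset(ds_perm)
        params_perm = ModelParameters(
            p=p[:, perm], mu_source=prior.mu_loc[perm],
            tau_source=np.full((K, T), 1.5),
            sigma_ind=np.array([0.7, 0.8]), sigma_samp=np.array([0.4, 0.5]),
            subgroups=ds.subgroups, tracers=ds.tracers,
        )
        assert log_posterior(ds_perm, params_perm, prior_perm) == pytest.approx(
            base, rel=1e-12
        )

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(
                p=np.array([[0.6, 0.6]]), mu_source=np.zeros((2, 1)),
                tau_source=np.ones((2, 1)), sigma_ind=[1.0], sigma_samp=[1.0],
            )


class TestVectorizedDensity:
    def test_matches_constrained_ops_plus_jacobian(self, default_dataset):
        ds = default_dataset
        prior = PriorConfig.from_dataset(ds)
        dens = PosteriorDensity(ds, prior)
        rng = np.random.default_rng(11)
        theta = 0.3 * rng.standard_normal((5, dens.ndim))
        sl = dens.blocks.slices
        theta[:, sl["mu"]] += prior.mu_loc.reshape(-1)
        batched = dens(theta)
        for w in range(5):
            params = dens.params_at(theta[w])
            jac = float(np.sum(np.log(params.p)))
            jac += float(np.sum(np.log(params.tau_source)))
            jac += float(np.sum(np.log(params.sigma_ind)))
            jac += float(np.sum(np.log(params.sigma_samp)))
            expected = log_posterior(ds, params, prior) + jac
            assert batched[w] == pytest.approx(expected, rel=1e-10)
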