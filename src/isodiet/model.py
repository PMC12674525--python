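"""Concentration-weighted Bayesian mixing model with hierarchical errors.

The consumer model: each isotopic measurement is conditionally normal with
mean equal to the concentration-weighted average of the (TEF-adjusted)
source means,

    m_{g,t} = Σ_k p_{g,k} c_{k,e(t)} (μ_{k,t} + λ_{k,t})
              / Σ_k p_{g,k} c_{k,e(t)},

where p_{g,k} are subgroup-g consumption proportions on the simplex,
c_{k,e} the elemental concentration of the element e(t) routing tracer t,
μ_{k,t} the (estimated) source mean and λ_{k,t} the trophic enrichment
factor. Bone contributes one measurement per individual with an
individual-level error σ_ind; sequential dentine slices share the
individual effect and add independent sample-level noise σ_samp, giving a
compound-symmetry covariance σ_ind²·11ᵀ + σ_samp²·I across a tooth's
slices. Source reference samples inform μ via a normal likelihood with
per-source SD τ. Proportions carry a Dirichlet prior (all-ones by default:
uniform over the simplex, marginally Beta(1, K−1) per component).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .records import TRACERS, TRACER_ELEMENT, SourceSpec, StudyDataset

__all__ = [
    "ModelParameters",
    "PriorConfig",
    "DegenerateInputError",
    "mixture_mean",
    "consumer_loglik",
    "source_loglik",
    "log_prior",
    "log_posterior",
]

SIMPLEX_TOL = 1e-10
_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateInputError(ValueError):
    """All proportion mass on zero-concentration sources (undefined mean)."""


def _check_simplex(p: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -tol) or abs(float(p.sum()) - 1.0) > max(tol, SIMPLEX_TOL * p.size):
        raise ValueError(f"proportions {p} are not on the simplex")
    return p


@dataclass
class ModelParameters:
    """One point in parameter space.

    Shapes: p (G, K); mu_source, tau_source (K, T); sigma_ind, sigma_samp
    (T,). G subgroups, K sources, T tracers. Label tuples are optional
    bookkeeping attached by the fitting code.
    """

    p: np.ndarray
    mu_source: np.ndarray
    tau_source: np.ndarray
    sigma_ind: np.ndarray
    sigma_samp: np.ndarray
    subgroups: tuple[str, ...] = ()
    source_names: tuple[str, ...] = ()
    tracers: tuple[str, ...] = TRACERS

    def __post_init__(self) -> None:
        self.p = np.atleast_2d(np.asarray(self.p, dtype=float))
        self.mu_source = np.atleast_2d(np.asarray(self.mu_source, dtype=float))
        self.tau_source = np.atleast_2d(np.asarray(self.tau_source, dtype=float))
        self.sigma_ind = np.atleast_1d(np.asarray(self.sigma_ind, dtype=float))
        self.sigma_samp = np.atleast_1d(np.asarray(self.sigma_samp, dtype=float))
        rows = np.abs(self.p.sum(axis=1) - 1.0)
        if np.any(rows > 1e-8):
            raise ValueError("each row of p must sum to 1")
        if np.any(self.p < 0):
            raise ValueError("proportions must be non-negative")
        for name, arr in (
            ("tau_source", self.tau_source),
            ("sigma_ind", self.sigma_ind),
            ("sigma_samp", self.sigma_samp),
        ):
            if np.any(arr < 0):
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_subgroups(self) -> int:
        return self.p.shape[0]

    @property
    def n_sources(self) -> int:
        return self.p.shape[1]

    @property
    def n_tracers(self) -> int:
        return self.mu_source.shape[1]

    def subgroup_index(self, subgroup: Union[int, str]) -> int:
        if isinstance(subgroup, (int, np.integer)):
            return int(subgroup)
        if self.subgroups and subgroup in self.subgroups:
            return self.subgroups.index(subgroup)
        raise KeyError(f"unknown subgroup {subgroup!r}")

    def tracer_index(self, tracer: str) -> int:
        return self.tracers.index(tracer)


@dataclass
class PriorConfig:
    """Priors for everything but the proportions are weakly informative.

    alpha : Dirichlet concentration over sources (all-ones = uniform).
    mu_loc, mu_scale : normal prior on source means μ, shape (K, T).
    tau_scale : half-normal scale on source SDs τ, shape (K, T).
    sigma_ind_scale, sigma_samp_scale : half-normal scales per tracer.
    tef_mode : "fixed" treats λ as known; "normal_uncertain" folds the TEF
        SD into the consumer variance through the mixture weights.
    propagate_source_variance : also fold Σ_k w_k² τ_{k,t}² into the
        consumer variance (classic fully-propagated mixing-model behavior).
    """

    alpha: np.ndarray
    mu_loc: np.ndarray
    mu_scale: np.ndarray
    tau_scale: np.ndarray
    sigma_ind_scale: np.ndarray
    sigma_samp_scale: np.ndarray
    tef_mode: str = "fixed"
    propagate_source_variance: bool = False

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.mu_loc = np.atleast_2d(np.asarray(self.mu_loc, dtype=float))
        self.mu_scale = np.atleast_2d(np.asarray(self.mu_scale, dtype=float))
        self.tau_scale = np.atleast_2d(np.asarray(self.tau_scale, dtype=float))
        self.sigma_ind_scale = np.atleast_1d(np.asarray(self.sigma_ind_scale, dtype=float))
        self.sigma_samp_scale = np.atleast_1d(np.asarray(self.sigma_samp_scale, dtype=float))
        if np.any(self.alpha <= 0):
            raise ValueError("Dirichlet alpha must be strictly positive")
        for name, arr in (
            ("mu_scale", self.mu_scale),
            ("tau_scale", self.tau_scale),
            ("sigma_ind_scale", self.sigma_ind_scale),
            ("sigma_samp_scale", self.sigma_samp_scale),
        ):
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.tef_mode not in ("fixed", "normal_uncertain"):
            raise ValueError(f"unknown tef_mode {self.tef_mode!r}")

    @classmethod
    def from_dataset(
        cls,
        dataset: StudyDataset,
        alpha: Optional[Sequence[float]] = None,
        **overrides,
    ) -> "PriorConfig":
        """Default data-scaled priors.

        μ prior centered at each source's sample mean with scale SD/√n
        (standard error); τ and the error SDs get half-normal scales equal
        to the pooled sample SD per tracer (source samples for τ, consumer
        values for σ), floored at 0.25‰ to stay proper on tiny fixtures.
        """
        K = len(dataset.sources)
        T = len(dataset.tracers)
        mu_loc = np.zeros((K, T))
        mu_scale = np.zeros((K, T))
        tau_scale = np.zeros((K, T))
        floor = 0.25
        for k, s in enumerate(dataset.sources):
            for t, tr in enumerate(dataset.tracers):
                x = np.asarray(s.samples[tr], dtype=float)
                n = max(x.size, 1)
                sd = float(np.std(x, ddof=1)) if x.size >= 2 else floor
                sd = max(sd, floor)
                mu_loc[k, t] = float(np.mean(x)) if x.size else 0.0
                mu_scale[k, t] = max(sd / math.sqrt(n), floor / math.sqrt(n))
        pooled_src = np.full(T, floor)
        for t, tr in enumerate(dataset.tracers):
            allx = np.concatenate(
                [np.asarray(s.samples[tr], dtype=float) - np.mean(s.samples[tr])
                 for s in dataset.sources if np.asarray(s.samples[tr]).size >= 2]
                or [np.zeros(1)]
            )
            if allx.size >= 2:
                pooled_src[t] = max(float(np.std(allx, ddof=1)), floor)
        tau_scale[:] = pooled_src[None, :]
        sigma_scale = np.full(T, 1.0)
        for t, tr in enumerate(dataset.tracers):
            vals = np.array([getattr(r, tr) for r in dataset.consumers], dtype=float)
            if vals.size >= 2:
                sigma_scale[t] = max(float(np.std(vals, ddof=1)), floor)
        kwargs = dict(
            alpha=np.ones(K) if alpha is None else np.asarray(alpha, float),
            mu_loc=mu_loc,
            mu_scale=mu_scale,
            tau_scale=tau_scale,
            sigma_ind_scale=sigma_scale,
            sigma_samp_scale=sigma_scale,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _conc_vector(sources: Sequence[SourceSpec], tracer: str) -> np.ndarray:
    element = TRACER_ELEMENT.get(tracer)
    if element is None:
        raise KeyError(f"tracer {tracer!r} has no element mapping")
    return np.array([s.conc[element] for s in sources], dtype=float)


def _adjusted_means(
    sources: Sequence[SourceSpec],
    tracer: str,
    mu: Optional[np.ndarray] = None,
    tef: Optional[np.ndarray] = None,
) -> np.ndarray:
    if mu is None:
        mu = np.array([float(np.mean(s.samples[tracer])) for s in sources])
    else:
        mu = np.asarray(mu, dtype=float)
    if tef is None:
        tef = np.array([float(s.tef[tracer][0]) for s in sources])
    else:
        tef = np.asarray(tef, dtype=float)
    return mu + tef


def mixture_weights(
    p_row: np.ndarray, sources: Sequence[SourceSpec], tracer: str
) -> np.ndarray:
    """Concentration-adjusted weights w_k = p_k c_k / Σ p_j c_j."""
    p = _check_simplex(p_row)
    c = _conc_vector(sources, tracer)
    den = float(np.dot(p, c))
    if den <= 1e-300:
        raise DegenerateInputError(
            "all proportion mass on zero-concentration sources"
        )
    return p * c / den


def mixture_mean(
    p_row: np.ndarray,
    sources: Sequence[SourceSpec],
    tracer: str,
    mu: Optional[np.ndarray] = None,
    tef: Optional[np.ndarray] = None,
) -> float:
    """Concentration-weighted, TEF-adjusted expected consumer value (‰).

    ``mu`` overrides the per-source tracer means (defaults to each source's
    sample mean, which is how the fitted model evaluates it at a parameter
    point); ``tef`` overrides the TEF means.
    """
    w = mixture_weights(p_row, sources, tracer)
    adj = _adjusted_means(sources, tracer, mu=mu, tef=tef)
    return float(np.dot(w, adj))


def _consumer_variance_extra(
    w: np.ndarray,
    sources: Sequence[SourceSpec],
    tracer: str,
    tau: Optional[np.ndarray],
    propagate_source_variance: bool,
    tef_mode: str,
) -> float:
    extra = 0.0
    if propagate_source_variance and tau is not None:
        extra += float(np.dot(w**2, np.asarray(tau, float) ** 2))
    if tef_mode == "normal_uncertain":
        lam_sd = np.array([float(s.tef[tracer][1]) for s in sources])
        extra += float(np.dot(w**2, lam_sd**2))
    return extra


def _cs_loglik(y: np.ndarray, m: float, u: float, v: float) -> float:
    """Marginal log-density of J exchangeable repeats under compound symmetry.

    y_j = m + a + e_j with a ~ N(0, u), e_j ~ N(0, v) independent; the
    covariance is u·11ᵀ + v·I. Equals the integral over a of the product of
    N(m + a, √v) densities.
    """
    y = np.asarray(y, dtype=float)
    J = y.size
    ybar = float(np.mean(y))
    ssw = float(np.sum((y - ybar) ** 2))
    if v <= 0.0:
        if ssw > 0.0:
            return -math.inf
        # Slices coincide: the within-slice factor is degenerate; only the
        # shared-mean factor remains (J repeats of a point mass contribute
        # no finite density term).
        if u <= 0.0:
            return 0.0 if ybar == m else -math.inf
        return -0.5 * (_LOG_2PI + math.log(u)) - (ybar - m) ** 2 / (2.0 * u)
    tot = v + J * u
    if tot <= 0.0:
        return -math.inf
    return (
        -0.5 * J * _LOG_2PI
        - 0.5 * (J - 1) * math.log(v)
        - 0.5 * math.log(tot)
        - ssw / (2.0 * v)
        - J * (ybar - m) ** 2 / (2.0 * tot)
    )


def _normal_loglik(y: float, m: float, var: float) -> float:
    if var <= 0.0:
        return 0.0 if y == m else -math.inf
    return -0.5 * (_LOG_2PI + math.log(var)) - (y - m) ** 2 / (2.0 * var)


def consumer_loglik(
    values: Union[Mapping[str, np.ndarray], np.ndarray],
    tissue: str,
    params: ModelParameters,
    subgroup: Union[int, str],
    sources: Sequence[SourceSpec],
    *,
    propagate_source_variance: bool = False,
    tef_mode: str = "fixed",
) -> float:
    """Log-density of one individual's measurements given parameters.

    ``values`` maps tracer → measurement(s): a scalar per tracer for bone,
    a length-J vector per tracer for dentine (the J sequential slices).
    Tracers are conditionally independent given the parameters.
    """
    g = params.subgroup_index(subgroup)
    if isinstance(values, np.ndarray):
        arr = np.atleast_2d(values)
        values = {tr: arr[:, i] for i, tr in enumerate(params.tracers)}
    total = 0.0
    for tr, y in values.items():
        it = params.tracer_index(tr)
        y = np.atleast_1d(np.asarray(y, dtype=float))
        w = mixture_weights(params.p[g], sources, tr)
        m = float(
            np.dot(w, _adjusted_means(sources, tr, mu=params.mu_source[:, it]))
        )
        extra = _consumer_variance_extra(
            w, sources, tr, params.tau_source[:, it],
            propagate_source_variance, tef_mode,
        )
        u = float(params.sigma_ind[it]) ** 2 + extra
        if tissue == "bone":
            if y.size != 1:
                raise ValueError("bone carries exactly one value per tracer")
            total += _normal_loglik(float(y[0]), m, u)
        elif tissue == "dentine":
            if y.size < 1:
                raise ValueError("dentine requires J >= 1 slice values")
            v = float(params.sigma_samp[it]) ** 2
            total += _cs_loglik(y, m, u, v)
        else:
            raise ValueError(f"unknown tissue {tissue!r}")
    return total


def source_loglik(sources: Sequence[SourceSpec], params: ModelParameters) -> float:
    """Sum of normal log-densities of all source reference samples."""
    total = 0.0
    for k, s in enumerate(sources):
        for tr in params.tracers:
            it = params.tracer_index(tr)
            x = np.asarray(s.samples[tr], dtype=float)
            if x.size == 0:
                raise ValueError(f"source {s.name!r} has no {tr} samples")
            tau = float(params.tau_source[k, it])
            if tau <= 0:
                raise ValueError("tau must be strictly positive for source_loglik")
            total += float(np.sum(stats.norm.logpdf(x, params.mu_source[k, it], tau)))
    return total


def _dirichlet_logpdf(p: np.ndarray, alpha: np.ndarray) -> float:
    p = np.clip(np.asarray(p, float), 1e-300, None)
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + np.sum((alpha - 1.0) * np.log(p))
    )


def _halfnormal_logpdf(x: np.ndarray, scale: np.ndarray) -> float:
    x = np.asarray(x, float)
    scale = np.asarray(scale, float)
    if np.any(x < 0):
        return -math.inf
    return float(
        np.sum(0.5 * math.log(2.0 / math.pi) - np.log(scale) - x**2 / (2 * scale**2))
    )


def log_prior(params: ModelParameters, prior: PriorConfig) -> float:
    """Joint log prior density at a constrained parameter point."""
    total = 0.0
    for g in range(params.n_subgroups):
        row = params.p[g]
        if abs(float(row.sum()) - 1.0) > 1e-8:
            raise ValueError("p row off the simplex beyond tolerance")
        total += _dirichlet_logpdf(row, prior.alpha)
    total += float(
        np.sum(stats.norm.logpdf(params.mu_source, prior.mu_loc, prior.mu_scale))
    )
    total += _halfnormal_logpdf(params.tau_source, prior.tau_scale)
    total += _halfnormal_logpdf(params.sigma_ind, prior.sigma_ind_scale)
    total += _halfnormal_logpdf(params.sigma_samp, prior.sigma_samp_scale)
    return total


def log_posterior(
    dataset: StudyDataset, params: ModelParameters, prior: PriorConfig
) -> float:
    """log prior + source likelihood + Σ consumer likelihoods."""
    total = log_prior(params, prior)
    total += source_loglik(dataset.sources, params)
    subgroups = params.subgroups or dataset.subgroups
    for (ind, tissue), recs in dataset.individuals().items():
        g = subgroups.index(recs[0].subgroup)
        values = {
            tr: np.array([getattr(r, tr) for r in recs], dtype=float)
            for tr in dataset.tracers
        }
        total += consumer_loglik(
            values,
            tissue,
            params,
            g,
            dataset.sources,
            propagate_source_variance=prior.propagate_source_variance,
            tef_mode=prior.tef_mode,
        )
    return total


# ---------------------------------------------------------------------------
# Vectorized unconstrained-space posterior used by the sampler.
# ---------------------------------------------------------------------------


@dataclass
class _Blocks:
    """Free-parameter layout in the flat sampling vector."""

    G: int
    K: int
    T: int
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slices: dict[str, slice] = {}
        pos = 0
        self.slices["z"] = slice(pos, pos + self.G * (self.K - 1))
        pos = self.slices["z"].stop
        for name, size in (
            ("mu", self.K * self.T),
            ("log_tau", self.K * self.T),
            ("log_sigma_ind", self.T),
            ("log_sigma_samp", self.T),
        ):
            if name.removeprefix("log_") not in self.fixed and name not in self.fixed:
                self.slices[name] = slice(pos, pos + size)
                pos += size
        self.ndim = pos


class PosteriorDensity:
    """Batched log-posterior over the unconstrained parameterization.

    Proportions use the additive log-ratio transform (softmax with the last
    component pinned), positive scales use log transforms; the Dirichlet
    and half-normal densities are applied with the change-of-variables
    Jacobians so the constrained-space model is sampled exactly.

    Nuisance blocks can be held fixed via ``fixed`` (keys "mu", "tau",
    "sigma_ind", "sigma_samp"), which shrinks the sampling space — used by
    the reduced-model oracle comparisons.
    """

    _LOG_SCALE_BOUND = 12.0

    def __init__(
        self,
        dataset: StudyDataset,
        prior: PriorConfig,
        fixed: Optional[Mapping[str, np.ndarray]] = None,
    ) -> None:
        self.dataset = dataset
        self.prior = prior
        self.fixed = {k: np.asarray(v, float) for k, v in (fixed or {}).items()}
        self.tracers = dataset.tracers
        self.subgroups = tuple(dataset.subgroups)
        self.source_names = dataset.source_names
        G, K, T = len(self.subgroups), len(dataset.sources), len(self.tracers)
        if K < 2:
            raise ValueError("need at least two sources")
        self.G, self.K, self.T = G, K, T
        self.blocks = _Blocks(G, K, T, dict(self.fixed))

        self.conc = np.stack(
            [_conc_vector(dataset.sources, tr) for tr in self.tracers], axis=1
        )  # (K, T)
        self.lam = np.array(
            [[float(s.tef[tr][0]) for tr in self.tracers] for s in dataset.sources]
        )
        self.lam_sd = np.array(
            [[float(s.tef[tr][1]) for tr in self.tracers] for s in dataset.sources]
        )

        # Source sample sufficient statistics.
        self.src_n = np.zeros((K, T))
        self.src_mean = np.zeros((K, T))
        self.src_ss = np.zeros((K, T))
        for k, s in enumerate(dataset.sources):
            for t, tr in enumerate(self.tracers):
                x = np.asarray(s.samples[tr], dtype=float)
                self.src_n[k, t] = x.size
                if x.size:
                    self.src_mean[k, t] = float(np.mean(x))
                    self.src_ss[k, t] = float(np.sum((x - np.mean(x)) ** 2))

        # Consumer sufficient statistics grouped by (individual, tissue).
        bone_y, bone_g = [], []
        dent_J, dent_ybar, dent_ssw, dent_g = [], [], [], []
        for (ind, tissue), recs in dataset.individuals().items():
            g = self.subgroups.index(recs[0].subgroup)
            ymat = np.array(
                [[getattr(r, tr) for tr in self.tracers] for r in recs], dtype=float
            )
            if tissue == "bone":
                for row in ymat:
                    bone_y.append(row)
                    bone_g.append(g)
            else:
                dent_J.append(ymat.shape[0])
                dent_ybar.append(ymat.mean(axis=0))
                dent_ssw.append(((ymat - ymat.mean(axis=0)) ** 2).sum(axis=0))
                dent_g.append(g)
        self.bone_y = np.array(bone_y, dtype=float).reshape(-1, T)
        self.bone_g = np.array(bone_g, dtype=int)
        self.dent_J = np.array(dent_J, dtype=float)
        self.dent_ybar = np.array(dent_ybar, dtype=float).reshape(-1, T)
        self.dent_ssw = np.array(dent_ssw, dtype=float).reshape(-1, T)
        self.dent_g = np.array(dent_g, dtype=int)

    # -- transforms ---------------------------------------------------------

    @property
    def ndim(self) -> int:
        return self.blocks.ndim

    def _unpack(self, theta: np.ndarray):
        W = theta.shape[0]
        sl = self.blocks.slices
        z = theta[:, sl["z"]].reshape(W, self.G, self.K - 1)
        zfull = np.concatenate([z, np.zeros((W, self.G, 1))], axis=2)
        zfull = zfull - zfull.max(axis=2, keepdims=True)
        ez = np.exp(zfull)
        p = ez / ez.sum(axis=2, keepdims=True)  # (W, G, K)

        def block(name, fixed_key, shape, log=False):
            if fixed_key in self.fixed:
                out = np.broadcast_to(self.fixed[fixed_key], (W,) + shape)
                return out, None
            raw = theta[:, sl[name]].reshape((W,) + shape)
            return (np.exp(raw) if log else raw), raw

        mu, _ = block("mu", "mu", (self.K, self.T))
        tau, log_tau = block("log_tau", "tau", (self.K, self.T), log=True)
        s_ind, log_s_ind = block("log_sigma_ind", "sigma_ind", (self.T,), log=True)
        s_samp, log_s_samp = block("log_sigma_samp", "sigma_samp", (self.T,), log=True)
        return p, mu, tau, s_ind, s_samp, (log_tau, log_s_ind, log_s_samp)

    def params_at(self, theta: np.ndarray) -> ModelParameters:
        """Constrained ModelParameters at one flat point."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        p, mu, tau, s_ind, s_samp, _ = self._unpack(theta)
        return ModelParameters(
            p=p[0],
            mu_source=np.array(mu[0]),
            tau_source=np.array(tau[0]),
            sigma_ind=np.array(s_ind[0]),
            sigma_samp=np.array(s_samp[0]),
            subgroups=self.subgroups,
            source_names=self.source_names,
            tracers=self.tracers,
        )

    # -- density ------------------------------------------------------------

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        W = theta.shape[0]
        out = np.full(W, -np.inf)
        ok = np.all(np.isfinite(theta), axis=1)
        # keep log-scales in a numerically safe box
        sl = self.blocks.slices
        for name in ("log_tau", "log_sigma_ind", "log_sigma_samp"):
            if name in sl:
                ok &= np.all(np.abs(theta[:, sl[name]]) < self._LOG_SCALE_BOUND, axis=1)
        if not np.any(ok):
            return out
        th = theta[ok]
        p, mu, tau, s_ind, s_samp, logs = self._unpack(th)
        lp = self._log_prior_unconstrained(p, mu, tau, s_ind, s_samp, logs)
        lp += self._source_loglik(mu, tau)
        lp += self._consumer_loglik(p, mu, tau, s_ind, s_samp)
        out[ok] = lp
        return out

    def _log_prior_unconstrained(self, p, mu, tau, s_ind, s_samp, logs):
        pr = self.prior
        logp = np.log(np.clip(p, 1e-300, None))  # (W, G, K)
        # Dirichlet density + ALR Jacobian: Σ_k α_k log p_k (+ const)
        const = self.G * float(gammaln(pr.alpha.sum()) - gammaln(pr.alpha).sum())
        lp = const + np.einsum("wgk,k->w", logp, pr.alpha)
        if "mu" not in self.fixed:
            lp += np.sum(
                -0.5 * _LOG_2PI
                - np.log(pr.mu_scale)
                - (mu - pr.mu_loc) ** 2 / (2 * pr.mu_scale**2),
                axis=(1, 2),
            )
        log_tau, log_s_ind, log_s_samp = logs

        def hn(x, scale, logx):
            # half-normal on x plus log-Jacobian of the log transform
            val = np.sum(
                0.5 * math.log(2.0 / math.pi) - np.log(scale) - x**2 / (2 * scale**2),
                axis=tuple(range(1, x.ndim)),
            )
            if logx is not None:
                val = val + np.sum(logx, axis=tuple(range(1, logx.ndim)))
            return val

        if "tau" not in self.fixed:
            lp += hn(tau, self.prior.tau_scale, log_tau)
        if "sigma_ind" not in self.fixed:
            lp += hn(s_ind, self.prior.sigma_ind_scale, log_s_ind)
        if "sigma_samp" not in self.fixed:
            lp += hn(s_samp, self.prior.sigma_samp_scale, log_s_samp)
        return lp

    def _source_loglik(self, mu, tau):
        n, mean, ss = self.src_n, self.src_mean, self.src_ss
        mask = n > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (
                -0.5 * n * _LOG_2PI
                - n * np.log(tau)
                - (ss + n * (mean - mu) ** 2) / (2 * tau**2)
            )
        return np.sum(np.where(mask, ll, 0.0), axis=(1, 2))

    def _mixture_moments(self, p, mu, tau):
        # p: (W,G,K); mu/tau: (W,K,T); conc: (K,T)
        num = np.einsum("wgk,kt,wkt->wgt", p, self.conc, mu + self.lam)
        den = np.einsum("wgk,kt->wgt", p, self.conc)
        m = num / den
        extra = np.zeros_like(m)
        if self.prior.propagate_source_variance or self.prior.tef_mode == "normal_uncertain":
            w = p[:, :, :, None] * self.conc[None, None] / den[:, :, None, :]
            if self.prior.propagate_source_variance:
                extra += np.einsum("wgkt,wkt->wgt", w**2, tau**2)
            if self.prior.tef_mode == "normal_uncertain":
                extra += np.einsum("wgkt,kt->wgt", w**2, self.lam_sd**2)
        return m, extra

    def _consumer_loglik(self, p, mu, tau, s_ind, s_samp):
        W = p.shape[0]
        m, extra = self._mixture_moments(p, mu, tau)  # (W, G, T)
        ll = np.zeros(W)
        u_all = s_ind[:, None, :] ** 2 + extra  # (W, G, T)
        if self.bone_y.size:
            mb = m[:, self.bone_g, :]  # (W, Nb, T)
            ub = u_all[:, self.bone_g, :]
            ll += np.sum(
                -0.5 * (_LOG_2PI + np.log(ub))
                - (self.bone_y[None] - mb) ** 2 / (2 * ub),
                axis=(1, 2),
            )
        if self.dent_J.size:
            md = m[:, self.dent_g, :]  # (W, Nd, T)
            ud = u_all[:, self.dent_g, :]
            v = s_samp[:, None, :] ** 2  # (W, 1, T)
            J = self.dent_J[None, :, None]
            tot = v + J * ud
            ll += np.sum(
                -0.5 * J * _LOG_2PI
                - 0.5 * (J - 1) * np.log(v)
                - 0.5 * np.log(tot)
                - self.dent_ssw[None] / (2 * v)
                - J * (self.dent_ybar[None] - md) ** 2 / (2 * tot),
                axis=(1, 2),
            )
        return ll
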