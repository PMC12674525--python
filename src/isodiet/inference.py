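"""Posterior sampling, convergence diagnostics and a grid-quadrature oracle.

Sampling uses differential-evolution ensemble MCMC over the unconstrained
parameterization of :class:`~isodiet.model.PosteriorDensity`. A fit runs
several independent ensembles. For diagnostics each independent ensemble
is one chain whose draws pool its walkers step-major — split-R̂ then
compares independent runs and first/second-half drift — while effective
sample size is computed on the per-walker trajectories, whose
autocorrelation is the quantity ESS must discount for.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    ModelParameters,
    PosteriorDensity,
    PriorConfig,
    _adjusted_means,
    _conc_vector,
)
from .records import SourceSpec, StudyDataset

__all__ = [
    "FitConfig",
    "PosteriorDraws",
    "InitializationError",
    "UnsupportedReductionError",
    "fit_mcmc",
    "convergence_diagnostics",
    "grid_posterior_oracle",
    "GridPosterior",
    "DietMixingModel",
]


class InitializationError(RuntimeError):
    """Could not find finite log-posterior starting points."""


class UnsupportedReductionError(ValueError):
    """The grid oracle only supports K=2 sources and a single tracer."""


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings.

    ``warmup``/``draws`` count ensemble steps; each retained step
    contributes one draw per walker. ``chains`` independent ensembles are
    run from seeds derived from ``seed``.
    """

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    nwalkers: Optional[int] = None

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.draws < 1:
            raise ValueError("chains >= 1, warmup >= 0, draws >= 1 required")

    def walkers_for(self, ndim: int) -> int:
        n = self.nwalkers or max(2 * ndim + 2, 32)
        return n + (n % 2)


@dataclass
class PosteriorDraws:
    """Posterior samples with chain structure.

    Array shapes: p (chain, draw, G, K); mu, tau (chain, draw, K, T);
    sigma_ind, sigma_samp (chain, draw, T); log_prob (chain, draw). Each
    chain is one independent ensemble; its draw axis runs step-major over
    the ensemble's walkers (``n_walkers`` per step).
    """

    p: np.ndarray
    mu: np.ndarray
    tau: np.ndarray
    sigma_ind: np.ndarray
    sigma_samp: np.ndarray
    log_prob: np.ndarray
    subgroups: tuple[str, ...]
    source_names: tuple[str, ...]
    tracers: tuple[str, ...]
    seed: int = 0
    config: Optional[FitConfig] = None
    n_ensembles: int = 1
    n_walkers: int = 1
    acceptance_fraction: float = float("nan")

    def __post_init__(self) -> None:
        sums = self.p.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise ValueError("stored proportions leave the simplex")

    @property
    def n_chains(self) -> int:
        return self.p.shape[0]

    @property
    def n_draws(self) -> int:
        return self.p.shape[1]

    def walker_view(self, arr: np.ndarray) -> Optional[np.ndarray]:
        """Reshape a (chain, draw) array to per-walker trajectories
        (chain·walker, step), or None if the walker factorization is unknown."""
        C, N = arr.shape[:2]
        if self.n_walkers <= 1 or N % self.n_walkers:
            return None
        steps = N // self.n_walkers
        return (
            arr.reshape(C, steps, self.n_walkers)
            .transpose(0, 2, 1)
            .reshape(C * self.n_walkers, steps)
        )

    def p_marginal(self, subgroup: Union[int, str], source: Union[int, str]) -> np.ndarray:
        """Flattened draws of one proportion component."""
        g = subgroup if isinstance(subgroup, int) else self.subgroups.index(subgroup)
        k = source if isinstance(source, int) else self.source_names.index(source)
        return self.p[:, :, g, k].reshape(-1)

    def scalar_series(self) -> dict[str, np.ndarray]:
        """Every scalar parameter as a (chain, draw) array, labeled."""
        out: dict[str, np.ndarray] = {}
        for g, gl in enumerate(self.subgroups):
            for k, kl in enumerate(self.source_names):
                out[f"p[{gl},{kl}]"] = self.p[:, :, g, k]
        for k, kl in enumerate(self.source_names):
            for t, tl in enumerate(self.tracers):
                out[f"mu[{kl},{tl}]"] = self.mu[:, :, k, t]
                out[f"tau[{kl},{tl}]"] = self.tau[:, :, k, t]
        for t, tl in enumerate(self.tracers):
            out[f"sigma_ind[{tl}]"] = self.sigma_ind[:, :, t]
            out[f"sigma_samp[{tl}]"] = self.sigma_samp[:, :, t]
        return out

    def to_inference_data(self):
        """Standard posterior container export (arviz InferenceData)."""
        import arviz as az

        return az.from_dict(
            posterior={
                "p": self.p,
                "mu": self.mu,
                "tau": self.tau,
                "sigma_ind": self.sigma_ind,
                "sigma_samp": self.sigma_samp,
            },
            coords={
                "subgroup": list(self.subgroups),
                "source": list(self.source_names),
                "tracer": list(self.tracers),
            },
            dims={
                "p": ["subgroup", "source"],
                "mu": ["source", "tracer"],
                "tau": ["source", "tracer"],
                "sigma_ind": ["tracer"],
                "sigma_samp": ["tracer"],
            },
        )

    def save(self, path, thin: int = 1) -> None:
        """Self-describing columnar text export (parameter, chain, iteration, value)."""
        meta = {
            "subgroups": list(self.subgroups),
            "sources": list(self.source_names),
            "tracers": list(self.tracers),
            "seed": self.seed,
            "n_ensembles": self.n_ensembles,
        }
        frames = []
        for name, arr in self.scalar_series().items():
            a = arr[:, ::thin]
            C, N = a.shape
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "chain": np.repeat(np.arange(C), N),
                        "iteration": np.tile(np.arange(N), C),
                        "value": a.reshape(-1),
                    }
                )
            )
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            pd.concat(frames, ignore_index=True).to_csv(fh, index=False)

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first.lstrip("# "))
            df = pd.read_csv(fh)
        subgroups = tuple(meta["subgroups"])
        sources = tuple(meta["sources"])
        tracers = tuple(meta["tracers"])
        C = int(df["chain"].max()) + 1
        N = int(df["iteration"].max()) + 1

        def grab(name):
            sub = df[df["parameter"] == name]
            return sub["value"].to_numpy().reshape(C, N)

        G, K, T = len(subgroups), len(sources), len(tracers)
        p = np.stack(
            [
                np.stack([grab(f"p[{gl},{kl}]") for kl in sources], axis=-1)
                for gl in subgroups
            ],
            axis=2,
        )
        mu = np.stack(
            [
                np.stack([grab(f"mu[{kl},{tl}]") for tl in tracers], axis=-1)
                for kl in sources
            ],
            axis=2,
        )
        tau = np.stack(
            [
                np.stack([grab(f"tau[{kl},{tl}]") for tl in tracers], axis=-1)
                for kl in sources
            ],
            axis=2,
        )
        s_ind = np.stack([grab(f"sigma_ind[{tl}]") for tl in tracers], axis=-1)
        s_samp = np.stack([grab(f"sigma_samp[{tl}]") for tl in tracers], axis=-1)
        # renormalize tiny CSV rounding drift
        p = p / p.sum(axis=-1, keepdims=True)
        return cls(
            p=p,
            mu=mu,
            tau=tau,
            sigma_ind=s_ind,
            sigma_samp=s_samp,
            log_prob=np.zeros((C, N)),
            subgroups=subgroups,
            source_names=sources,
            tracers=tracers,
            seed=int(meta.get("seed", 0)),
            n_ensembles=int(meta.get("n_ensembles", 1)),
        )


def _chain_seed(seed: int, chain: int) -> int:
    ss = np.random.SeedSequence([int(seed) % (2**31), chain])
    return int(ss.generate_state(1)[0] % (2**31))


def _initial_walkers(
    density: PosteriorDensity, nwalkers: int, rng: np.random.Generator
) -> np.ndarray:
    """Prior-median starting points with seed-controlled jitter."""
    sl = density.blocks.slices
    D = density.ndim
    pr = density.prior
    theta = np.zeros((nwalkers, D))
    theta[:, sl["z"]] = 0.4 * rng.standard_normal((nwalkers, sl["z"].stop - sl["z"].start))
    if "mu" in sl:
        loc = pr.mu_loc.reshape(-1)
        scale = pr.mu_scale.reshape(-1)
        theta[:, sl["mu"]] = loc + 0.5 * scale * rng.standard_normal(
            (nwalkers, loc.size)
        )
    for name, scales in (
        ("log_tau", pr.tau_scale.reshape(-1)),
        ("log_sigma_ind", pr.sigma_ind_scale.reshape(-1)),
        ("log_sigma_samp", pr.sigma_samp_scale.reshape(-1)),
    ):
        if name in sl:
            # half-normal median is ~0.674 * scale
            med = np.log(0.674 * scales)
            theta[:, sl[name]] = med + 0.3 * rng.standard_normal((nwalkers, med.size))
    lp = density(theta)
    bad = ~np.isfinite(lp)
    tries = 0
    while np.any(bad):
        tries += 1
        if tries > 100:
            raise InitializationError(
                "non-finite log-posterior at initialization; check priors and data"
            )
        theta[bad] += 0.1 * rng.standard_normal((int(bad.sum()), D))
        lp = density(theta)
        bad = ~np.isfinite(lp)
    return theta


def fit_mcmc(
    dataset: StudyDataset,
    prior: Optional[PriorConfig] = None,
    config: Optional[FitConfig] = None,
    fixed: Optional[Mapping[str, np.ndarray]] = None,
) -> PosteriorDraws:
    """Sample the joint posterior; deterministic given (seed, config, data).

    ``fixed`` pins nuisance blocks ("mu", "tau", "sigma_ind",
    "sigma_samp") at known values and removes them from the sampling
    space — used for reduced-model validation runs.
    """
    import emcee

    config = config or FitConfig()
    prior = prior or PriorConfig.from_dataset(dataset)
    density = PosteriorDensity(dataset, prior, fixed=fixed)
    ndim = density.ndim
    nwalkers = config.walkers_for(ndim)

    moves = [
        (emcee.moves.DEMove(), 0.8),
        (emcee.moves.DESnookerMove(), 0.2),
    ]
    all_theta = []  # per ensemble: (draws*nwalkers, D), step-major
    all_lp = []
    acc = []
    for c in range(config.chains):
        rs = _chain_seed(config.seed, c)
        rng = np.random.default_rng(rs)
        theta0 = _initial_walkers(density, nwalkers, rng)
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, density, vectorize=True, moves=moves
        )
        sampler.random_state = np.random.RandomState(rs).get_state()
        sampler.run_mcmc(
            theta0, config.warmup + config.draws, skip_initial_state_check=True
        )
        chain = sampler.get_chain()[config.warmup :]  # (steps, nwalkers, D)
        lp = sampler.get_log_prob()[config.warmup :]
        all_theta.append(chain.reshape(-1, ndim))
        all_lp.append(lp.reshape(-1))
        acc.append(float(np.mean(sampler.acceptance_fraction)))

    theta = np.stack(all_theta, axis=0)  # (chains, draws*nwalkers, D)
    log_prob = np.stack(all_lp, axis=0)
    C, N, D = theta.shape
    flat = theta.reshape(C * N, D)
    p, mu, tau, s_ind, s_samp, _ = density._unpack(flat)
    shape = (C, N)
    return PosteriorDraws(
        p=p.reshape(shape + p.shape[1:]),
        mu=np.broadcast_to(mu, (C * N,) + mu.shape[1:]).reshape(shape + mu.shape[1:]).copy(),
        tau=np.broadcast_to(tau, (C * N,) + tau.shape[1:]).reshape(shape + tau.shape[1:]).copy(),
        sigma_ind=np.broadcast_to(s_ind, (C * N,) + s_ind.shape[1:]).reshape(shape + s_ind.shape[1:]).copy(),
        sigma_samp=np.broadcast_to(s_samp, (C * N,) + s_samp.shape[1:]).reshape(shape + s_samp.shape[1:]).copy(),
        log_prob=log_prob,
        subgroups=density.subgroups,
        source_names=density.source_names,
        tracers=density.tracers,
        seed=config.seed,
        config=config,
        n_ensembles=config.chains,
        n_walkers=nwalkers,
        acceptance_fraction=float(np.mean(acc)),
    )


def convergence_diagnostics(
    draws: PosteriorDraws, rhat_max: float = 1.01, ess_min: float = 100.0
) -> pd.DataFrame:
    """Split-R̂, bulk/tail ESS and a flag per scalar parameter.

    Split-R̂ is computed across the independent-ensemble chains; ESS is
    computed on per-walker trajectories (when the walker factorization is
    known), which carry the sampler's true autocorrelation. With a single
    chain only ESS is reported and every row carries a ``single_chain``
    warning flag. Never mutates ``draws``.
    """
    import arviz as az

    series = draws.scalar_series()
    single = draws.n_chains < 2
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in series.items():
            if np.allclose(arr, arr.reshape(-1)[0]):
                rows.append(
                    {
                        "parameter": name,
                        "rhat": float("nan"),
                        "ess_bulk": 1.0,
                        "ess_tail": 1.0,
                        "flagged": True,
                        "single_chain": single,
                    }
                )
                continue
            data = az.convert_to_dataset(arr[None] if arr.ndim == 1 else arr)
            wv = draws.walker_view(arr)
            ess_data = az.convert_to_dataset(wv) if wv is not None else data
            ess_b = float(az.ess(ess_data, method="bulk").x)
            ess_t = float(az.ess(ess_data, method="tail").x)
            rhat = float("nan") if single else float(az.rhat(data).x)
            flagged = (not single and rhat > rhat_max) or ess_b < ess_min
            rows.append(
                {
                    "parameter": name,
                    "rhat": rhat,
                    "ess_bulk": ess_b,
                    "ess_tail": ess_t,
                    "flagged": bool(flagged),
                    "single_chain": single,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GridPosterior:
    """Deterministic quadrature posterior over p₁ for the two-source model."""

    grid: np.ndarray
    pdf: np.ndarray
    mean: float
    _cdf: np.ndarray = field(repr=False, default=None)

    def quantile(self, q) -> np.ndarray:
        return np.interp(np.asarray(q, float), self._cdf, self.grid)

    def cdf(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, float), self.grid, self._cdf)


def grid_posterior_oracle(
    values: Sequence[float],
    sources: Sequence[SourceSpec],
    sigma: float,
    tracer: str = "d13c",
    alpha: tuple[float, float] = (1.0, 1.0),
    mu: Optional[Sequence[float]] = None,
    grid_size: int = 20001,
) -> GridPosterior:
    """Brute-force posterior of p₁ for K=2 sources, one tracer, bone-only.

    Source means, TEFs, concentrations and the error SD are held fixed; the
    only unknown is the proportion p₁ of the first source. The density is
    evaluated on a midpoint grid over (0, 1) and normalized by quadrature —
    an independent check on the MCMC machinery, not a general-purpose fit.
    """
    if len(sources) != 2:
        raise UnsupportedReductionError("grid oracle requires exactly K=2 sources")
    if grid_size < 10**4:
        raise ValueError("grid size must be >= 10^4")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    y = np.asarray(values, dtype=float).reshape(-1)
    adj = _adjusted_means(sources, tracer, mu=mu)
    if not np.all(np.isfinite(adj)):
        raise ValueError(
            "non-finite adjusted source means; pass mu= when sources carry no samples"
        )
    c = _conc_vector(sources, tracer)
    p1 = (np.arange(grid_size) + 0.5) / grid_size
    den = p1 * c[0] + (1 - p1) * c[1]
    m = (p1 * c[0] * adj[0] + (1 - p1) * c[1] * adj[1]) / den
    loglik = -0.5 * np.sum(
        (y[:, None] - m[None, :]) ** 2, axis=0
    ) / sigma**2
    logprior = (alpha[0] - 1.0) * np.log(p1) + (alpha[1] - 1.0) * np.log(1 - p1)
    logpost = loglik + logprior
    logpost -= logpost.max()
    w = np.exp(logpost)
    w /= w.sum()
    pdf = w * grid_size  # midpoint-rule density
    mean = float(np.sum(p1 * w))
    cdf = np.cumsum(w)
    cdf = cdf - 0.5 * w  # midpoint CDF
    return GridPosterior(grid=p1, pdf=pdf, mean=mean, _cdf=cdf)


class DietMixingModel:
    """Estimator-style front end: configure, ``fit`` a StudyDataset, read
    fitted attributes.

    Parameters mirror :class:`PriorConfig` and :class:`FitConfig`; after
    ``fit`` the instance exposes ``posterior_`` (PosteriorDraws),
    ``prior_``, ``diagnostics_`` (DataFrame) and ``summary_`` (per
    subgroup × source proportion summaries).
    """

    def __init__(
        self,
        alpha: Optional[Sequence[float]] = None,
        tef_mode: str = "fixed",
        propagate_source_variance: bool = False,
        chains: int = 4,
        warmup: int = 1000,
        draws: int = 1000,
        nwalkers: Optional[int] = None,
        seed: int = 0,
    ) -> None:
        self.alpha = alpha
        self.tef_mode = tef_mode
        self.propagate_source_variance = propagate_source_variance
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.nwalkers = nwalkers
        self.seed = seed

    # sklearn-compatible parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {
            "alpha": self.alpha,
            "tef_mode": self.tef_mode,
            "propagate_source_variance": self.propagate_source_variance,
            "chains": self.chains,
            "warmup": self.warmup,
            "draws": self.draws,
            "nwalkers": self.nwalkers,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "DietMixingModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: StudyDataset, y=None) -> "DietMixingModel":
        from .summarize import summarize_proportions

        if not isinstance(X, StudyDataset):
            raise TypeError("X must be a StudyDataset")
        self.prior_ = PriorConfig.from_dataset(
            X,
            alpha=self.alpha,
            tef_mode=self.tef_mode,
            propagate_source_variance=self.propagate_source_variance,
        )
        self.fit_config_ = FitConfig(
            chains=self.chains,
            warmup=self.warmup,
            draws=self.draws,
            seed=self.seed,
            nwalkers=self.nwalkers,
        )
        self.posterior_ = fit_mcmc(X, self.prior_, self.fit_config_)
        self.diagnostics_ = convergence_diagnostics(self.posterior_)
        self.summary_ = summarize_proportions(self.posterior_)
        return self

    def predict(self, X=None) -> pd.DataFrame:
        """Posterior-median proportions per subgroup × source."""
        if not hasattr(self, "posterior_"):
            raise RuntimeError("call fit() first")
        med = np.median(
            self.posterior_.p.reshape(-1, *self.posterior_.p.shape[2:]), axis=0
        )
        return pd.DataFrame(
            med,
            index=list(self.posterior_.subgroups),
            columns=list(self.posterior_.source_names),
        )
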