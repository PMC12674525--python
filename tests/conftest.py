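import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_truth():
    import isodiet as iso

    return iso.default_truth(5)


@pytest.fixture(scope="session")
def default_dataset(default_truth):
    import isodiet as iso

    return iso.generate_dataset(default_truth)


@pytest.fixture(scope="session")
def small_fit(default_dataset):
    """A quick joint fit shared by summary-level tests."""
    import isodiet as iso
    from isodiet.inference import FitConfig

    return iso.fit_mcmc(
        default_dataset, config=FitConfig(chains=2, warmup=400, draws=200, seed=9)
    )


def cs_loglik_quadrature(y, m, u, v, nodes=150):
    """Gauss–Hermite marginalization over the shared individual effect.

    Independent oracle for the compound-symmetry likelihood: integrates the
    product of N(m + a, sqrt(v)) slice densities against the N(0, u) latent
    density. The quadrature is centered and scaled on the integrand's own
    Gaussian envelope so it stays accurate when the conditional posterior of
    the latent effect is much narrower than its prior.
    """
    from scipy.special import logsumexp

    y = np.asarray(y, dtype=float)
    J = y.size
    ybar = float(np.mean(y))
    # Envelope: conditional posterior of a given the data (mean a_star, sd s).
    a_star = u * J * (ybar - m) / (v + J * u)
    s = np.sqrt(u * v / (v + J * u))
    x, w = np.polynomial.hermite.hermgauss(nodes)
    a = a_star + np.sqrt(2.0) * s * x  # (nodes,)
    log_h = (
        -0.5 * np.log(2 * np.pi * u)
        - a**2 / (2 * u)
        + np.sum(
            -0.5 * np.log(2 * np.pi * v) - (y[:, None] - (m + a[None, :])) ** 2 / (2 * v),
            axis=0,
        )
    )
    return float(
        logsumexp(np.log(w) + x**2 + log_h) + 0.5 * np.log(2.0) + np.log(s)
    )
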