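import numpy as np
import pytest

from pqifgene.qif import LongitudinalDesign


def make_binary_design(seed, n=80, T=3, p=3, beta=None, rho=0.0):
    """Small balanced logistic panel used across unit tests.

    Covariates are mostly time-invariant (subject level plus a small
    per-visit perturbation), mirroring designs whose within-subject margins
    stay close enough for any exchangeable binary correlation up to ~0.5 to
    be attainable.  With rho=0 visits are independent; otherwise the
    Emrich-Piedmonte construction induces the requested correlation.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, 1, p - 1))
    jitter = 0.1 * rng.normal(size=(n, T, p - 1))
    X = np.concatenate([np.ones((n, T, 1)), base + jitter], axis=2)
    if beta is None:
        beta = np.linspace(0.4, -0.4, p)
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    if rho == 0.0:
        y = (rng.random((n, T)) < mu).astype(float)
    else:
        from pqifgene.simulate import simulate_responses

        y = simulate_responses(mu, "exchangeable", rho, rng)
    cols = ["intercept"] + [f"x{j}" for j in range(1, p)]
    return LongitudinalDesign(
        y=y, X=X, mask=np.ones((n, T), dtype=bool), columns=cols
    ), np.asarray(beta, dtype=float)


@pytest.fixture
def small_design():
    return make_binary_design(seed=11)[0]
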