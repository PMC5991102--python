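"""Seeded affine-invariant ensemble MCMC (Goodman & Weare stretch moves).

A minimal dependency-free sampler sufficient for the low-dimensional,
cheap-likelihood posteriors in this package.  Walkers are updated in two
half-ensemble sweeps so the log-posterior can be evaluated on a whole batch
of parameter vectors at once (``vectorized=True``), which is what keeps the
repeated-fit coverage simulations fast.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["run_ensemble", "split_rhat", "effective_sample_size"]


def _eval(log_prob: Callable, x: np.ndarray, vectorized: bool) -> np.ndarray:
    if vectorized:
        return np.asarray(log_prob(x), dtype=float)
    return np.array([log_prob(xi) for xi in x], dtype=float)


def run_ensemble(
    log_prob: Callable,
    p0: np.ndarray,
    n_burn: int,
    n_steps: int,
    rng: np.random.Generator,
    a: float = 2.0,
    vectorized: bool = False,
    return_log_prob: bool = False,
) -> np.ndarray:
    """Sample with stretch moves; returns chain (n_steps, n_walkers, ndim).

    With ``return_log_prob=True`` also returns the matching
    (n_steps, n_walkers) log-posterior values (free — they are tracked for
    the accept/reject step anyway).

    ``p0`` is the (n_walkers, ndim) initial ensemble; walkers with initially
    non-finite posterior are rejected with an error since the ensemble cannot
    recover from an all-invalid start.  ``a`` is the stretch scale (2.0 is
    the standard choice).
    """
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    n_walkers, ndim = p0.shape
    if n_walkers < 2 * ndim or n_walkers % 2:
        raise ValueError("need an even number of walkers, at least 2*ndim")
    x = p0.copy()
    lp = _eval(log_prob, x, vectorized)
    if not np.all(np.isfinite(lp)):
        bad = np.flatnonzero(~np.isfinite(lp))
        raise ValueError(
            f"{bad.size} walkers start at zero posterior density "
            f"(first bad walker: {x[bad[0]]})"
        )
    half = n_walkers // 2
    chain = np.empty((n_steps, n_walkers, ndim))
    chain_lp = np.empty((n_steps, n_walkers))
    for step in range(n_burn + n_steps):
        for first in (slice(0, half), slice(half, n_walkers)):
            other = slice(half, n_walkers) if first.start == 0 else slice(0, half)
            xs, xo = x[first], x[other]
            k = xs.shape[0]
            # stretch factor z ~ g(z) prop. 1/sqrt(z) on [1/a, a]
            z = (1.0 + (a - 1.0) * rng.random(k)) ** 2 / a
            partners = rng.integers(0, xo.shape[0], size=k)
            proposal = xo[partners] + z[:, None] * (xs - xo[partners])
            lp_prop = _eval(log_prob, proposal, vectorized)
            log_accept = (ndim - 1.0) * np.log(z) + lp_prop - lp[first]
            accept = np.log(rng.random(k)) < log_accept
            xs[accept] = proposal[accept]
            lp_slice = lp[first]
            lp_slice[accept] = lp_prop[accept]
            lp[first] = lp_slice
        if step >= n_burn:
            chain[step - n_burn] = x
            chain_lp[step - n_burn] = lp
    if return_log_prob:
        return chain, chain_lp
    return chain


def split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter for a (n_steps, n_walkers, ndim) chain."""
    import arviz as az

    return np.asarray(
        az.rhat(az.convert_to_dataset(_to_arviz(chain))).to_array()
    ).ravel()


def effective_sample_size(chain: np.ndarray) -> np.ndarray:
    """Bulk effective sample size per parameter."""
    import arviz as az

    return np.asarray(
        az.ess(az.convert_to_dataset(_to_arviz(chain))).to_array()
    ).ravel()


def _to_arviz(chain: np.ndarray) -> np.ndarray:
    # arviz expects (chain, draw, ...); treat each walker as a chain
    return np.moveaxis(chain, 1, 0)
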