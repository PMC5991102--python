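"""Grand-canonical (fugacity) model of repressor titration by many promoters.

When N identical specific binding sites (e.g. a reporter carried on a
multi-copy plasmid) compete for a fixed pool of R_tot repressors, the
chemical potential mu of the repressor — through its fugacity
lambda_r = e^{mu} — distributes the active repressors over specific and
non-specific sites.  The fold-change of any one promoter is then
1/(1 + lambda_r e^{-d_eps_ra}).

The behaviour of fold-change versus R_tot changes qualitatively when the
number of active repressors p_A(0) R_tot crosses N, which is what makes
repression-versus-copy-number data informative about the allosteric energy
difference d_eps_ai: historical binding energies fitted assuming all
repressors active are convoluted values d_eps_ra_tilde, related to the true
energy by beta*d_eps_ra = beta*d_eps_ra_tilde + log p_A(0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

from .model import N_NS_DEFAULT

__all__ = [
    "MultiPromoterSpec",
    "TitrationDataset",
    "effective_to_true_energy",
    "true_to_effective_energy",
    "solve_fugacity",
    "fold_change_multi",
    "fit_d_eps_ai",
    "DeltaEpsAIModel",
]

# bracket for the root find on ln(lambda_r); the conservation function is
# monotone in lambda_r so the root is unique
_LAMBDA_BRACKET = (1e-15, 1e6)
_RTOL = 1e-12

#: Above this allosteric energy essentially all repressors are active and the
#: data can only bound d_eps_ai from below.
LOWER_BOUND_REGIME = 5.0


@dataclass(frozen=True)
class MultiPromoterSpec:
    """N competing specific promoters sharing R_tot repressor dimers."""

    n_promoters: float
    r_total: float
    d_eps_ra: float
    d_eps_ai: float
    n_ns: float = N_NS_DEFAULT

    def __post_init__(self) -> None:
        if self.n_promoters < 1:
            raise ValueError("n_promoters must be >= 1")
        if self.r_total < 0:
            raise ValueError("r_total must be >= 0")
        if not self.n_ns > self.n_promoters:
            raise ValueError("n_ns must exceed n_promoters")


def _pa0(d_eps_ai: float) -> float:
    # active fraction at zero inducer
    return 1.0 / (1.0 + np.exp(-d_eps_ai))


def effective_to_true_energy(d_eps_ra_tilde: float, d_eps_ai: float) -> float:
    """Convoluted (all-active assumption) binding energy -> true energy.

    beta*d_eps_ra = beta*d_eps_ra_tilde + log(1/(1+e^{-d_eps_ai})).
    """
    return float(d_eps_ra_tilde + np.log(_pa0(d_eps_ai)))


def true_to_effective_energy(d_eps_ra: float, d_eps_ai: float) -> float:
    """Inverse of `effective_to_true_energy` (round-trips to 1e-12)."""
    return float(d_eps_ra - np.log(_pa0(d_eps_ai)))


def _conservation_gap(lam: float, m: MultiPromoterSpec) -> float:
    # active pool minus repressors accounted for at fugacity lam
    w = lam * np.exp(-m.d_eps_ra)
    r_s = m.n_promoters * w / (1.0 + w)
    r_ns = m.n_ns * lam / (1.0 + lam)
    return _pa0(m.d_eps_ai) * m.r_total - (r_s + r_ns)


def solve_fugacity_arrays(
    n_promoters,
    r_total,
    d_eps_ra,
    d_eps_ai,
    n_ns: float = N_NS_DEFAULT,
    n_iter: int = 100,
) -> np.ndarray:
    """Vectorized fugacity solve by bisection on ln(lambda_r).

    All arguments broadcast; zero r_total entries return lambda_r = 0.
    The conservation gap is monotone in lambda_r so bisection is safe; 160
    halvings of the ~48-log-unit bracket are ample for machine precision.
    """
    n_promoters, r_total, d_eps_ra, d_eps_ai = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (n_promoters, r_total, d_eps_ra, d_eps_ai))
    )
    pa0 = 1.0 / (1.0 + np.exp(-d_eps_ai))

    def gap(loglam):
        lam = np.exp(loglam)
        w = lam * np.exp(-d_eps_ra)
        return pa0 * r_total - (n_promoters * w / (1.0 + w) + n_ns * lam / (1.0 + lam))

    lo = np.full(r_total.shape, np.log(_LAMBDA_BRACKET[0]))
    hi = np.full(r_total.shape, np.log(_LAMBDA_BRACKET[1]))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        pos = gap(mid) > 0  # need larger lambda
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    lam = np.exp(0.5 * (lo + hi))
    return np.where(r_total == 0, 0.0, lam)


def solve_fugacity(m: MultiPromoterSpec) -> float:
    """Fugacity lambda_r distributing the active repressor pool over sites.

    Solves repressor conservation p_A(0) R_tot = R_S + R_NS for the unique
    positive root, where R_S = N w/(1+w) with w = lambda_r e^{-d_eps_ra} and
    R_NS = N_NS lambda_r/(1+lambda_r).  Returns 0 for an empty pool.
    """
    if m.r_total == 0:
        return 0.0
    lo, hi = _LAMBDA_BRACKET
    f = lambda loglam: _conservation_gap(np.exp(loglam), m)
    flo, fhi = f(np.log(lo)), f(np.log(hi))
    if flo * fhi > 0:
        raise RuntimeError(
            "fugacity bracket does not straddle the conservation root: "
            f"f({lo:g})={flo:g}, f({hi:g})={fhi:g} for {m}"
        )
    root = brentq(f, np.log(lo), np.log(hi), rtol=_RTOL, xtol=1e-300)
    return float(np.exp(root))


def fold_change_multi(m: MultiPromoterSpec) -> float:
    """Fold-change of one of N competing promoters at zero inducer.

    1/(1 + lambda_r e^{-d_eps_ra}); converges to the single-promoter
    simple-repression result when N = 1 and R_tot << N_NS.
    """
    lam = solve_fugacity(m)
    return float(1.0 / (1.0 + lam * np.exp(-m.d_eps_ra)))


class TitrationDataset(NamedTuple):
    """Fold-change versus total repressor count at fixed promoter number N.

    ``d_eps_ra_tilde`` is the convoluted binding energy of the operator
    carried by the N promoters (fitted historically under the all-active
    assumption).
    """

    n_promoters: float
    r_total: Sequence[float]
    fold_change: Sequence[float]
    d_eps_ra_tilde: float


@dataclass
class DeltaEpsAIResults:
    """Posterior summary for the allosteric energy difference."""

    samples: np.ndarray  # draws of (d_eps_ai, log10 sigma)
    mode: float
    ci_lower: float
    ci_upper: float
    lower_bound_only: bool
    seed: int

    def summary(self) -> str:
        kind = "lower bound" if self.lower_bound_only else "estimate"
        return (
            f"d_eps_ai {kind}: mode={self.mode:.3f} kBT, "
            f"95% CI [{self.ci_lower:.3f}, {self.ci_upper:.3f}] "
            f"({self.samples.shape[0]} draws, seed={self.seed})"
        )


class DeltaEpsAIModel:
    """Fit d_eps_ai to repression-versus-copy-number datasets.

    For each candidate d_eps_ai the convoluted energies are converted to true
    energies and the grand-canonical fold-change is predicted for every
    (N, R_tot) point; residuals enter the same iid Gaussian likelihood used
    for the induction fits.  Above ~5 k_BT the predictions become insensitive
    to d_eps_ai (all repressors active), so the estimate is flagged as a
    lower bound there.
    """

    def __init__(
        self,
        datasets: Sequence[TitrationDataset],
        n_ns: float = N_NS_DEFAULT,
        prior_bounds: tuple[float, float] = (-2.0, 12.0),
    ) -> None:
        if len(datasets) == 0:
            raise ValueError("at least one titration dataset is required")
        self.datasets = list(datasets)
        self.n_ns = n_ns
        self.prior_bounds = prior_bounds
        self._rows = None
        self._obs = None
        for ds in self.datasets:
            r = np.asarray(ds.r_total, dtype=float)
            if not np.any(_pa0(LOWER_BOUND_REGIME) * r < ds.n_promoters) or not np.any(
                _pa0(LOWER_BOUND_REGIME) * r > ds.n_promoters
            ):
                warnings.warn(
                    f"dataset N={ds.n_promoters}: repressor counts do not "
                    "straddle the p_A(0) R_tot = N transition; d_eps_ai may "
                    "be poorly identified",
                    stacklevel=2,
                )

    def _row_arrays(self):
        if self._rows is not None:
            return self._rows
        n = np.concatenate(
            [np.full(len(ds.r_total), ds.n_promoters) for ds in self.datasets]
        )
        r = np.concatenate(
            [np.asarray(ds.r_total, dtype=float) for ds in self.datasets]
        )
        dtil = np.concatenate(
            [np.full(len(ds.r_total), ds.d_eps_ra_tilde) for ds in self.datasets]
        )
        self._rows = (n, r, dtil)
        return self._rows

    def predict(self, d_eps_ai) -> np.ndarray:
        """Fold-change for every data row; d_eps_ai may be scalar or a column
        vector of candidates (shape (k, 1)) for batched evaluation."""
        n, r, dtil = self._row_arrays()
        d_eps_ai = np.asarray(d_eps_ai, dtype=float)
        pa0 = 1.0 / (1.0 + np.exp(-d_eps_ai))
        d_eps_ra = dtil + np.log(pa0)
        lam = solve_fugacity_arrays(n, r, d_eps_ra, d_eps_ai, self.n_ns)
        return 1.0 / (1.0 + lam * np.exp(-d_eps_ra))

    def _observed(self) -> np.ndarray:
        if self._obs is None:
            self._obs = np.concatenate(
                [np.asarray(ds.fold_change, dtype=float) for ds in self.datasets]
            )
        return self._obs

    def log_posterior(self, theta: np.ndarray):
        """Log posterior of (d_eps_ai, log10 sigma); vectorized over rows of a
        (k, 2) batch (flat prior in log10 sigma = Jeffreys in sigma)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        d_eps_ai, log10_sigma = theta[:, 0], theta[:, 1]
        lo, hi = self.prior_bounds
        ok = (
            (d_eps_ai >= lo) & (d_eps_ai <= hi)
            & (log10_sigma >= -5.0) & (log10_sigma <= 0.0)
        )
        out = np.full(theta.shape[0], -np.inf)
        if np.any(ok):
            sigma = 10.0 ** log10_sigma[ok]
            resid = self._observed() - self.predict(d_eps_ai[ok][:, None])
            n = resid.shape[-1]
            out[ok] = -n * np.log(sigma) - 0.5 * np.sum(resid**2, axis=-1) / sigma**2
        return out if theta.shape[0] > 1 else float(out[0])

    def fit(
        self,
        seed: int = 0,
        n_walkers: int = 24,
        n_burn: int = 400,
        n_steps: int = 700,
    ) -> DeltaEpsAIResults:
        from .sampler import run_ensemble
        from .summaries import marginal_mode

        rng = np.random.default_rng(seed)
        lo, hi = self.prior_bounds
        p0 = np.column_stack(
            [
                rng.uniform(lo + 0.5, hi - 0.5, n_walkers),
                rng.uniform(-2.5, -1.0, n_walkers),
            ]
        )
        chain = run_ensemble(
            self.log_posterior, p0, n_burn=n_burn, n_steps=n_steps, rng=rng,
            vectorized=True,
        )
        draws = chain.reshape(-1, 2)
        eps = draws[:, 0]
        mode = marginal_mode(eps)
        ci_lo, ci_hi = np.percentile(eps, [2.5, 97.5])
        lower_only = bool(mode > LOWER_BOUND_REGIME or ci_hi > hi - 0.5)
        return DeltaEpsAIResults(
            samples=draws,
            mode=float(mode),
            ci_lower=float(ci_lo),
            ci_upper=float(ci_hi),
            lower_bound_only=lower_only,
            seed=seed,
        )


def fit_d_eps_ai(
    datasets: Sequence[TitrationDataset], seed: int = 0, **kwargs
) -> DeltaEpsAIResults:
    """Posterior over d_eps_ai from repression-vs-copy-number datasets."""
    return DeltaEpsAIModel(datasets).fit(seed=seed, **kwargs)
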