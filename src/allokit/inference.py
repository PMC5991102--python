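"""Bayesian estimation of the allosteric parameters from induction tables.

The measurement model is deliberately simple: observed fold-change deviates
from the thermodynamic prediction by iid Gaussian noise of unknown scale
sigma.  Dissociation constants are sampled as negative base-10 logarithms
k~ = -log10(K / 1 M) with uniform priors on [-7, 7]; sigma carries a Jeffreys
prior, regularized by sampling log10(sigma) on [-5, 0].  Posteriors are
summarized by the marginal KDE mode and equal-tailed 95% credible bounds.

Model classes follow the statsmodels convention: construct from data, call
``fit(seed=...)``, get a results object with draws, modes, credible bounds,
diagnostics and ``summary()``.  The module-level functions
(`fit_single_strain`, `fit_global`, `fit_hill`, ...) are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import model as mwc
from .model import AllosterySpec, StrainSpec, FlatResponseError
from .sampler import run_ensemble, split_rhat, effective_sample_size
from .summaries import credible_interval, marginal_mode, summarize_draws

__all__ = [
    "PosteriorSamples",
    "GlobalFitPriors",
    "SingleStrainModel",
    "GlobalFitModel",
    "HillModel",
    "HillThermoModel",
    "log_likelihood",
    "log_prior_single",
    "log_prior_global",
    "fit_single_strain",
    "fit_global",
    "fit_hill",
    "fit_hill_thermo",
    "degeneracy_scan",
    "propagate_properties",
]

KT_BOUNDS = (-7.0, 7.0)
LOG10_SIGMA_BOUNDS = (-5.0, 0.0)
D_EPS_AI_DEFAULT = 4.5
REQUIRED_COLUMNS = ("d_eps_ra_kT", "repressors", "iptg_M", "fold_change")


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class PosteriorSamples:
    """Flattened MCMC draws with convergence diagnostics.

    ``draws`` is (n_draws, ndim); ``diagnostics`` holds per-parameter
    split-R-hat and bulk effective sample size, computed before any summary
    is reported.
    """

    draws: np.ndarray
    names: list
    diagnostics: pd.DataFrame
    seed: int
    chain: Optional[np.ndarray] = field(default=None, repr=False)
    log_post: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("posterior draws contain non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names)

    def converged(self, rhat_max: float = 1.1, ess_min: float = 400.0) -> bool:
        d = self.diagnostics
        return bool((d["rhat"] < rhat_max).all() and (d["ess"] > ess_min).all())


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"induction table missing columns: {missing}")
    return table.reset_index(drop=True)


def _predict_foldchange(kt_a, kt_i, c, repressors, d_eps_ra, d_eps_ai, n_sites):
    """Vectorized thermodynamic fold-change; kt arrays broadcast against rows.

    ``kt_a``/``kt_i`` may be scalars or (k, 1) walker columns; the row data
    ``c``, ``repressors``, ``d_eps_ra`` are 1-D of common length m.
    """
    ka = 10.0 ** (-np.asarray(kt_a, dtype=float))
    ki = 10.0 ** (-np.asarray(kt_i, dtype=float))
    r = (1.0 + c / ki) / (1.0 + c / ka)
    pa = 1.0 / (1.0 + np.exp(-d_eps_ai) * r**n_sites)
    rho = repressors / mwc.N_NS_DEFAULT * np.exp(-d_eps_ra)
    return 1.0 / (1.0 + pa * rho)


def log_likelihood(
    params: Sequence[float],
    table: pd.DataFrame,
    d_eps_ai: float = D_EPS_AI_DEFAULT,
    n_sites: int = 2,
) -> float:
    """Gaussian iid log-likelihood of a table under (k~_A, k~_I, sigma).

    Non-finite predictions yield -inf (and a warning) rather than an
    exception, so samplers can reject such parameter vectors.
    """
    kt_a, kt_i, sigma = params
    table = _validate_table(table)
    pred = _predict_foldchange(
        kt_a,
        kt_i,
        table["iptg_M"].to_numpy(),
        table["repressors"].to_numpy(),
        table["d_eps_ra_kT"].to_numpy(),
        d_eps_ai,
        n_sites,
    )
    if not np.all(np.isfinite(pred)):
        warnings.warn("non-finite fold-change prediction; log-likelihood -inf")
        return -np.inf
    resid = table["fold_change"].to_numpy() - pred
    n = resid.size
    return float(
        -0.5 * n * np.log(2.0 * np.pi * sigma**2)
        - 0.5 * np.sum(resid**2) / sigma**2
    )


def log_prior_single(params: Sequence[float]) -> float:
    """Uniform prior on k~_A, k~_I over [-7, 7]; Jeffreys 1/sigma on sigma."""
    kt_a, kt_i, sigma = params
    lo, hi = KT_BOUNDS
    if not (lo <= kt_a <= hi and lo <= kt_i <= hi):
        return -np.inf
    s_lo, s_hi = 10.0 ** LOG10_SIGMA_BOUNDS[0], 10.0 ** LOG10_SIGMA_BOUNDS[1]
    if not (s_lo <= sigma <= s_hi):
        return -np.inf
    return float(-np.log(sigma))


@dataclass(frozen=True)
class GlobalFitPriors:
    """Gaussian informative priors on repressor counts and binding energies.

    Keyed by the nominal repressor count (RBS variant) and operator name as
    they appear in the induction table.
    """

    r_means: dict
    r_sds: dict
    eps_means: dict
    eps_sds: dict

    def __post_init__(self) -> None:
        if any(sd <= 0 for sd in self.r_sds.values()) or any(
            sd <= 0 for sd in self.eps_sds.values()
        ):
            raise ValueError("all prior SDs must be positive")


def log_prior_global(params: Sequence[float], priors: GlobalFitPriors) -> float:
    """Single-strain priors plus independent Gaussians on each R and eps.

    ``params`` is (k~_A, k~_I, R_1..R_nr, eps_1..eps_ne, sigma), with R and
    eps ordered as in the sorted prior dictionaries.
    """
    r_keys = sorted(priors.r_means)
    e_keys = sorted(priors.eps_means)
    nr, ne = len(r_keys), len(e_keys)
    kt_a, kt_i = params[0], params[1]
    r_vals = np.asarray(params[2 : 2 + nr], dtype=float)
    e_vals = np.asarray(params[2 + nr : 2 + nr + ne], dtype=float)
    sigma = params[2 + nr + ne]
    base = log_prior_single((kt_a, kt_i, sigma))
    if not np.isfinite(base) or np.any(r_vals < 0):
        return -np.inf
    lp = base
    for val, key in zip(r_vals, r_keys):
        mu, sd = priors.r_means[key], priors.r_sds[key]
        lp += -0.5 * np.log(2 * np.pi * sd**2) - 0.5 * ((val - mu) / sd) ** 2
    for val, key in zip(e_vals, e_keys):
        mu, sd = priors.eps_means[key], priors.eps_sds[key]
        lp += -0.5 * np.log(2 * np.pi * sd**2) - 0.5 * ((val - mu) / sd) ** 2
    return float(lp)


def _diagnose(chain: np.ndarray, names, seed: int, lp=None) -> PosteriorSamples:
    diag = pd.DataFrame(
        {"rhat": split_rhat(chain), "ess": effective_sample_size(chain)},
        index=list(names),
    )
    samples = PosteriorSamples(
        draws=chain.reshape(-1, chain.shape[-1]),
        names=list(names),
        diagnostics=diag,
        seed=seed,
        chain=chain,
        log_post=None if lp is None else lp.ravel(),
    )
    if not samples.converged():
        warnings.warn(
            f"chain convergence contract not met:\n{diag}", ConvergenceWarning
        )
    return samples


class _MCMCResults:
    """Shared results behaviour: modes, credible bounds, summary table."""

    def __init__(self, posterior: PosteriorSamples, model) -> None:
        self.posterior = posterior
        self.model = model

    @property
    def params(self) -> pd.Series:
        """Marginal KDE modes (the reported point estimates)."""
        return pd.Series(
            {
                name: marginal_mode(self.posterior.draws[:, j])
                for j, name in enumerate(self.posterior.names)
            }
        )

    @property
    def map_params(self) -> pd.Series:
        """The single highest-posterior draw: a jointly coherent parameter
        vector, used for point predictions (marginal modes need not be)."""
        if self.posterior.log_post is None:
            return self.params
        j = int(np.argmax(self.posterior.log_post))
        return pd.Series(self.posterior.draws[j], index=self.posterior.names)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        rows = {
            name: credible_interval(self.posterior.draws[:, j], level)
            for j, name in enumerate(self.posterior.names)
        }
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        tab = summarize_draws(self.posterior.draws, self.posterior.names, level)
        tab["rhat"] = self.posterior.diagnostics["rhat"].values
        tab["ess"] = self.posterior.diagnostics["ess"].values
        return tab


class SingleStrainModel:
    """MWC induction fit for one (R, d_eps_ra) strain.

    Fits (k~_A, k~_I, sigma) to a single strain's titration with d_eps_ai
    fixed (it is degenerate with the dissociation constants on single-strain
    data and must come from an independent experiment).
    """

    param_names = ["kt_a", "kt_i", "sigma"]

    def __init__(
        self,
        table: pd.DataFrame,
        d_eps_ai: float = D_EPS_AI_DEFAULT,
        n_sites: int = 2,
    ) -> None:
        table = _validate_table(table)
        strains = table[["repressors", "d_eps_ra_kT"]].drop_duplicates()
        if len(strains) != 1:
            raise ValueError(
                f"single-strain fit requires one (R, d_eps_ra); got {len(strains)}"
            )
        if table["iptg_M"].nunique() < 6:
            raise ValueError(
                "need at least 6 distinct inducer concentrations to constrain "
                "the dissociation constants"
            )
        self.table = table
        self.d_eps_ai = d_eps_ai
        self.n_sites = n_sites
        self.strain = StrainSpec(
            repressors=float(strains["repressors"].iloc[0]),
            d_eps_ra=float(strains["d_eps_ra_kT"].iloc[0]),
        )
        self._c = table["iptg_M"].to_numpy()
        self._obs = table["fold_change"].to_numpy()
        self._rho = (
            self.strain.repressors
            / self.strain.n_ns
            * np.exp(-self.strain.d_eps_ra)
        )
        obs_range = self._obs.max() - self._obs.min()
        if obs_range < 0.2:
            warnings.warn(
                "observed response is nearly flat; expect a wide, degenerate "
                "posterior for the dissociation constants"
            )

    @classmethod
    def from_dataframe(cls, table, **kwargs) -> "SingleStrainModel":
        return cls(table, **kwargs)

    # log posterior over (kt_a, kt_i, log10_sigma), vectorized over walkers
    def _log_post(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        kt_a, kt_i, l10s = theta[:, 0:1], theta[:, 1:2], theta[:, 2]
        lo, hi = KT_BOUNDS
        s_lo, s_hi = LOG10_SIGMA_BOUNDS
        ok = (
            (kt_a[:, 0] >= lo) & (kt_a[:, 0] <= hi)
            & (kt_i[:, 0] >= lo) & (kt_i[:, 0] <= hi)
            & (l10s >= s_lo) & (l10s <= s_hi)
        )
        out = np.full(theta.shape[0], -np.inf)
        if not np.any(ok):
            return out
        pred = _predict_foldchange(
            kt_a[ok],
            kt_i[ok],
            self._c,
            self.strain.repressors,
            self.strain.d_eps_ra,
            self.d_eps_ai,
            self.n_sites,
        )
        sigma = 10.0 ** l10s[ok]
        resid = self._obs - pred
        n = self._obs.size
        # flat prior in log10(sigma) is the Jeffreys prior in sigma
        out[ok] = -n * np.log(sigma) - 0.5 * np.sum(resid**2, axis=1) / sigma**2
        return out

    def _initial_point(self) -> np.ndarray:
        """Crude multi-start least-squares point to seed the walker ball."""
        best, best_val = None, np.inf
        for kt_a0 in (1.0, 3.0, 5.0):
            for kt_i0 in (2.0, 4.0, 6.0):
                res = minimize(
                    lambda p: float(
                        np.sum(
                            (
                                self._obs
                                - _predict_foldchange(
                                    p[0], p[1], self._c,
                                    self.strain.repressors,
                                    self.strain.d_eps_ra,
                                    self.d_eps_ai, self.n_sites,
                                )
                            )
                            ** 2
                        )
                    ),
                    x0=[kt_a0, kt_i0],
                    method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400},
                )
                if res.fun < best_val:
                    best, best_val = res.x, res.fun
        sigma0 = np.sqrt(best_val / max(self._obs.size - 2, 1))
        l10s0 = np.clip(np.log10(max(sigma0, 1e-4)), -4.5, -0.5)
        return np.array([
            np.clip(best[0], -6.5, 6.5), np.clip(best[1], -6.5, 6.5), l10s0
        ])

    def fit(
        self,
        seed: int = 0,
        n_walkers: int = 64,
        n_burn: int = 600,
        n_steps: int = 800,
    ) -> "SingleStrainResults":
        rng = np.random.default_rng(seed)
        center = self._initial_point()
        p0 = center + 0.05 * rng.standard_normal((n_walkers, 3))
        chain, lp = run_ensemble(
            self._log_post, p0, n_burn=n_burn, n_steps=n_steps, rng=rng,
            vectorized=True, return_log_prob=True,
        )
        # report sigma on its natural scale
        chain = chain.copy()
        chain[..., 2] = 10.0 ** chain[..., 2]
        posterior = _diagnose(chain, self.param_names, seed, lp)
        return SingleStrainResults(posterior, self)


class SingleStrainResults(_MCMCResults):
    """Posterior for (k~_A, k~_I, sigma) with property propagation."""

    @property
    def allostery(self) -> AllosterySpec:
        p = self.params
        return AllosterySpec(
            ka=10.0 ** (-p["kt_a"]),
            ki=10.0 ** (-p["kt_i"]),
            d_eps_ai=self.model.d_eps_ai,
            n_sites=self.model.n_sites,
        )

    def predict(self, c, strain: Optional[StrainSpec] = None):
        strain = strain or self.model.strain
        p = self.map_params
        a = AllosterySpec(
            ka=10.0 ** (-p["kt_a"]),
            ki=10.0 ** (-p["kt_i"]),
            d_eps_ai=self.model.d_eps_ai,
            n_sites=self.model.n_sites,
        )
        return mwc.fold_change(c, a, strain)

    def propagate_properties(
        self, strain: Optional[StrainSpec] = None, level: float = 0.95
    ) -> pd.DataFrame:
        strain = strain or self.model.strain
        return propagate_properties(
            self.posterior,
            strain,
            d_eps_ai=self.model.d_eps_ai,
            n_sites=self.model.n_sites,
            level=level,
        )


class GlobalFitModel:
    """Joint fit of k~_A, k~_I, every R, every d_eps_ra, and sigma.

    Informative Gaussian priors keep the repressor counts and binding
    energies near their independently measured values while letting the fit
    absorb calibration error in those measurements.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        priors: GlobalFitPriors,
        d_eps_ai: float = D_EPS_AI_DEFAULT,
        n_sites: int = 2,
    ) -> None:
        table = _validate_table(table)
        if "operator" not in table.columns:
            raise ValueError("global fit requires an 'operator' column")
        ops = sorted(table["operator"].unique())
        rbs = sorted(table["repressors"].unique())
        if len(ops) < 2 or len(rbs) < 2:
            raise ValueError(
                "global fit requires >= 2 operators and >= 2 repressor "
                f"copy-number variants; got {len(ops)} and {len(rbs)}"
            )
        for key in rbs:
            if key not in priors.r_means:
                raise ValueError(f"no repressor-count prior for RBS variant {key}")
        for key in ops:
            if key not in priors.eps_means:
                raise ValueError(f"no binding-energy prior for operator {key}")
        self.table = table
        self.priors = priors
        self.d_eps_ai = d_eps_ai
        self.n_sites = n_sites
        self.r_keys = sorted(priors.r_means)
        self.e_keys = sorted(priors.eps_means)
        # keep only prior entries present in the data when indexing rows
        self._r_idx = table["repressors"].map(
            {k: j for j, k in enumerate(self.r_keys)}
        ).to_numpy()
        self._e_idx = table["operator"].map(
            {k: j for j, k in enumerate(self.e_keys)}
        ).to_numpy()
        self._c = table["iptg_M"].to_numpy()
        self._obs = table["fold_change"].to_numpy()
        self.param_names = (
            ["kt_a", "kt_i"]
            + [f"R[{k}]" for k in self.r_keys]
            + [f"eps[{k}]" for k in self.e_keys]
            + ["sigma"]
        )

    def _log_post(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        nr, ne = len(self.r_keys), len(self.e_keys)
        kt_a = theta[:, 0:1]
        kt_i = theta[:, 1:2]
        r_par = theta[:, 2 : 2 + nr]
        e_par = theta[:, 2 + nr : 2 + nr + ne]
        l10s = theta[:, 2 + nr + ne]
        lo, hi = KT_BOUNDS
        s_lo, s_hi = LOG10_SIGMA_BOUNDS
        ok = (
            (kt_a[:, 0] >= lo) & (kt_a[:, 0] <= hi)
            & (kt_i[:, 0] >= lo) & (kt_i[:, 0] <= hi)
            & (l10s >= s_lo) & (l10s <= s_hi)
            & np.all(r_par >= 0, axis=1)
        )
        out = np.full(theta.shape[0], -np.inf)
        if not np.any(ok):
            return out
        rows_r = r_par[ok][:, self._r_idx]
        rows_e = e_par[ok][:, self._e_idx]
        pred = _predict_foldchange(
            kt_a[ok], kt_i[ok], self._c, rows_r, rows_e,
            self.d_eps_ai, self.n_sites,
        )
        sigma = 10.0 ** l10s[ok]
        n = self._obs.size
        ll = -n * np.log(sigma) - 0.5 * np.sum(
            (self._obs - pred) ** 2, axis=1
        ) / sigma**2
        r_mu = np.array([self.priors.r_means[k] for k in self.r_keys])
        r_sd = np.array([self.priors.r_sds[k] for k in self.r_keys])
        e_mu = np.array([self.priors.eps_means[k] for k in self.e_keys])
        e_sd = np.array([self.priors.eps_sds[k] for k in self.e_keys])
        lp = (
            -0.5 * np.sum(((r_par[ok] - r_mu) / r_sd) ** 2, axis=1)
            - 0.5 * np.sum(((e_par[ok] - e_mu) / e_sd) ** 2, axis=1)
        )
        out[ok] = ll + lp
        return out

    def fit(
        self,
        seed: int = 0,
        n_walkers: Optional[int] = None,
        n_burn: int = 3000,
        n_steps: int = 1500,
    ) -> "GlobalFitResults":
        ndim = len(self.param_names)
        n_walkers = n_walkers or max(4 * ndim, 40)
        if n_walkers % 2:
            n_walkers += 1
        rng = np.random.default_rng(seed)
        # seed walkers at the prior means with a conditional (kt) optimum
        center = np.empty(ndim)
        r_mu = np.array([self.priors.r_means[k] for k in self.r_keys])
        e_mu = np.array([self.priors.eps_means[k] for k in self.e_keys])
        kt0 = self._conditional_kt(r_mu, e_mu)
        center[0:2] = kt0[:2]
        center[2 : 2 + len(r_mu)] = r_mu
        center[2 + len(r_mu) : 2 + len(r_mu) + len(e_mu)] = e_mu
        center[-1] = kt0[2]
        scale = np.concatenate(
            [
                [0.05, 0.05],
                0.01 * np.maximum(r_mu, 1.0),
                0.02 * np.ones(len(e_mu)),
                [0.05],
            ]
        )
        p0 = center + scale * rng.standard_normal((n_walkers, ndim))
        chain, lp = run_ensemble(
            self._log_post, p0, n_burn=n_burn, n_steps=n_steps, rng=rng,
            vectorized=True, return_log_prob=True,
        )
        chain = chain.copy()
        chain[..., -1] = 10.0 ** chain[..., -1]
        posterior = _diagnose(chain, self.param_names, seed, lp)
        return GlobalFitResults(posterior, self)

    def _conditional_kt(self, r_vals, e_vals) -> np.ndarray:
        rows_r = r_vals[self._r_idx]
        rows_e = e_vals[self._e_idx]

        def ssr(p):
            pred = _predict_foldchange(
                p[0], p[1], self._c, rows_r, rows_e, self.d_eps_ai, self.n_sites
            )
            return float(np.sum((self._obs - pred) ** 2))

        best, best_val = None, np.inf
        for x0 in ([3.0, 5.0], [2.0, 4.0], [4.0, 6.0]):
            res = minimize(ssr, x0=x0, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-12})
            if res.fun < best_val:
                best, best_val = res.x, res.fun
        sigma0 = np.sqrt(best_val / max(self._obs.size - 2, 1))
        return np.array(
            [best[0], best[1], np.clip(np.log10(max(sigma0, 1e-4)), -4.5, -0.5)]
        )


class GlobalFitResults(_MCMCResults):
    @property
    def allostery(self) -> AllosterySpec:
        p = self.params
        return AllosterySpec(
            ka=10.0 ** (-p["kt_a"]),
            ki=10.0 ** (-p["kt_i"]),
            d_eps_ai=self.model.d_eps_ai,
            n_sites=self.model.n_sites,
        )


def degeneracy_scan(
    table: pd.DataFrame,
    d_eps_ai_grid: Sequence[float],
    n_sites: int = 2,
) -> pd.DataFrame:
    """Conditional best-fit (K_A, K_I) along a grid of fixed d_eps_ai.

    The strain's nominal binding energy is treated as a convoluted value
    (fitted historically under the all-active assumption) and corrected to
    the true energy for each candidate d_eps_ai, mirroring how single-strain
    data cannot distinguish the allosteric energy from the dissociation
    constants: on ideal data the residuals barely change across the grid.

    Returns a frame with columns d_eps_ai, ka, ki, rss, resid_sd.
    """
    table = _validate_table(table)
    c = table["iptg_M"].to_numpy()
    obs = table["fold_change"].to_numpy()
    repressors = table["repressors"].to_numpy()
    eps_tilde = table["d_eps_ra_kT"].to_numpy()
    rows = []
    x0 = np.array([3.0, 5.0])
    for d_eps_ai in d_eps_ai_grid:
        pa0 = 1.0 / (1.0 + np.exp(-d_eps_ai))
        eps_true = eps_tilde + np.log(pa0)

        def ssr(p, eps=eps_true, dai=d_eps_ai):
            pred = _predict_foldchange(
                p[0], p[1], c, repressors, eps, dai, n_sites
            )
            return float(np.sum((obs - pred) ** 2))

        best, best_val = None, np.inf
        for start in (x0, [2.0, 4.0], [4.0, 6.0]):
            res = minimize(ssr, x0=start, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-14,
                                    "maxiter": 2000})
            if res.fun < best_val:
                best, best_val = res.x, res.fun
        x0 = best  # warm-start the next grid point
        rows.append(
            {
                "d_eps_ai": float(d_eps_ai),
                "ka": 10.0 ** (-best[0]),
                "ki": 10.0 ** (-best[1]),
                "rss": best_val,
                "resid_sd": np.sqrt(best_val / obs.size),
            }
        )
    return pd.DataFrame(rows)


def propagate_properties(
    samples: PosteriorSamples,
    s: StrainSpec,
    d_eps_ai: float = D_EPS_AI_DEFAULT,
    n_sites: int = 2,
    level: float = 0.95,
) -> pd.DataFrame:
    """Push posterior draws of (k~_A, k~_I) through the phenotypic properties.

    Returns mode and equal-tailed bounds per property; draws on which a
    property is undefined (flat response) are excluded with a count.
    """
    names = list(samples.names)
    ja, ji = names.index("kt_a"), names.index("kt_i")
    ka = 10.0 ** (-samples.draws[:, ja])
    ki = 10.0 ** (-samples.draws[:, ji])
    values = {k: [] for k in
              ("leakiness", "saturation", "dynamic_range", "ec50", "eff_hill")}
    undefined = {k: 0 for k in values}
    for ka_d, ki_d in zip(ka, ki):
        a = AllosterySpec(ka=ka_d, ki=ki_d, d_eps_ai=d_eps_ai, n_sites=n_sites)
        values["leakiness"].append(mwc.leakiness(a, s))
        values["saturation"].append(mwc.saturation(a, s))
        values["dynamic_range"].append(mwc.dynamic_range(a, s))
        try:
            values["ec50"].append(mwc.ec50(a, s))
            values["eff_hill"].append(mwc.effective_hill(a, s))
        except FlatResponseError:
            undefined["ec50"] += 1
            undefined["eff_hill"] += 1
    rows = []
    for prop, vals in values.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            rows.append({"property": prop, "mode": np.nan, "lower": np.nan,
                         "upper": np.nan, "n_undefined": undefined[prop]})
            continue
        lo, hi = credible_interval(arr, level)
        rows.append(
            {
                "property": prop,
                "mode": marginal_mode(arr),
                "lower": lo,
                "upper": hi,
                "n_undefined": undefined[prop],
            }
        )
    return pd.DataFrame(rows).set_index("property")


class HillModel:
    """Phenomenological Hill fit of a single titration curve.

    fold-change = leakiness + dynamic_range * (c/K)^n / (1 + (c/K)^n).
    Describes one curve but carries no mechanism: the fitted K and n absorb
    copy number and binding energy and do not transfer to other strains.
    """

    param_names = ["leakiness", "dynamic_range", "log10_k", "n_hill", "sigma"]

    def __init__(self, table: pd.DataFrame, fix_n: Optional[float] = None) -> None:
        table = _validate_table(table)
        if (table["iptg_M"] > 0).sum() == 0:
            raise ValueError(
                "Hill fit requires non-zero inducer concentrations"
            )
        if len(table[["repressors", "d_eps_ra_kT"]].drop_duplicates()) != 1:
            raise ValueError("Hill fit is per-strain; got multiple strains")
        self.table = table
        self.fix_n = fix_n
        self._c = table["iptg_M"].to_numpy()
        self._obs = table["fold_change"].to_numpy()
        # the response midpoint is only identifiable near the measured
        # concentration window; restrict it to that window plus one decade
        pos_c = self._c[self._c > 0]
        self._l10k_bounds = (
            float(np.log10(pos_c.min())) - 1.0,
            float(np.log10(pos_c.max())) + 1.0,
        )
        if self._obs.max() - self._obs.min() < 0.05:
            warnings.warn(
                "nearly flat response: Hill K and n are unidentifiable"
            )

    @staticmethod
    def curve(c, leak, dr, k, n):
        c = np.asarray(c, dtype=float)
        x = (c / k) ** n
        return leak + dr * x / (1.0 + x)

    def _log_post(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        leak, dr, l10k, n_h, l10s = (theta[:, j] for j in range(5))
        ok = (
            (leak >= -0.5) & (leak <= 1.5)
            & (dr >= -1.5) & (dr <= 1.5)
            & (l10k >= self._l10k_bounds[0]) & (l10k <= self._l10k_bounds[1])
            & (n_h > 0.05) & (n_h <= 10.0)
            & (l10s >= LOG10_SIGMA_BOUNDS[0]) & (l10s <= LOG10_SIGMA_BOUNDS[1])
        )
        if self.fix_n is not None:
            ok &= np.abs(n_h - self.fix_n) < np.inf  # n overwritten below
        out = np.full(theta.shape[0], -np.inf)
        if not np.any(ok):
            return out
        n_used = np.full_like(n_h[ok], self.fix_n) if self.fix_n else n_h[ok]
        x = (self._c[None, :] / 10.0 ** l10k[ok][:, None]) ** n_used[:, None]
        pred = leak[ok][:, None] + dr[ok][:, None] * x / (1.0 + x)
        sigma = 10.0 ** l10s[ok]
        m = self._obs.size
        out[ok] = -m * np.log(sigma) - 0.5 * np.sum(
            (self._obs - pred) ** 2, axis=1
        ) / sigma**2
        return out

    def fit(self, seed: int = 0, n_walkers: int = 64, n_burn: int = 1500,
            n_steps: int = 2500) -> "HillResults":
        rng = np.random.default_rng(seed)
        leak0 = float(np.clip(self._obs.min(), 0.0, 1.0))
        dr0 = float(np.clip(self._obs.max() - self._obs.min(), 0.01, 1.0))
        pos_c = self._c[self._c > 0]
        k0 = float(np.log10(np.median(pos_c)))
        n0 = self.fix_n if self.fix_n is not None else 1.5
        center = np.array([leak0, dr0, k0, n0, -1.8])
        scale = np.array([0.02, 0.02, 0.2, 0.1 if self.fix_n is None else 1e-6,
                          0.1])
        p0 = center + scale * rng.standard_normal((n_walkers, 5))
        chain, lp = run_ensemble(self._log_post, p0, n_burn=n_burn,
                                 n_steps=n_steps, rng=rng, vectorized=True,
                                 return_log_prob=True)
        chain = chain.copy()
        chain[..., 4] = 10.0 ** chain[..., 4]
        if self.fix_n is not None:
            chain[..., 3] = self.fix_n
        posterior = _diagnose_maybe_fixed(chain, self.param_names, seed,
                                          fixed=[3] if self.fix_n else [],
                                          lp=lp)
        return HillResults(posterior, self)


def _diagnose_maybe_fixed(chain, names, seed, fixed=(), lp=None):
    """Diagnostics that skip parameters pinned to a constant."""
    free = [j for j in range(chain.shape[-1]) if j not in fixed]
    diag_free = pd.DataFrame(
        {
            "rhat": split_rhat(chain[..., free]),
            "ess": effective_sample_size(chain[..., free]),
        },
        index=[names[j] for j in free],
    )
    diag = diag_free.reindex(names)
    samples = PosteriorSamples(
        draws=chain.reshape(-1, chain.shape[-1]),
        names=list(names),
        diagnostics=diag.fillna({"rhat": 1.0, "ess": np.inf}),
        seed=seed,
        chain=chain,
        log_post=None if lp is None else lp.ravel(),
    )
    if not samples.converged():
        warnings.warn(
            f"chain convergence contract not met:\n{samples.diagnostics}",
            ConvergenceWarning,
        )
    return samples


class HillResults(_MCMCResults):
    def predict(self, c):
        p = self.map_params
        return HillModel.curve(
            c, p["leakiness"], p["dynamic_range"], 10.0 ** p["log10_k"],
            p["n_hill"],
        )


class HillThermoModel:
    """Hill-shaped active fraction inside the thermodynamic fold-change.

    p_A(c) = p_A_max - p_A_range (c/K_D)^n / (1 + (c/K_D)^n), inserted into
    fold-change = (1 + p_A(c) R e^{-d_eps_ra}/N_NS)^{-1}.  Unlike the bare
    Hill fit, the fitted ligand-binding parameters transfer to strains with
    other R and d_eps_ra.
    """

    param_names = ["pa_max", "pa_range", "log10_kd", "n_hill", "sigma"]

    def __init__(self, table: pd.DataFrame) -> None:
        table = _validate_table(table)
        if (table["iptg_M"] > 0).sum() == 0:
            raise ValueError("fit requires non-zero inducer concentrations")
        strains = table[["repressors", "d_eps_ra_kT"]].drop_duplicates()
        if len(strains) != 1:
            raise ValueError("fit is per-strain; got multiple strains")
        self.table = table
        self.strain = StrainSpec(
            repressors=float(strains["repressors"].iloc[0]),
            d_eps_ra=float(strains["d_eps_ra_kT"].iloc[0]),
        )
        self._c = table["iptg_M"].to_numpy()
        self._obs = table["fold_change"].to_numpy()
        self._rho = (
            self.strain.repressors / self.strain.n_ns
            * np.exp(-self.strain.d_eps_ra)
        )
        pos_c = self._c[self._c > 0]
        self._l10k_bounds = (
            float(np.log10(pos_c.min())) - 1.0,
            float(np.log10(pos_c.max())) + 1.0,
        )

    @staticmethod
    def active_fraction(c, pa_max, pa_range, kd, n):
        c = np.asarray(c, dtype=float)
        x = (c / kd) ** n
        return pa_max - pa_range * x / (1.0 + x)

    # the saturating active fraction pa_min = pa_max - pa_range spans decades
    # (it plays the role of a leak rate), so it is sampled as log10(pa_min);
    # pa_range is reconstructed when the chain is reported
    def _log_post(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        pa_max, l10_min, l10k, n_h, l10s = (theta[:, j] for j in range(5))
        ok = (
            (pa_max >= 0.0) & (pa_max <= 1.0)
            & (l10_min >= -6.0) & (10.0**l10_min <= pa_max)
            & (l10k >= self._l10k_bounds[0]) & (l10k <= self._l10k_bounds[1])
            & (n_h > 0.05) & (n_h <= 10.0)
            & (l10s >= LOG10_SIGMA_BOUNDS[0]) & (l10s <= LOG10_SIGMA_BOUNDS[1])
        )
        out = np.full(theta.shape[0], -np.inf)
        if not np.any(ok):
            return out
        x = (self._c[None, :] / 10.0 ** l10k[ok][:, None]) ** n_h[ok][:, None]
        pa_rng = pa_max[ok] - 10.0 ** l10_min[ok]
        pa = pa_max[ok][:, None] - pa_rng[:, None] * x / (1.0 + x)
        pred = 1.0 / (1.0 + pa * self._rho)
        sigma = 10.0 ** l10s[ok]
        m = self._obs.size
        out[ok] = -m * np.log(sigma) - 0.5 * np.sum(
            (self._obs - pred) ** 2, axis=1
        ) / sigma**2
        return out

    def _initial_point(self) -> np.ndarray:
        pos_c = self._c[self._c > 0]
        guess = np.array([0.95, -2.0, float(np.log10(np.median(pos_c))),
                          1.5, -1.8])

        def nlp(p):
            v = self._log_post(p[None, :])[0]
            return -v if np.isfinite(v) else 1e12

        best, best_val = guess, nlp(guess)
        for l10k0 in np.linspace(*self._l10k_bounds, 5)[1:-1]:
            x0 = guess.copy()
            x0[2] = l10k0
            res = minimize(nlp, x0, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10,
                                    "maxiter": 2000})
            if res.fun < best_val:
                best, best_val = res.x, res.fun
        return best

    def fit(self, seed: int = 0, n_walkers: int = 64, n_burn: int = 2000,
            n_steps: int = 3000) -> "HillThermoResults":
        rng = np.random.default_rng(seed)
        center = self._initial_point()
        scale = np.array([0.01, 0.05, 0.05, 0.05, 0.05])
        p0 = np.clip(
            center + scale * rng.standard_normal((n_walkers, 5)),
            [0.01, -5.9, self._l10k_bounds[0] + 0.1, 0.06, -4.9],
            [1.0, -0.5, self._l10k_bounds[1] - 0.1, 9.9, -0.1],
        )
        p0[:, 1] = np.minimum(p0[:, 1], np.log10(p0[:, 0]) - 1e-6)
        chain, lp = run_ensemble(self._log_post, p0, n_burn=n_burn,
                                 n_steps=n_steps, rng=rng, vectorized=True,
                                 return_log_prob=True)
        chain = chain.copy()
        chain[..., 4] = 10.0 ** chain[..., 4]
        chain[..., 1] = chain[..., 0] - 10.0 ** chain[..., 1]  # -> pa_range
        posterior = _diagnose(chain, self.param_names, seed, lp)
        return HillThermoResults(posterior, self)


class HillThermoResults(_MCMCResults):
    def predict(self, c, strain: Optional[StrainSpec] = None):
        strain = strain or self.model.strain
        p = self.map_params
        pa = HillThermoModel.active_fraction(
            c, p["pa_max"], p["pa_range"], 10.0 ** p["log10_kd"], p["n_hill"]
        )
        rho = strain.repressors / strain.n_ns * np.exp(-strain.d_eps_ra)
        out = 1.0 / (1.0 + pa * rho)
        return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# spec-surface wrappers

def fit_single_strain(table, d_eps_ai=D_EPS_AI_DEFAULT, seed=0, **kwargs):
    """Single-strain MWC fit; returns the results object (see class docs)."""
    return SingleStrainModel(table, d_eps_ai=d_eps_ai).fit(seed=seed, **kwargs)


def fit_global(table, priors, d_eps_ai=D_EPS_AI_DEFAULT, seed=0, **kwargs):
    return GlobalFitModel(table, priors, d_eps_ai=d_eps_ai).fit(seed=seed, **kwargs)


def fit_hill(table, seed=0, **kwargs):
    return HillModel(table).fit(seed=seed, **kwargs)


def fit_hill_thermo(table, seed=0, **kwargs):
    return HillThermoModel(table).fit(seed=seed, **kwargs)
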