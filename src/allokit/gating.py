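"""Unsupervised elliptical gating of cytometry-like event tables.

Events carry forward scatter (fsc), side scatter (ssc) and fluorescence (fl),
one row per event.  The densest region of (log10 fsc, log10 ssc) space is
assumed to hold the single-cell measurements: a bivariate Gaussian is fitted
by sample moments and events inside the ellipse containing probability mass
``alpha`` (Mahalanobis squared distance below the chi-squared 2-dof quantile)
are retained.  Fold-change is then the ratio of gated mean fluorescence in
the presence versus absence of repressor, after subtracting the gated mean
of an autofluorescence control from both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GateEllipse",
    "chi2_quantile_2dof",
    "fit_gate",
    "apply_gate",
    "fold_change_from_events",
]

DEFAULT_ALPHA = 0.4
MIN_GATEABLE_EVENTS = 100
EVENT_COLUMNS = ("fsc", "ssc", "fl")


def chi2_quantile_2dof(p: float) -> float:
    """Chi-squared quantile with 2 degrees of freedom: -2 ln(1 - p)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie in (0, 1); got {p}")
    return -2.0 * math.log1p(-p)


@dataclass(frozen=True)
class GateEllipse:
    """Elliptical gate in (log10 fsc, log10 ssc) space."""

    mu: np.ndarray  # 2-vector
    cov: np.ndarray  # 2x2, symmetric positive-definite
    alpha: float
    threshold: float

    def mahalanobis_sq(self, log_fsc: np.ndarray, log_ssc: np.ndarray):
        x = np.column_stack([log_fsc, log_ssc]) - self.mu
        sol = np.linalg.solve(self.cov, x.T)
        return np.einsum("ij,ji->i", x, sol)


def _validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    return events


def _gateable(events: pd.DataFrame):
    """Drop events with non-positive scatter (not log-transformable)."""
    ok = (events["fsc"] > 0) & (events["ssc"] > 0)
    n_dropped = int((~ok).sum())
    return events.loc[ok], n_dropped


def fit_gate(events: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> GateEllipse:
    """Fit the Gaussian gate by sample moments of the log10 scatter channels."""
    events = _validate_events(events)
    events, n_dropped = _gateable(events)
    if len(events) < MIN_GATEABLE_EVENTS:
        raise ValueError(
            f"need at least {MIN_GATEABLE_EVENTS} gateable events; got "
            f"{len(events)} ({n_dropped} dropped for non-positive scatter)"
        )
    log_fsc = np.log10(events["fsc"].to_numpy())
    log_ssc = np.log10(events["ssc"].to_numpy())
    for name, channel in (("fsc", log_fsc), ("ssc", log_ssc)):
        if np.ptp(channel) == 0:
            raise ValueError(
                f"channel {name} is constant: covariance is singular"
            )
    mu = np.array([log_fsc.mean(), log_ssc.mean()])
    cov = np.cov(np.vstack([log_fsc, log_ssc]))
    if np.linalg.det(cov) <= 0:
        raise ValueError("scatter covariance is singular (collinear channels)")
    return GateEllipse(
        mu=mu, cov=cov, alpha=alpha, threshold=chi2_quantile_2dof(alpha)
    )


def apply_gate(events: pd.DataFrame, gate: GateEllipse):
    """Retain events inside the ellipse; returns (gated table, retained frac).

    On truly Gaussian scatter the retained fraction converges to alpha.
    """
    events = _validate_events(events)
    events, _ = _gateable(events)
    d2 = gate.mahalanobis_sq(
        np.log10(events["fsc"].to_numpy()), np.log10(events["ssc"].to_numpy())
    )
    keep = d2 <= gate.threshold
    return events.loc[keep].reset_index(drop=True), float(keep.mean())


def _gated_mean_fl(events: pd.DataFrame, alpha: float):
    gate = fit_gate(events, alpha)
    gated, _ = apply_gate(events, gate)
    return float(gated["fl"].mean()), len(gated)


def fold_change_from_events(
    sample: pd.DataFrame,
    no_repressor: pd.DataFrame,
    autofluor: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    subtract_autofluorescence: bool = True,
):
    """Fold-change from gated mean fluorescence of three event tables.

    Each table is gated independently; the autofluorescence-strain gated mean
    is subtracted from both the sample and the no-repressor (constitutive)
    means before taking the ratio.  Set
    ``subtract_autofluorescence=False`` for the uncorrected ratio.

    Returns ``(fold_change, counts)`` where counts maps table name to the
    number of gated events used.
    """
    mean_sample, n_sample = _gated_mean_fl(sample, alpha)
    mean_norep, n_norep = _gated_mean_fl(no_repressor, alpha)
    counts = {"sample": n_sample, "no_repressor": n_norep}
    if subtract_autofluorescence:
        mean_auto, n_auto = _gated_mean_fl(autofluor, alpha)
        counts["autofluor"] = n_auto
        mean_sample -= mean_auto
        mean_norep -= mean_auto
    if mean_norep <= 0:
        raise ValueError(
            "constitutive signal is at or below background after "
            "autofluorescence subtraction; fold-change undefined"
        )
    return mean_sample / mean_norep, counts
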