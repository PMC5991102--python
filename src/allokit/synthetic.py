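"""Synthetic data with the statistical structure the analysis assumes.

Emulates the full measurement design of the study system: 6 repressor
copy-number variants (R = 22, 60, 124, 260, 1220, 1740 dimers/cell) crossed
with the three native operators (O1 = -15.3, O2 = -13.9, O3 = -9.7 k_BT) and
a 12-point IPTG titration from 0 to 5 mM, with iid Gaussian noise on
fold-change matching the inference likelihood.  Event-level cytometry tables
are drawn from a 2D log-normal scatter model with an optional uniform
contamination cloud, and multi-promoter repression curves come from the
grand-canonical model.  Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fugacity import MultiPromoterSpec, fold_change_multi
from .model import AllosterySpec, StrainSpec, fold_change

__all__ = [
    "DesignSpec",
    "EventModel",
    "default_iptg_grid",
    "simulate_induction_table",
    "simulate_event_tables",
    "simulate_multipromoter",
    "FITTED_ALLOSTERY",
]

#: The headline fitted allosteric parameters of the reference system
#: (K_A = 139 uM, K_I = 0.53 uM, d_eps_ai = 4.5 k_BT, n = 2).
FITTED_ALLOSTERY = AllosterySpec(ka=139e-6, ki=0.53e-6, d_eps_ai=4.5, n_sites=2)

REPRESSOR_LEVELS = (22.0, 60.0, 124.0, 260.0, 1220.0, 1740.0)
OPERATORS = (("O1", -15.3), ("O2", -13.9), ("O3", -9.7))
OID = ("Oid", -17.0)


def default_iptg_grid() -> np.ndarray:
    """Zero plus 11 log-spaced concentrations from 0.1 uM to 5 mM (molar)."""
    return np.concatenate([[0.0], np.logspace(-7, np.log10(5e-3), 11)])


@dataclass(frozen=True)
class DesignSpec:
    """Factorial measurement design: strains x concentrations x replicates."""

    repressor_levels: Sequence[float] = REPRESSOR_LEVELS
    operators: Sequence[tuple] = OPERATORS
    iptg_M: Sequence[float] = field(default_factory=default_iptg_grid)
    replicates: int = 1
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.iptg_M, dtype=float)
        if np.any(c < 0) or len(np.unique(c)) != len(c):
            raise ValueError("concentrations must be non-negative and unique")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def simulate_induction_table(
    design: DesignSpec, truth: AllosterySpec = FITTED_ALLOSTERY
) -> pd.DataFrame:
    """Tidy fold-change table: model prediction plus iid Gaussian noise.

    One row per (operator, repressor level, concentration, replicate), with
    the generating (noise-free) fold-change kept in ``fold_change_true``.
    Noise is not truncated to [0, 1], matching the plain-normal likelihood.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for op_name, d_eps_ra in design.operators:
        for r in design.repressor_levels:
            strain = StrainSpec(repressors=r, d_eps_ra=d_eps_ra)
            fc_true = fold_change(
                np.asarray(design.iptg_M, dtype=float), truth, strain
            )
            for rep in range(1, design.replicates + 1):
                for c, fc in zip(design.iptg_M, np.atleast_1d(fc_true)):
                    rows.append(
                        {
                            "operator": op_name,
                            "d_eps_ra_kT": d_eps_ra,
                            "repressors": r,
                            "iptg_M": float(c),
                            "fold_change_true": float(fc),
                            "replicate": rep,
                        }
                    )
    table = pd.DataFrame(rows)
    table["fold_change"] = table["fold_change_true"] + rng.normal(
        0.0, design.sigma, len(table)
    )
    return table


@dataclass(frozen=True)
class EventModel:
    """Log-normal cytometry event model (instrument-agnostic).

    Scatter is bivariate Gaussian in log10 space; fluorescence is
    background plus expression scaled by the true fold-change, with a
    per-event log-normal factor of unit mean and coefficient of variation
    ``cv``.  A fraction ``contamination`` of events is replaced by a broad
    uniform cloud emulating debris/doublets.
    """

    scatter_mu: tuple = (4.4, 4.1)
    scatter_cov: tuple = ((0.0225, 0.0135), (0.0135, 0.0225))
    autofluor_mean: float = 300.0
    expression_scale: float = 30000.0
    cv: float = 0.25
    contamination: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination < 0.5:
            raise ValueError("contamination must lie in [0, 0.5)")
        if not self.cv > 0:
            raise ValueError("cv must be positive")


def simulate_event_tables(
    model: EventModel,
    fold_change_true: float,
    n_events: int,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """One event table (fsc, ssc, fl) at a given true fold-change.

    Generate the trio needed by the gating pipeline by calling this with
    ``fold_change_true`` for the sample, 1.0 for the no-repressor control and
    0.0 for the autofluorescence control (sharing one rng keeps the tables
    independent but jointly reproducible).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    log_scatter = rng.multivariate_normal(
        np.asarray(model.scatter_mu, dtype=float),
        np.asarray(model.scatter_cov, dtype=float),
        size=n_events,
    )
    fsc = 10.0 ** log_scatter[:, 0]
    ssc = 10.0 ** log_scatter[:, 1]
    # unit-mean log-normal expression noise
    s_ln = np.sqrt(np.log1p(model.cv**2))
    expr_noise = rng.lognormal(-0.5 * s_ln**2, s_ln, size=n_events)
    fl = model.autofluor_mean + fold_change_true * model.expression_scale * expr_noise
    n_contam = int(round(model.contamination * n_events))
    if n_contam:
        idx = rng.choice(n_events, size=n_contam, replace=False)
        lo = np.asarray(model.scatter_mu) - 2.0
        hi = np.asarray(model.scatter_mu) + 2.0
        cloud = rng.uniform(lo, hi, size=(n_contam, 2))
        fsc[idx] = 10.0 ** cloud[:, 0]
        ssc[idx] = 10.0 ** cloud[:, 1]
    return pd.DataFrame({"fsc": fsc, "ssc": ssc, "fl": fl})


def simulate_multipromoter(
    d_eps_ai: float,
    n_promoters: Sequence[float],
    r_tot_grid: Sequence[float],
    d_eps_ra: float,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Repression-vs-copy-number curves from the grand-canonical model.

    One row per (N, R_tot) with fold-change from the fugacity solution plus
    optional Gaussian noise; ``d_eps_ra`` is the TRUE binding energy.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_promoters:
        for r_tot in r_tot_grid:
            m = MultiPromoterSpec(
                n_promoters=float(n),
                r_total=float(r_tot),
                d_eps_ra=d_eps_ra,
                d_eps_ai=d_eps_ai,
            )
            rows.append(
                {
                    "n_promoters": float(n),
                    "r_total": float(r_tot),
                    "fold_change_true": fold_change_multi(m),
                }
            )
    table = pd.DataFrame(rows)
    table["fold_change"] = table["fold_change_true"]
    if noise > 0:
        table["fold_change"] += rng.normal(0.0, noise, len(table))
    return table
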