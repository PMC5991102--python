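"""Closed-form thermodynamic/MWC model of the simple repression motif.

The model describes a promoter occluded by an allosteric repressor that
fluctuates between an active (DNA-binding) and an inactive conformation.
Inducer at concentration ``c`` binds the two conformations with dissociation
constants ``K_A`` and ``K_I``; the conformational equilibrium in the absence
of inducer is set by the energy difference ``d_eps_ai`` (in units of k_BT).
Gene expression is reported as fold-change: expression with repressor present
divided by constitutive expression, a number in (0, 1] for repression.

All energies are dimensionless multiples of k_BT (beta = 1 internally);
concentrations are molar.  ``repressors`` counts repressor *dimers* per cell
(twice the tetramer count for a dimer-of-dimers protein such as LacI).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AllosterySpec",
    "StrainSpec",
    "PropertySet",
    "active_probability",
    "fold_change",
    "fold_change_exact",
    "leakiness",
    "saturation",
    "dynamic_range",
    "ec50",
    "effective_hill",
    "peak_dynamic_range",
    "free_energy",
    "fold_change_from_free_energy",
]

#: Number of non-specific genomic binding sites (E. coli genome length, bp).
N_NS_DEFAULT = 4.6e6

#: Dynamic ranges below this are treated as flat responses: EC50 and the
#: effective Hill coefficient are undefined for them.
FLAT_RESPONSE_TOL = 1e-4

#: Multiplier of K_A used as the numerically "saturating" concentration.
SATURATING_FACTOR = 1e4


class FlatResponseError(ValueError):
    """Raised when EC50 / effective Hill are requested for a flat response."""


@dataclass(frozen=True)
class AllosterySpec:
    """MWC parameters of an allosteric repressor.

    Parameters
    ----------
    ka, ki : float
        Inducer dissociation constants of the active and inactive
        conformations, molar.  Induction requires ``ki < ka``.
    d_eps_ai : float
        Free-energy difference eps_I - eps_A between the inactive and active
        conformations, k_BT units.  Positive values favour the active state
        at zero inducer.
    n_sites : int
        Number of inducer binding sites per repressor (2 for a LacI dimer).
    """

    ka: float
    ki: float
    d_eps_ai: float
    n_sites: int = 2

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.ki > 0):
            raise ValueError("dissociation constants must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be a positive integer")
        if not np.isfinite(self.d_eps_ai):
            raise ValueError("d_eps_ai must be finite")


@dataclass(frozen=True)
class StrainSpec:
    """Circuit parameters of one simple-repression strain.

    ``repressors`` is the mean number of repressor dimers per cell;
    ``d_eps_ra`` the active-repressor/operator binding energy relative to the
    non-specific background (k_BT).  The optional RNAP fields enable the full
    four-state partition function (`fold_change_exact`).
    """

    repressors: float
    d_eps_ra: float
    n_ns: float = N_NS_DEFAULT
    rnap_copies: Optional[float] = None
    d_eps_p: Optional[float] = None
    d_eps_ri: Optional[float] = None

    def __post_init__(self) -> None:
        if self.repressors < 0:
            raise ValueError("repressors must be >= 0")
        if not self.n_ns > 0:
            raise ValueError("n_ns must be positive")
        if self.rnap_copies is not None and self.d_eps_p is None:
            raise ValueError("d_eps_p required when rnap_copies is given")

    def with_repressors(self, repressors: float) -> "StrainSpec":
        return replace(self, repressors=repressors)


@dataclass(frozen=True)
class PropertySet:
    """The five phenotypic properties of an induction profile."""

    leakiness: float
    saturation: float
    dynamic_range: float
    ec50: Optional[float] = None
    eff_hill: Optional[float] = None


def _check_concentration(c) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("inducer concentration must be non-negative")
    return c


def active_probability(c, a: AllosterySpec):
    """Fraction of repressors in the active conformation at concentration c.

    p_A(c) = (1+c/K_A)^n / [ (1+c/K_A)^n + e^{-d_eps_ai} (1+c/K_I)^n ].

    Strictly decreasing in ``c`` for induction (K_I < K_A).  Scalar in,
    scalar out; arrays broadcast.
    """
    c = _check_concentration(c)
    # ratio form is robust for large c: r = (1+c/K_I)/(1+c/K_A)
    r = (1.0 + c / a.ki) / (1.0 + c / a.ka)
    out = 1.0 / (1.0 + np.exp(-a.d_eps_ai) * r**a.n_sites)
    return out if out.ndim else float(out)


def _repression_strength(s: StrainSpec) -> float:
    # the single multiplicative knob R e^{-d_eps_ra} / N_NS
    return s.repressors / s.n_ns * np.exp(-s.d_eps_ra)


def fold_change(c, a: AllosterySpec, s: StrainSpec):
    """Fold-change in gene expression under the weak-promoter approximation.

    fold-change = (1 + p_A(c) R e^{-d_eps_ra} / N_NS)^{-1}.
    """
    pa = active_probability(c, a)
    out = 1.0 / (1.0 + pa * _repression_strength(s))
    return out if np.ndim(out) else float(out)


def fold_change_exact(c, a: AllosterySpec, s: StrainSpec):
    """Fold-change from the full four-state partition function.

    States: empty promoter, RNAP-bound, active-repressor-bound, and
    inactive-repressor-bound.  Requires ``rnap_copies``, ``d_eps_p`` and
    ``d_eps_ri`` on the strain.  Reduces to `fold_change` when the RNAP term
    P e^{-d_eps_p}/N_NS << 1 and inactive-repressor binding is negligible.
    """
    if s.rnap_copies is None or s.d_eps_p is None or s.d_eps_ri is None:
        raise ValueError(
            "fold_change_exact requires rnap_copies, d_eps_p and d_eps_ri"
        )
    if s.rnap_copies == 0:
        raise ZeroDivisionError(
            "fold-change is undefined without polymerase (p_bound = 0/0)"
        )
    c = _check_concentration(c)
    pa = active_probability(c, a)
    p_term = s.rnap_copies / s.n_ns * np.exp(-s.d_eps_p)
    ra_term = pa * s.repressors / s.n_ns * np.exp(-s.d_eps_ra)
    ri_term = (1.0 - pa) * s.repressors / s.n_ns * np.exp(-s.d_eps_ri)
    # p_bound(R>0) / p_bound(R=0); the P-dependent numerators cancel
    out = (1.0 + p_term) / (1.0 + ra_term + ri_term + p_term)
    return out if np.ndim(out) else float(out)


def leakiness(a: AllosterySpec, s: StrainSpec) -> float:
    """Minimum fold-change, at zero inducer."""
    return float(fold_change(0.0, a, s))


def saturation(a: AllosterySpec, s: StrainSpec) -> float:
    """Maximum fold-change, in the limit of saturating inducer."""
    pa_inf = _active_probability_saturating(a)
    return float(1.0 / (1.0 + pa_inf * _repression_strength(s)))


def _active_probability_saturating(a: AllosterySpec) -> float:
    # lim c->inf p_A(c) = 1 / (1 + e^{-d_eps_ai} (K_A/K_I)^n)
    return 1.0 / (1.0 + np.exp(-a.d_eps_ai) * (a.ka / a.ki) ** a.n_sites)


def dynamic_range(a: AllosterySpec, s: StrainSpec) -> float:
    """Saturation minus leakiness; >= 0 for induction (K_I < K_A)."""
    return saturation(a, s) - leakiness(a, s)


def ec50(a: AllosterySpec, s: StrainSpec) -> float:
    """Inducer concentration at the response midpoint, closed form.

    Solves fold_change(EC50) = (leakiness + saturation)/2 analytically.
    Raises `FlatResponseError` when the dynamic range is below the flat
    tolerance (e.g. the weak-operator, low-copy pathology where the response
    is nearly flat and the midpoint is unidentifiable).
    """
    dr = dynamic_range(a, s)
    if abs(dr) < FLAT_RESPONSE_TOL:
        raise FlatResponseError(
            f"dynamic range {dr:.3g} below {FLAT_RESPONSE_TOL:g}; "
            "EC50 is undefined for a flat response"
        )
    rho = _repression_strength(s)
    kk = (a.ka / a.ki) ** a.n_sites
    e_ai = np.exp(-a.d_eps_ai)
    one_rho = 1.0 + rho
    num = one_rho + kk * (2.0 * e_ai + one_rho)
    den = 2.0 * one_rho + e_ai + kk * e_ai
    r = (num / den) ** (1.0 / a.n_sites)
    ratio = a.ka / a.ki
    return float(a.ka * ((ratio - 1.0) / (ratio - r) - 1.0))


def _ec50_bisection(a: AllosterySpec, s: StrainSpec) -> float:
    """Numerical midpoint root; independent check of the closed form."""
    target = 0.5 * (leakiness(a, s) + saturation(a, s))
    f = lambda logc: fold_change(np.exp(logc), a, s) - target
    lo, hi = np.log(min(a.ka, a.ki) * 1e-8), np.log(max(a.ka, a.ki) * 1e8)
    return float(np.exp(brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)))


def effective_hill(a: AllosterySpec, s: StrainSpec, rel_step: float = 1e-6) -> float:
    """Effective Hill coefficient: steepness of the response at the EC50.

    Twice the slope of log[(fold-change - leakiness)/dynamic range] with
    respect to log c, evaluated at c = EC50 by central finite difference with
    relative step ``rel_step`` in ln c.  For n = 2 binding sites the value
    lies in (0, 2]; it is a steepness measure, not a binding-site count.
    """
    c0 = ec50(a, s)  # raises FlatResponseError on flat curves
    leak = leakiness(a, s)
    dr = dynamic_range(a, s)
    h = rel_step
    lo, hi = np.log(c0) - h, np.log(c0) + h
    g = lambda logc: np.log((fold_change(np.exp(logc), a, s) - leak) / dr)
    return float(2.0 * (g(hi) - g(lo)) / (2.0 * h))


def peak_dynamic_range(a: AllosterySpec, s_template: StrainSpec):
    """Repressor count maximizing the dynamic range, and the peak value.

    The dynamic range peaks at an interior repressor copy number
    R* = N_NS e^{d_eps_ra} / sqrt(p_A(0) p_A(inf)); the peak magnitude
    (sqrt(p_A(0)) - sqrt(p_A(inf)))^2 / (p_A(0) - p_A(inf)) is independent of
    the operator binding energy, which only shifts the peak location.

    Returns ``(r_star, peak_value)``.  Requires K_I < K_A (an inducible
    response); otherwise there is no interior peak and a ValueError is raised.
    """
    if a.ki >= a.ka:
        raise ValueError("no interior dynamic-range peak unless K_I < K_A")
    pa0 = float(active_probability(0.0, a))
    pa_inf = _active_probability_saturating(a)
    rho_star = 1.0 / np.sqrt(pa0 * pa_inf)
    r_star = rho_star * s_template.n_ns * np.exp(s_template.d_eps_ra)
    peak = (np.sqrt(pa0) - np.sqrt(pa_inf)) ** 2 / (pa0 - pa_inf)
    return float(r_star), float(peak)


def free_energy(c, a: AllosterySpec, s: StrainSpec):
    """Free energy (Bohr parameter) of repressor-operator binding, k_BT.

    F(c) = d_eps_ra - log p_A-term - log(R/N_NS), defined so that
    fold-change = 1/(1 + e^{-F(c)}) exactly.  The single collapsed variable
    onto which all induction profiles fall (the master curve).  Undefined at
    R = 0.
    """
    if s.repressors == 0:
        raise ValueError("free energy undefined at zero repressor copy number")
    c = _check_concentration(c)
    pa = active_probability(c, a)
    out = s.d_eps_ra - np.log(pa) - np.log(s.repressors / s.n_ns)
    return out if np.ndim(out) else float(out)


def fold_change_from_free_energy(f):
    """Fermi function: fold-change implied by a free energy F (k_BT)."""
    out = 1.0 / (1.0 + np.exp(-np.asarray(f, dtype=float)))
    return out if np.ndim(out) else float(out)


def properties(
    a: AllosterySpec, s: StrainSpec, strict: bool = False
) -> PropertySet:
    """All five phenotypic properties; EC50/Hill set to None on flat curves."""
    leak = leakiness(a, s)
    sat = saturation(a, s)
    try:
        c50 = ec50(a, s)
        hill = effective_hill(a, s)
    except FlatResponseError:
        if strict:
            raise
        c50, hill = None, None
    return PropertySet(
        leakiness=leak,
        saturation=sat,
        dynamic_range=sat - leak,
        ec50=c50,
        eff_hill=hill,
    )
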