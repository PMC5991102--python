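"""Plot-ready figures: induction profiles and the free-energy master curve."""

from __future__ import annotations

import numpy as np

from . import model
from .model import AllosterySpec, StrainSpec

__all__ = ["plot_induction", "plot_collapse"]


def plot_induction(a: AllosterySpec, strains, data=None, ax=None):
    """Predicted titration curves for a list of `StrainSpec`, plus data points.

    ``data`` is an optional tidy induction table with iptg_M / fold_change /
    repressors columns.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    c = np.concatenate([[0.0], np.logspace(-9, -2, 200)])
    for s in strains:
        ax.plot(c, model.fold_change(c, a, s), label=f"R={s.repressors:g}")
    if data is not None:
        ax.plot(data["iptg_M"], data["fold_change"], "o", ms=3, alpha=0.5,
                color="k", label="data")
    ax.set_xscale("symlog", linthresh=1e-7)
    ax.set_xlabel("IPTG (M)")
    ax.set_ylabel("fold-change")
    ax.legend(fontsize=7)
    return ax


def plot_collapse(table, a: AllosterySpec, ax=None):
    """Scatter measured fold-change against free energy, with the Fermi curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    f_vals = []
    for _, row in table.iterrows():
        s = StrainSpec(repressors=float(row["repressors"]),
                       d_eps_ra=float(row["d_eps_ra_kT"]))
        f_vals.append(model.free_energy(row["iptg_M"], a, s))
    ax.plot(f_vals, table["fold_change"], "o", ms=3, alpha=0.5)
    grid = np.linspace(min(f_vals) - 1, max(f_vals) + 1, 300)
    ax.plot(grid, model.fold_change_from_free_energy(grid), "k-", lw=1)
    ax.set_xlabel("free energy $F$ ($k_BT$)")
    ax.set_ylabel("fold-change")
    return ax
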