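"""Matplotlib views of melt data: normalized curves, difference plots and
derivative plots — the three standard ways HRM genotypes are inspected."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib.pyplot as plt

from .hrm_classify import difference_plot
from .melt_thermo import MeltCurve, derivative_curve


def plot_melt_curves(curves: Mapping[str, MeltCurve], ax=None):
    """Normalized melting curves, one line per label."""
    if ax is None:
        _, ax = plt.subplots()
    for label, c in curves.items():
        ax.plot(c.temperatures, c.helicity, label=label)
    ax.set_xlabel("Temperature (°C)")
    ax.set_ylabel("Normalized signal")
    ax.legend(fontsize="small")
    return ax


def plot_difference(curves: Mapping[str, MeltCurve], reference: str, ax=None):
    """Difference plot against one reference genotype's curve."""
    if ax is None:
        _, ax = plt.subplots()
    ref = curves[reference]
    for label, c in curves.items():
        ax.plot(c.temperatures, difference_plot(c, ref), label=label)
    ax.set_xlabel("Temperature (°C)")
    ax.set_ylabel(f"Signal difference vs {reference}")
    ax.legend(fontsize="small")
    return ax


def plot_derivative(curves: Mapping[str, MeltCurve], ax=None):
    """-dF/dT view; peaks sit at Tm."""
    if ax is None:
        _, ax = plt.subplots()
    for label, c in curves.items():
        t, d = derivative_curve(c)
        ax.plot(t, d, label=label)
    ax.set_xlabel("Temperature (°C)")
    ax.set_ylabel("-dF/dT")
    ax.legend(fontsize="small")
    return ax
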