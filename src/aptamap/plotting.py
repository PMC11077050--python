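"""Plot helpers mirroring the published figure layouts (matplotlib)."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .occupancy_profile import SiteProfile, Trace
from .sigmoid_fit import FitResult


def plot_site_profile(
    profile: SiteProfile,
    traces: Sequence[Trace] | None = None,
    fits: Mapping[int, FitResult] | None = None,
    ax=None,
):
    """Percentage-vs-cleavage-site panel with a reversed right-hand axis.

    Plots per-ligand traces (circles for the c-side estimate, triangles for
    the complementary y-side estimate) and, when given, the fitted sigmoid
    curves; the right axis shows 100 - percent, matching the convention of
    plotting complementary fragments on a reversed scale.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    mt = profile.m_total
    sites = profile.sites
    for m in range(mt + 1):
        ax.plot(sites, profile.pct_c[:, m], "o", ms=3, label=f"c({m})")
        ax.plot(sites, profile.pct_y[:, mt - m], "^", ms=3, mfc="none",
                label=f"y({mt - m})")
    if traces is not None and fits is not None:
        for trace in traces:
            fit = fits.get(trace.k)
            if fit is None:
                continue
            xx = np.linspace(trace.sites.min(), trace.sites.max(), 400)
            ax.plot(xx, fit.model(xx), "-", lw=1.2, color="red")
    ax.set_xlabel("cleavage site")
    ax.set_ylabel("fragment percentage (%)")
    ax.set_ylim(-5, 105)
    right = ax.twinx()
    right.set_ylim(105, -5)
    right.set_ylabel("complementary percentage (%)")
    ax.legend(fontsize=6, ncol=2, loc="center right")
    return ax


def plot_occupancy_bars(
    occupancies_by_stoichiometry: Mapping[int, Mapping[str, tuple[float, float]]],
    ax=None,
):
    """Grouped occupancy bars per motif and stoichiometry (100% per ligand).

    ``occupancies_by_stoichiometry`` maps m_total -> motif -> (occupancy,
    error).  A dashed line at 100% marks full occupancy of a motif by one
    ligand; bars above it show overoccupancy.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    stoichs = sorted(occupancies_by_stoichiometry)
    motifs = sorted({m for d in occupancies_by_stoichiometry.values() for m in d})
    width = 0.8 / max(len(stoichs), 1)
    xs = np.arange(len(motifs))
    for s_i, m_total in enumerate(stoichs):
        vals = [occupancies_by_stoichiometry[m_total].get(m, (np.nan, 0.0)) for m in motifs]
        ax.bar(
            xs + s_i * width,
            [v[0] for v in vals],
            width=width * 0.9,
            yerr=[v[1] for v in vals],
            capsize=2,
            label=f"1:{m_total}",
        )
    ax.axhline(100.0, ls="--", lw=0.8, color="k")
    ax.set_xticks(xs + width * (len(stoichs) - 1) / 2)
    ax.set_xticklabels([f"motif {m}" for m in motifs])
    ax.set_ylabel("occupancy (%)")
    ax.legend(fontsize=7)
    return ax


def plot_delta_bars(reports, ax=None, floor: float = 1e-3):
    """Log-scale bars of |delta shift| per residue for one equivalents range."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2.5))
    shown = [r for r in reports if not r.no_data]
    residues = [r.residue for r in shown]
    values = [max(r.abs_delta, floor) if r.abs_delta is not None else floor for r in shown]
    colors = ["tab:orange" if r.appeared else "tab:blue" for r in shown]
    ax.bar(residues, values, color=colors)
    ax.set_yscale("log")
    ax.set_ylabel(r"|$\Delta\delta$| (ppm)")
    ax.tick_params(axis="x", labelrotation=90, labelsize=6)
    return ax
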