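"""End-to-end occupancy quantification from a site profile.

Ties the modules together the way the analysis is run in practice: build
per-ligand cumulative traces, fit each with one sigmoidal transition per
configured binding region (midpoints bounded to the region site intervals,
baseline fixed at 0), convert fits to transition tables, assign transitions
to regions and sum into per-motif occupancies, and run the stoichiometric
normalization check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .motif_occupancy import (
    MotifOccupancy,
    NormalizationResult,
    RegionDef,
    assign_transitions,
    compute_occupancies,
    normalization_check,
    validate_regions,
)
from .occupancy_profile import SiteProfile, Trace, build_traces
from .sigmoid_fit import FitResult, TRUNCATION_HALF_WIDTH, fit_multisigmoid, transition_table

__all__ = ["OccupancyAnalysis", "region_informed_fit", "quantify_occupancies"]


@dataclass
class OccupancyAnalysis:
    """Full result of the occupancy pipeline for one precursor stoichiometry."""

    traces: list[Trace]
    fits: dict[int, FitResult]
    transitions: dict[int, pd.DataFrame]
    assigned: pd.DataFrame
    occupancies: list[MotifOccupancy]
    unassigned_total: float
    unassigned_error: float
    normalization: NormalizationResult

    def occupancy(self, motif: str) -> MotifOccupancy:
        for o in self.occupancies:
            if o.motif == motif:
                return o
        raise KeyError(motif)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "motif": o.motif,
                "occupancy_percent": o.occupancy,
                "error_percent": o.error,
                "overoccupied": o.overoccupied,
            }
            for o in self.occupancies
        ]
        return pd.DataFrame(rows, columns=["motif", "occupancy_percent",
                                           "error_percent", "overoccupied"])


def _plateau_levels(trace: Trace, regions: Sequence[RegionDef]) -> np.ndarray:
    """Mean trace level on the flat segments before/between/after regions.

    Region ``a..b`` rises over sites strictly inside ``(a-1, b)``; the
    boundary sites themselves are already flat, so plateau ``r`` (after
    region ``r``, before region ``r+1``) averages observed sites in
    ``[end_r, start_{r+1} - 1]`` inclusive.
    """
    x, y = trace.sites, trace.values
    bounds = [x.min() - 1] + [r.site_interval[0] for r in regions]
    ends = [r.site_interval[1] for r in regions] + [x.max() + 1]
    levels = np.empty(len(regions) + 1)
    for j in range(len(regions) + 1):
        lo = ends[j - 1] if j > 0 else x.min()
        hi = bounds[j + 1] if j < len(regions) else x.max()
        mask = (x >= lo) & (x <= hi)
        if mask.any():
            levels[j] = float(np.mean(y[mask]))
        else:
            # no flat site between two abutting regions: fall back to the
            # nearest observation to the shared boundary
            target = ends[j - 1] if j > 0 else x.min()
            levels[j] = float(y[np.argmin(np.abs(x - target))])
    return levels


def region_informed_fit(
    trace: Trace,
    regions: Sequence[RegionDef],
    shape: str = "truncated_logistic",
    w_min: float = 0.2,
) -> FitResult:
    """Fit one sigmoidal transition per binding region to a cumulative trace.

    Midpoints are initialized at (and bounded to) each region's cleavage-site
    interval, and widths are bounded so a transition's support stays
    commensurate with its region (w <= span/3); without the width bound a
    noisy fit can stretch one transition across the whole domain and steal
    amplitude from neighboring regions.  Amplitudes are initialized from the
    plateau level differences flanking the region, which pins the
    transition-to-region allocation even for adjacent regions.  The baseline
    is fixed at 0 (cumulative traces start at 0 by construction).
    """
    regions = sorted(regions, key=lambda r: r.start)
    validate_regions(regions)
    levels = _plateau_levels(trace, regions)
    init = []
    x0_bounds = []
    w_bounds = []
    for j, r in enumerate(regions):
        lo, hi = r.site_interval
        span = hi - lo
        w_hi = max(span / TRUNCATION_HALF_WIDTH, w_min * 1.5)
        amp = max(levels[j + 1] - levels[j], 1e-6)
        w0 = min(max(span / (2 * TRUNCATION_HALF_WIDTH), w_min), w_hi)
        init.append((amp, (lo + hi) / 2.0, w0))
        x0_bounds.append((lo, hi))
        w_bounds.append((w_min, w_hi))
    return fit_multisigmoid(
        trace,
        k=len(regions),
        init=init,
        shape=shape,
        baseline="zero",
        x0_bounds=x0_bounds,
        w_bounds=w_bounds,
    )


def _pruned_region_fit(
    trace: Trace,
    regions: Sequence[RegionDef],
    shape: str,
) -> tuple[FitResult, list[RegionDef]]:
    """Region-informed fit with AICc backward elimination.

    Not every trace carries a transition in every configured region (a motif
    unoccupied at a given stoichiometry contributes nothing), and keeping a
    zero-amplitude transition in the model inflates its region by the
    non-negativity floor under noise.  Starting from the full region set, the
    smallest-amplitude transition is dropped whenever that lowers the
    small-sample-corrected AICc, until no drop helps (at least one region is
    always kept).
    """
    active = sorted(regions, key=lambda r: r.start)
    fit = region_informed_fit(trace, active, shape=shape)
    while len(active) > 1:
        amps = np.array([t[0] for t in fit.model.transitions])
        ses = np.array([fit.amplitude_se(j + 1) for j in range(len(active))])
        # only transitions statistically indistinguishable from zero are
        # candidates; dropping a small but real transition hands its rise to
        # a neighboring region and biases motif allocation
        weak = np.flatnonzero(amps < ses)
        if weak.size == 0:
            break
        candidate = int(weak[np.argmin(amps[weak])])
        reduced = [r for j, r in enumerate(active) if j != candidate]
        trial = region_informed_fit(trace, reduced, shape=shape)
        if trial.aicc < fit.aicc:
            active, fit = reduced, trial
        else:
            break
    return fit, active


def quantify_occupancies(
    profile: SiteProfile,
    regions: Sequence[RegionDef],
    mode: str = "cumulative",
    shape: str = "truncated_logistic",
    prune: bool = True,
    norm_tol: float | None = None,
) -> OccupancyAnalysis:
    """Run the full trace -> fit -> motif occupancy pipeline on a profile.

    With ``prune=True`` (default) each per-ligand trace keeps only the
    regions whose transition earns its AICc; disable to force one transition
    per configured region on every trace.
    """
    traces = build_traces(profile, mode=mode)
    fits: dict[int, FitResult] = {}
    tables: dict[int, pd.DataFrame] = {}
    for trace in traces:
        if prune:
            fit, _active = _pruned_region_fit(trace, regions, shape)
        else:
            fit = region_informed_fit(trace, regions, shape=shape)
        fits[trace.k] = fit
        tables[trace.k] = transition_table(
            fit, domain=(float(trace.sites.min()), float(trace.sites.max()))
        )
    assigned = assign_transitions(tables, regions)
    occupancies, un_total, un_err = compute_occupancies(assigned, regions)
    norm = normalization_check(
        occupancies, profile.m_total, unassigned_total=un_total, tol=norm_tol
    )
    return OccupancyAnalysis(
        traces=traces,
        fits=fits,
        transitions=tables,
        assigned=assigned,
        occupancies=occupancies,
        unassigned_total=un_total,
        unassigned_error=un_err,
        normalization=norm,
    )
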