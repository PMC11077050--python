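"""Site-specific c(m)/y(m) percentage profiles and per-ligand traces.

For a precursor of stoichiometry 1:m_total, backbone cleavage at site ``i``
(between residues ``i`` and ``i+1``) yields a c_i / y_{n-i} pair whose ligand
counts sum to ``m_total`` (ligand loss is a minor channel).  Percentages of
c_i(m) are computed relative to all c fragments from that cleavage site, and
likewise for y, so each defined site/series sums to 100%.

The occupancy analysis consumes *cumulative traces*

    T_k(i) = sum_{m >= k} pct_c(i, m),

the percentage of complexes with at least ``k`` ligands on the 5' side of
site ``i``.  Each T_k runs from 0% (site before any binding region) to 100%
(site after all of them) and carries exactly one ligand's worth of sigmoidal
transitions, which is the quantity the manually stitched plotted traces
approximate.  The complementary y-based estimate of the same quantity is
``sum_{m <= m_total-k} pct_y(i, m)``; where both exist they are combined by
unweighted mean (abundance weighting is available as an option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .spectrum_io import Assignment, abundance_table

__all__ = [
    "SiteProfile",
    "Trace",
    "ComplementarityReport",
    "site_percentages",
    "complementarity_check",
    "build_traces",
    "profile_to_tidy",
]


@dataclass
class SiteProfile:
    """Per-site fragment percentages for one precursor stoichiometry.

    Arrays have shape ``(n-1, m_total+1)``; row ``i-1`` is cleavage site
    ``i``; NaN marks sites with no observed fragments (never zero-filled).
    ``pct_y`` is keyed by *site*: ``pct_y[i-1, m]`` is the percentage of
    y_{n-i}(m) among all y fragments from site ``i``.
    """

    n: int
    m_total: int
    pct_c: np.ndarray
    pct_y: np.ndarray
    abundance_c: np.ndarray | None = None
    abundance_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (self.n - 1, self.m_total + 1)
        if self.pct_c.shape != shape or self.pct_y.shape != shape:
            raise ValueError(f"percentage arrays must have shape {shape}")

    @property
    def sites(self) -> np.ndarray:
        return np.arange(1, self.n)

    def defined_sites(self, series: Literal["c", "y"]) -> np.ndarray:
        arr = self.pct_c if series == "c" else self.pct_y
        return self.sites[~np.all(np.isnan(arr), axis=1)]


@dataclass
class Trace:
    """A 0-100% per-ligand trace over cleavage sites."""

    k: int
    sites: np.ndarray
    values: np.ndarray
    source: Literal["cumulative", "stitched"] = "cumulative"

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.values):
            raise ValueError("sites and values must have equal length")


@dataclass
class ComplementarityReport:
    """Per-site, per-m discrepancy between c and complementary y percentages."""

    table: pd.DataFrame
    max_abs: float
    rms: float

    def worst_site(self) -> int:
        idx = self.table["abs_delta"].idxmax()
        return int(self.table.loc[idx, "site"])


def site_percentages(
    assignments: Iterable[Assignment],
    n: int,
    m_total: int,
) -> SiteProfile:
    """Convert assignments of one precursor stoichiometry into a SiteProfile.

    ``pct_c(i, m) = 100 * abundance(c_i(m)) / sum_m' abundance(c_i(m'))`` and
    correspondingly for y (with y_j mapped to site ``i = n - j``).  Sites with
    no fragments in a series stay NaN.
    """
    shape = (n - 1, m_total + 1)
    abund_c = np.zeros(shape)
    abund_y = np.zeros(shape)
    seen_c = np.zeros(n - 1, dtype=bool)
    seen_y = np.zeros(n - 1, dtype=bool)
    table = abundance_table(assignments)
    if table.empty:
        warnings.warn("no assignments; returning all-missing profile", stacklevel=2)
    for row in table.itertuples(index=False):
        if row.m > m_total:
            raise ValueError(
                f"fragment with m={row.m} exceeds precursor stoichiometry {m_total}"
            )
        if row.ion_type == "c":
            site = row.index
            if not 1 <= site <= n - 1:
                raise ValueError(f"c fragment index {site} outside 1..{n-1}")
            abund_c[site - 1, row.m] += row.abundance
            seen_c[site - 1] = True
        else:
            site = n - row.index
            if not 1 <= site <= n - 1:
                raise ValueError(f"y fragment index {row.index} outside 1..{n-1}")
            abund_y[site - 1, row.m] += row.abundance
            seen_y[site - 1] = True

    def _pct(abund: np.ndarray, seen: np.ndarray) -> np.ndarray:
        pct = np.full(shape, np.nan)
        totals = abund.sum(axis=1)
        ok = seen & (totals > 0)
        pct[ok] = 100.0 * abund[ok] / totals[ok, None]
        return pct

    return SiteProfile(
        n=n,
        m_total=m_total,
        pct_c=_pct(abund_c, seen_c),
        pct_y=_pct(abund_y, seen_y),
        abundance_c=abund_c,
        abundance_y=abund_y,
    )


def complementarity_check(profile: SiteProfile) -> ComplementarityReport:
    """Discrepancies ``pct_c(i, m) - pct_y(i, m_total - m)`` where both exist.

    With ligand loss a minor channel, complementary percentages agree within
    experimental error; large per-site deviations flag assignment problems.
    """
    rows = []
    mt = profile.m_total
    for i in range(profile.n - 1):
        for m in range(mt + 1):
            c = profile.pct_c[i, m]
            y = profile.pct_y[i, mt - m]
            if np.isnan(c) or np.isnan(y):
                continue
            delta = c - y
            rows.append(
                {"site": i + 1, "m": m, "delta": delta, "abs_delta": abs(delta)}
            )
    table = pd.DataFrame(rows, columns=["site", "m", "delta", "abs_delta"])
    if table.empty:
        return ComplementarityReport(table=table, max_abs=np.nan, rms=np.nan)
    return ComplementarityReport(
        table=table,
        max_abs=float(table["abs_delta"].max()),
        rms=float(np.sqrt(np.mean(table["delta"] ** 2))),
    )


def _combine(c_est: np.ndarray, y_est: np.ndarray, weights=None) -> np.ndarray:
    stacked = np.stack([c_est, y_est])
    if weights is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(stacked, axis=0)
    w = np.stack(weights)
    w = np.where(np.isnan(stacked), 0.0, w)
    total = w.sum(axis=0)
    vals = np.where(np.isnan(stacked), 0.0, stacked)
    out = np.full(c_est.shape, np.nan)
    ok = total > 0
    out[ok] = (vals * w).sum(axis=0)[ok] / total[ok]
    return out


def build_traces(
    profile: SiteProfile,
    mode: Literal["cumulative", "stitched"] = "cumulative",
    combine: Literal["mean", "abundance"] = "mean",
) -> list[Trace]:
    """Per-ligand traces T_k (k = 1..m_total) from a site profile.

    ``cumulative`` (default) computes ``T_k(i) = sum_{m>=k} pct_c(i,m)``
    averaged with the complementary y estimate ``sum_{m<=m_total-k} pct_y``.
    ``stitched`` reproduces the plotted-trace construction: the exact-count
    trace pair (c(k), y(m_total-k)) at low sites joined to the pair
    (c(k-1), y(m_total-k+1)), read on a reversed axis, at high sites; the
    crossover is the site minimizing their disagreement.
    """
    mt = profile.m_total
    if mt == 0:
        return []
    sites = profile.sites
    traces: list[Trace] = []
    for k in range(1, mt + 1):
        c_def = ~np.all(np.isnan(profile.pct_c), axis=1)
        y_def = ~np.all(np.isnan(profile.pct_y), axis=1)
        c_est = np.where(c_def, np.nansum(profile.pct_c[:, k:], axis=1), np.nan)
        y_est = np.where(y_def, np.nansum(profile.pct_y[:, : mt - k + 1], axis=1), np.nan)
        if mode == "cumulative":
            weights = None
            if combine == "abundance":
                if profile.abundance_c is None or profile.abundance_y is None:
                    raise ValueError("abundance weighting requires abundance arrays")
                weights = (
                    profile.abundance_c.sum(axis=1),
                    profile.abundance_y.sum(axis=1),
                )
            values = _combine(c_est, y_est, weights)
            source = "cumulative"
        elif mode == "stitched":
            low = _combine(
                np.where(c_def, profile.pct_c[:, k], np.nan),
                np.where(y_def, profile.pct_y[:, mt - k], np.nan),
            )
            high = 100.0 - _combine(
                np.where(c_def, profile.pct_c[:, k - 1], np.nan),
                np.where(y_def, profile.pct_y[:, mt - k + 1], np.nan),
            )
            both = ~np.isnan(low) & ~np.isnan(high)
            if not both.any():
                values = np.where(np.isnan(low), high, low)
            else:
                crossover = int(np.flatnonzero(both)[np.argmin(np.abs(low - high)[both])])
                values = np.where(np.arange(len(sites)) <= crossover, low, high)
            source = "stitched"
        else:
            raise ValueError(f"unknown mode {mode!r}")
        defined = ~np.isnan(values)
        traces.append(
            Trace(
                k=k,
                sites=sites[defined],
                values=np.clip(values[defined], 0.0, 100.0),
                source=source,
            )
        )
    return traces


def profile_to_tidy(profile: SiteProfile) -> pd.DataFrame:
    """Tidy export: one row per (site, series, m) with a percent column."""
    rows = []
    for series, arr in (("c", profile.pct_c), ("y", profile.pct_y)):
        for i in range(profile.n - 1):
            for m in range(profile.m_total + 1):
                if not np.isnan(arr[i, m]):
                    rows.append(
                        {"site": i + 1, "series": series, "m": m, "percent": arr[i, m]}
                    )
    return pd.DataFrame(rows, columns=["site", "series", "m", "percent"])
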