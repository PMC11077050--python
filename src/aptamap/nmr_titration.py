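"""Residue-specific imino-proton chemical-shift changes across a titration.

Imino protons of base-paired G/U residues resonate in the 9-15 ppm window;
signal appearance reports base-pair formation, and coexisting free/bound
resonances ("doubled" peaks) report slow exchange on the chemical-shift
timescale, i.e. high-affinity binding.  The module tabulates per-residue
absolute shift changes over configured ligand-equivalents ranges (defaults
0-1, 1-3, 3-4.5) from an assigned shift table; peak picking and assignment
are expert upstream steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

__all__ = [
    "TitrationPoint",
    "DeltaReport",
    "DEFAULT_EQUIVALENT_RANGES",
    "MINOR_CHANGE_PPM",
    "load_titration",
    "delta_shifts",
    "deltas_to_tsv",
]

#: Default equivalents ranges: lower, intermediate, higher regimes.
DEFAULT_EQUIVALENT_RANGES: tuple[tuple[float, float], ...] = (
    (0.0, 1.0),
    (1.0, 3.0),
    (3.0, 4.5),
)

#: Below this absolute shift change a range is flagged as minor-change (ppm).
MINOR_CHANGE_PPM: float = 0.1


@dataclass(frozen=True)
class TitrationPoint:
    """One assigned imino-proton resonance at one titration step."""

    residue: str
    equivalents: float
    shift: float
    peak_form: Literal["single", "doubled"] = "single"

    def __post_init__(self) -> None:
        if self.equivalents < 0:
            raise ValueError("equivalents must be >= 0")
        if self.peak_form not in ("single", "doubled"):
            raise ValueError("peak_form must be 'single' or 'doubled'")
        if not 9.0 <= self.shift <= 15.0:
            warnings.warn(
                f"{self.residue} at {self.equivalents} eq: shift {self.shift} ppm "
                "outside the 9-15 ppm imino-proton window",
                stacklevel=3,
            )


@dataclass
class DeltaReport:
    """Shift change of one residue over one equivalents range."""

    residue: str
    range: tuple[float, float]
    abs_delta: float | None
    appeared: bool
    slow_exchange: bool
    no_data: bool = False

    @property
    def minor_change(self) -> bool:
        return self.abs_delta is not None and self.abs_delta < MINOR_CHANGE_PPM


def load_titration(path) -> list[TitrationPoint]:
    """Read a titration CSV with columns residue, equivalents, shift[, peak_form].

    An empty shift cell means the signal is absent at that equivalents value
    (recorded as absence, not a point).  Duplicate (residue, equivalents,
    peak_form) rows and malformed numbers raise row-numbered errors.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"residue", "equivalents", "shift"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"titration table missing columns {sorted(missing)}")
    points: list[TitrationPoint] = []
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        line = i + 2
        residue = str(row["residue"]).strip()
        try:
            eq = float(row["equivalents"])
        except (TypeError, ValueError):
            raise ValueError(
                f"row {line}: malformed equivalents {row['equivalents']!r}"
            ) from None
        form = str(row.get("peak_form", "single") or "single").strip() or "single"
        if pd.isna(row.get("peak_form", "single")):
            form = "single"
        key = (residue, eq, form)
        if key in seen:
            raise ValueError(f"row {line}: duplicate entry for {key}")
        seen.add(key)
        shift = row["shift"]
        if pd.isna(shift):
            continue  # absent signal at this step
        try:
            shift = float(shift)
        except (TypeError, ValueError):
            raise ValueError(f"row {line}: malformed shift {row['shift']!r}") from None
        points.append(TitrationPoint(residue, eq, shift, form))  # type: ignore[arg-type]
    points.sort(key=lambda p: (p.residue, p.equivalents, p.peak_form))
    return points


def delta_shifts(
    points: Sequence[TitrationPoint],
    ranges: Sequence[tuple[float, float]] = DEFAULT_EQUIVALENT_RANGES,
) -> list[DeltaReport]:
    """Per-residue absolute shift changes for each equivalents range.

    Endpoints use nearest-point selection without interpolation: the start
    shift is the residue's point at the largest equivalents <= eq_lo, the
    end shift the point at the smallest equivalents >= eq_hi (falling back
    to the last point inside the range when the titration stops short).
    ``appeared`` marks residues with no signal at the range start but signal
    at (or before) the range end; ``slow_exchange`` marks ranges containing
    doubled (coexisting free/bound) peaks.
    """
    ordered = sorted(ranges)
    if any(b[0] < a[1] for a, b in zip(ordered, ordered[1:])):
        raise ValueError("equivalents ranges must be disjoint")
    by_res: dict[str, list[TitrationPoint]] = {}
    for p in points:
        by_res.setdefault(p.residue, []).append(p)
    reports: list[DeltaReport] = []
    for residue in sorted(by_res):
        series = sorted(by_res[residue], key=lambda p: p.equivalents)
        for eq_lo, eq_hi in ordered:
            in_range = [p for p in series if eq_lo <= p.equivalents <= eq_hi]
            starts = [p for p in series if p.equivalents <= eq_lo and p.peak_form == "single"]
            ends_after = [p for p in series if p.equivalents >= eq_hi and p.peak_form == "single"]
            singles_in = [p for p in in_range if p.peak_form == "single"]
            slow = any(p.peak_form == "doubled" for p in in_range)
            if not in_range and not starts:
                reports.append(
                    DeltaReport(residue, (eq_lo, eq_hi), None, False, slow, no_data=True)
                )
                continue
            start = starts[-1] if starts else None
            end = ends_after[0] if ends_after else (singles_in[-1] if singles_in else None)
            if start is None:
                appeared = bool(singles_in or ends_after and ends_after[0].equivalents <= eq_hi)
                reports.append(
                    DeltaReport(residue, (eq_lo, eq_hi), None, appeared, slow,
                                no_data=not appeared)
                )
                continue
            if end is None:
                reports.append(
                    DeltaReport(residue, (eq_lo, eq_hi), None, False, slow, no_data=True)
                )
                continue
            reports.append(
                DeltaReport(
                    residue,
                    (eq_lo, eq_hi),
                    abs(end.shift - start.shift),
                    False,
                    slow,
                )
            )
    return reports


def deltas_to_tsv(reports: Sequence[DeltaReport], path) -> None:
    """Export delta reports as TSV."""
    rows = [
        {
            "residue": r.residue,
            "eq_lo": r.range[0],
            "eq_hi": r.range[1],
            "abs_delta_ppm": r.abs_delta,
            "appeared": r.appeared,
            "slow_exchange": r.slow_exchange,
            "minor_change": r.minor_change,
            "no_data": r.no_data,
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
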