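"""Mapping fitted transitions to binding regions and motif occupancies.

A *binding region* is a contiguous residue stretch across which
fragment-with-ligand percentages rise sigmoidally; a *binding motif* is a
set of (typically two) sequence-distant regions close in space that jointly
accommodate one ligand molecule.  Region/motif pairing comes from structure
prediction and is therefore user configuration (JSON), not inferred here.

Site/residue convention: cleavage site ``i`` lies between residues ``i`` and
``i+1``, so a region covering residues ``a..b`` corresponds to the half-open
site interval ``(a-1, b]``; a transition is assigned to the region whose
site interval contains its fitted midpoint (midpoint containment avoids
double counting between adjacent regions).

Occupancies sum transition amplitudes per motif across all per-ligand
traces; each ligand in the precursor stoichiometry corresponds to 100%, so
motif occupancies of a 1:m complex add up to ``m * 100`` (plus any
unassigned amplitude).  Values above 100% (overoccupancy: two ligands on one
motif in a fraction of complexes) are reported, never clipped.  Errors are
propagated as root-sum-square of the amplitude standard errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sigmoid_fit import FitResult

__all__ = [
    "RegionDef",
    "MotifOccupancy",
    "NormalizationResult",
    "RNA2_REGIONS",
    "load_regions",
    "regions_to_json",
    "validate_regions",
    "assign_transitions",
    "compute_occupancies",
    "normalization_check",
    "occupancies_to_json",
]


@dataclass(frozen=True)
class RegionDef:
    """A binding region: inclusive 1-based residue span belonging to a motif."""

    id: str
    start: int
    end: int
    motif: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"region {self.id!r}: invalid span {self.start}..{self.end}")

    @property
    def site_interval(self) -> tuple[float, float]:
        """Half-open cleavage-site interval (start-1, end] carrying the rise."""
        return (self.start - 1, self.end)

    def contains_site(self, x0: float) -> bool:
        lo, hi = self.site_interval
        return lo < x0 <= hi


@dataclass
class MotifOccupancy:
    """Occupancy of one binding motif with propagated error."""

    motif: str
    occupancy: float
    error: float
    contributing: list[dict] = field(default_factory=list)

    @property
    def overoccupied(self) -> bool:
        """True when more than one ligand binds the motif in some complexes."""
        return self.occupancy > 100.0


@dataclass
class NormalizationResult:
    """Outcome of the stoichiometric normalization check."""

    passed: bool
    deviation: float
    tolerance: float
    expected_total: float
    observed_total: float


#: Binding regions of the 40-nt neomycin-sensing riboswitch aptamer (RNA 2):
#: motif A = hairpin loop + bulge (regions I and II), motif B = minor groove
#: of the lower stem (regions 0 and III), motif C = minor groove of the
#: upper stem (regions IV and V).
RNA2_REGIONS: tuple[RegionDef, ...] = (
    RegionDef("0", 6, 7, "B"),
    RegionDef("I", 8, 11, "A"),
    RegionDef("IV", 13, 16, "C"),
    RegionDef("II", 19, 23, "A"),
    RegionDef("V", 25, 29, "C"),
    RegionDef("III", 31, 37, "B"),
)


def validate_regions(regions: Sequence[RegionDef], n: int | None = None) -> None:
    """Reject overlapping site intervals or spans outside the sequence."""
    by_start = sorted(regions, key=lambda r: r.site_interval)
    for a, b in zip(by_start, by_start[1:]):
        if b.site_interval[0] < a.site_interval[1]:
            raise ValueError(
                f"regions {a.id!r} and {b.id!r} overlap "
                f"(site intervals {a.site_interval} and {b.site_interval})"
            )
    ids = [r.id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("region ids must be unique")
    if n is not None:
        for r in regions:
            if r.end > n:
                raise ValueError(f"region {r.id!r} extends past sequence length {n}")


def load_regions(path) -> list[RegionDef]:
    """Load region/motif configuration from JSON.

    Format: ``{"regions": [{"id": "I", "start": 8, "end": 11, "motif": "A"},
    ...]}`` (a bare list is also accepted).
    """
    if hasattr(path, "read"):
        data = json.load(path)
    else:
        with open(path) as fh:
            data = json.load(fh)
    items = data["regions"] if isinstance(data, dict) else data
    regions = [RegionDef(str(d["id"]), int(d["start"]), int(d["end"]), str(d["motif"])) for d in items]
    validate_regions(regions)
    return regions


def regions_to_json(regions: Sequence[RegionDef], path=None) -> dict:
    doc = {
        "regions": [
            {"id": r.id, "start": r.start, "end": r.end, "motif": r.motif}
            for r in regions
        ]
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
    return doc


def assign_transitions(
    tables: Mapping[int, pd.DataFrame],
    regions: Sequence[RegionDef],
) -> pd.DataFrame:
    """Assign fitted transitions (one table per trace k) to binding regions.

    Each transition goes to the region whose site interval contains its
    midpoint; transitions falling in no region are kept with
    ``region = None`` and their amplitude preserved, so that unassigned
    signal shows up in the normalization check rather than vanishing.
    """
    validate_regions(regions)
    rows = []
    for k in sorted(tables):
        table = tables[k]
        for row in table.itertuples(index=False):
            region_id = None
            motif = None
            for r in regions:
                if r.contains_site(row.x0):
                    region_id = r.id
                    motif = r.motif
                    break
            rows.append(
                {
                    "trace_k": k,
                    "region": region_id,
                    "motif": motif,
                    "A": row.A,
                    "se_A": row.se_A,
                    "x0": row.x0,
                    "w": row.w,
                }
            )
    return pd.DataFrame(
        rows, columns=["trace_k", "region", "motif", "A", "se_A", "x0", "w"]
    )


def compute_occupancies(
    assigned: pd.DataFrame,
    regions: Sequence[RegionDef],
) -> tuple[list[MotifOccupancy], float, float]:
    """Per-motif occupancies with root-sum-square error propagation.

    Returns ``(occupancies, unassigned_total, unassigned_error)``.  Motifs
    configured but without any assigned transition report occupancy 0.
    """
    motifs = []
    for r in regions:
        if r.motif not in motifs:
            motifs.append(r.motif)
    out = []
    for motif in motifs:
        sub = assigned[assigned["motif"] == motif]
        occ = float(sub["A"].sum())
        err = float(np.sqrt(np.sum(sub["se_A"] ** 2)))
        out.append(
            MotifOccupancy(
                motif=motif,
                occupancy=occ,
                error=err,
                contributing=sub.to_dict("records"),
            )
        )
    un = assigned[assigned["region"].isna()]
    un_total = float(un["A"].sum())
    un_err = float(np.sqrt(np.sum(un["se_A"] ** 2)))
    return out, un_total, un_err


def normalization_check(
    occupancies: Iterable[MotifOccupancy],
    m_total: int,
    unassigned_total: float = 0.0,
    tol: float | None = None,
) -> NormalizationResult:
    """Check that motif occupancies (plus unassigned amplitude) sum to m_total*100.

    The default tolerance is three times the propagated error of the total
    (floored at a small absolute value so noise-free data is not failed on
    round-off).
    """
    occupancies = list(occupancies)
    observed = sum(o.occupancy for o in occupancies) + unassigned_total
    expected = m_total * 100.0
    if tol is None:
        total_err = float(np.sqrt(np.sum([o.error**2 for o in occupancies])))
        tol = max(3.0 * total_err, 1e-6)
    deviation = abs(observed - expected)
    return NormalizationResult(
        passed=deviation <= tol,
        deviation=deviation,
        tolerance=tol,
        expected_total=expected,
        observed_total=observed,
    )


def occupancies_to_json(
    occupancies: Sequence[MotifOccupancy],
    unassigned_total: float = 0.0,
    path=None,
) -> dict:
    doc = {
        "motifs": [
            {
                "motif": o.motif,
                "occupancy_percent": o.occupancy,
                "error_percent": o.error,
                "overoccupied": o.overoccupied,
                "contributing": o.contributing,
            }
            for o in occupancies
        ],
        "unassigned_percent": unassigned_total,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
    return doc
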