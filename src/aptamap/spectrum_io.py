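"""Peak-list reading, ppm matching against fragment ladders, and abundances.

The module consumes *deconvoluted* centroid peak lists (isotope deconvolution
is an upstream step) in two dialects:

* ``neutral_mass`` — columns ``mass, intensity[, z, snr]``;
* ``mz_charge`` — columns ``mz, z, intensity[, snr]`` (negative-ion mode;
  neutral mass is recovered as ``mz*z + z*proton``).

Matching follows the acquisition-side data-reduction rules: only peaks with
S/N above a threshold (default 3) are considered, and a peak is assigned to
the ladder species with the smallest absolute ppm error if that error is
within tolerance (default 5 ppm).  Relative abundances are signal heights
divided by the number of charges, since FT-ICR detector response is
proportional to charge.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .constants import PROTON_MASS
from .rna_mass import (
    FragmentSpecies,
    Ligand,
    NEOMYCIN_B,
    RNASequence,
    neutral_from_mz,
    neutral_mass,
)

__all__ = [
    "Peak",
    "Assignment",
    "MatchResult",
    "read_peaklist",
    "read_mzml_centroids",
    "match_peaks",
    "abundance_table",
    "stoichiometry_distribution",
    "assignments_to_tsv",
]


@dataclass(frozen=True)
class Peak:
    """A deconvoluted centroid peak.

    ``neutral_mass`` is always populated; for the ``mz_charge`` dialect it is
    derived from m/z and charge at parse time.  ``charge`` may be None when
    the source provides neutral masses without charge annotation.
    """

    neutral_mass: float
    intensity: float
    charge: int | None = None
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.snr is not None and self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be >= 1 when given")


@dataclass(frozen=True)
class Assignment:
    """A peak assigned to a theoretical fragment species."""

    peak: Peak
    fragment: FragmentSpecies
    ppm_error: float
    normalized_abundance: float


@dataclass
class MatchResult:
    """Outcome of :func:`match_peaks`.

    ``assignments`` hold unambiguous matches; ``ambiguous`` are peaks with two
    candidate species within tolerance whose ppm errors differ by < 1 ppm
    (excluded from downstream profiles, conservatively); ``unassigned`` are
    surviving peaks with no species in tolerance.
    """

    assignments: list[Assignment] = field(default_factory=list)
    ambiguous: list[Peak] = field(default_factory=list)
    unassigned: list[Peak] = field(default_factory=list)
    n_snr_rejected: int = 0


def _parse_row(row_num: int, dialect: str, row: pd.Series, proton_mass: float) -> Peak:
    def _get(col, required=True):
        val = row.get(col)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            if required:
                raise ValueError(f"row {row_num}: missing required field {col!r}")
            return None
        try:
            return float(val)
        except (TypeError, ValueError):
            raise ValueError(f"row {row_num}: non-numeric value {val!r} in {col!r}") from None

    snr = _get("snr", required=False)
    intensity = _get("intensity")
    if intensity < 0:
        raise ValueError(f"row {row_num}: negative intensity {intensity}")
    if dialect == "neutral_mass":
        mass = _get("mass")
        z = _get("z", required=False)
        charge = int(z) if z is not None else None
        return Peak(neutral_mass=mass, intensity=intensity, charge=charge, snr=snr)
    elif dialect == "mz_charge":
        mz = _get("mz")
        z = int(_get("z"))
        return Peak(
            neutral_mass=neutral_from_mz(mz, z, proton_mass),
            intensity=intensity,
            charge=z,
            snr=snr,
        )
    raise ValueError(f"unknown dialect {dialect!r} (use 'neutral_mass' or 'mz_charge')")


def read_peaklist(
    path,
    dialect: Literal["neutral_mass", "mz_charge"] = "neutral_mass",
    sep: str | None = None,
    proton_mass: float = PROTON_MASS,
) -> list[Peak]:
    """Read a CSV/TSV peak list into :class:`Peak` objects.

    The separator is sniffed (comma vs tab) unless given.  Rows with missing
    or non-numeric required fields raise a row-numbered ``ValueError``.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"neutral_mass": {"mass", "intensity"}, "mz_charge": {"mz", "z", "intensity"}}
    if dialect not in required:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = required[dialect] - set(df.columns)
    if missing:
        raise ValueError(f"peak list is missing columns {sorted(missing)} for dialect {dialect!r}")
    return [
        _parse_row(i + 2, dialect, row, proton_mass)  # +2: header is line 1
        for i, (_, row) in enumerate(df.iterrows())
    ]


def read_mzml_centroids(path) -> list[Peak]:
    """Read centroided spectra from an mzML file as charge-unknown peaks.

    Minimal centroid-only reader (64-bit/32-bit float arrays, optional zlib
    compression): each (m/z, intensity) pair becomes a :class:`Peak` whose
    ``neutral_mass`` holds the raw m/z (charge unknown); intended for
    already charge-reduced/deconvoluted centroid data exported to mzML.
    """
    import base64
    import struct
    import xml.etree.ElementTree as ET
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"

    def _decode(bda) -> np.ndarray:
        accessions = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
        binary = bda.find(f"{ns}binary")
        raw = base64.b64decode(binary.text or "")
        if "MS:1000574" in accessions:  # zlib compression
            raw = zlib.decompress(raw)
        fmt = "f" if "MS:1000521" in accessions else "d"  # 32- vs 64-bit float
        width = 4 if fmt == "f" else 8
        return np.array(struct.unpack(f"<{len(raw) // width}{fmt}", raw))

    peaks: list[Peak] = []
    root = ET.parse(str(path)).getroot()
    for spectrum in root.iter(f"{ns}spectrum"):
        mzs = ints = None
        for bda in spectrum.iter(f"{ns}binaryDataArray"):
            accessions = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
            if "MS:1000514" in accessions:  # m/z array
                mzs = _decode(bda)
            elif "MS:1000515" in accessions:  # intensity array
                ints = _decode(bda)
        if mzs is None or ints is None:
            continue
        for mz, inten in zip(mzs, ints):
            peaks.append(Peak(neutral_mass=float(mz), intensity=float(inten)))
    return peaks


def _normalized_abundance(peak: Peak) -> float:
    if peak.charge is None:
        warnings.warn(
            "peak has unknown charge; using charge 1 for abundance normalization",
            stacklevel=3,
        )
        return peak.intensity
    return peak.intensity / peak.charge


def match_peaks(
    peaks: Sequence[Peak],
    ladder: Sequence[FragmentSpecies],
    ppm_tol: float = 5.0,
    snr_min: float = 3.0,
    ambiguity_ppm: float = 1.0,
) -> MatchResult:
    """Assign peaks to the nearest ladder species within a ppm tolerance.

    Peaks failing the S/N threshold are dropped (peaks without an S/N value
    are kept).  Each surviving peak is assigned to the species with the
    smallest absolute ppm error if within ``ppm_tol``; a peak with two
    candidates in tolerance whose ppm errors differ by less than
    ``ambiguity_ppm`` is flagged ambiguous and excluded.  Matching is
    per-peak and therefore deterministic and order-independent.
    """
    if len(ladder) == 0:
        raise ValueError("empty fragment ladder")
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be > 0")
    masses = np.array([f.neutral_mass for f in ladder])
    order = np.argsort(masses, kind="stable")
    sorted_masses = masses[order]

    result = MatchResult()
    for peak in peaks:
        if peak.snr is not None and not peak.snr > snr_min:
            result.n_snr_rejected += 1
            continue
        ppm = (peak.neutral_mass - sorted_masses) / sorted_masses * 1e6
        abs_ppm = np.abs(ppm)
        best = int(np.argmin(abs_ppm))
        if abs_ppm[best] > ppm_tol:
            result.unassigned.append(peak)
            continue
        in_tol = np.flatnonzero(abs_ppm <= ppm_tol)
        runner_up = [j for j in in_tol if j != best]
        if runner_up and min(abs_ppm[j] for j in runner_up) - abs_ppm[best] < ambiguity_ppm:
            result.ambiguous.append(peak)
            continue
        frag = ladder[int(order[best])]
        result.assignments.append(
            Assignment(
                peak=peak,
                fragment=frag,
                ppm_error=float(ppm[best]),
                normalized_abundance=_normalized_abundance(peak),
            )
        )
    return result


def abundance_table(assignments: Iterable[Assignment]) -> pd.DataFrame:
    """Sum charge-normalized abundances per fragment species.

    Peaks matching the same species across charge states are summed after
    charge normalization.  Returns a DataFrame with columns
    ``ion_type, index, m, abundance, n_peaks``.
    """
    rows = [
        {
            "ion_type": a.fragment.ion_type,
            "index": a.fragment.index,
            "m": a.fragment.ligand_count,
            "abundance": a.normalized_abundance,
        }
        for a in assignments
    ]
    if not rows:
        return pd.DataFrame(columns=["ion_type", "index", "m", "abundance", "n_peaks"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["ion_type", "index", "m"], as_index=False)
        .agg(abundance=("abundance", "sum"), n_peaks=("abundance", "size"))
        .sort_values(["ion_type", "index", "m"], ignore_index=True)
    )
    return out


def stoichiometry_distribution(
    peaks: Sequence[Peak],
    seq: RNASequence | str,
    ligand: Ligand = NEOMYCIN_B,
    m_range: Sequence[int] = (0, 1, 2, 3),
    ppm_tol: float = 5.0,
    snr_min: float = 3.0,
) -> dict[int, float]:
    """Fraction of each precursor stoichiometry in an undissociated spectrum.

    For each ``m`` in ``m_range`` the intact species ``RNA + m*ligand`` is
    matched against the peak list; charge-normalized abundances are summed
    across charge states and normalized to 1 over ``m_range``.
    """
    if isinstance(seq, str):
        seq = RNASequence(seq)
    base = neutral_mass(seq)
    lig = ligand.neutral_monoisotopic_mass
    # Represent precursor species through the FragmentSpecies contract so the
    # same matcher applies; index is a placeholder (full-length marker).
    species = [
        FragmentSpecies("c", len(seq), m, base + m * lig) for m in m_range
    ]
    result = match_peaks(peaks, species, ppm_tol=ppm_tol, snr_min=snr_min)
    totals = {m: 0.0 for m in m_range}
    for a in result.assignments:
        totals[a.fragment.ligand_count] += a.normalized_abundance
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("no precursor species matched in the peak list")
    return {m: totals[m] / grand for m in m_range}


def assignments_to_tsv(assignments: Iterable[Assignment], path) -> None:
    """Export assignments as TSV."""
    rows = [
        {
            "ion_type": a.fragment.ion_type,
            "index": a.fragment.index,
            "m": a.fragment.ligand_count,
            "theoretical_mass": a.fragment.neutral_mass,
            "observed_mass": a.peak.neutral_mass,
            "ppm_error": a.ppm_error,
            "intensity": a.peak.intensity,
            "charge": a.peak.charge,
            "normalized_abundance": a.normalized_abundance,
        }
        for a in assignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
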