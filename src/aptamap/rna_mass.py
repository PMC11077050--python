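"""Neutral monoisotopic masses of RNA, its CAD c/y fragments, and ligand adducts.

Collisionally activated dissociation (CAD) of RNA cleaves the phosphodiester
backbone into complementary c/y fragment pairs (McLuckey nomenclature):

* ``c_i`` — the 5' fragment covering residues ``1..i``, terminated by a
  3'-phosphate at the cleaved end;
* ``y_j`` — the 3' fragment covering residues ``n-j+1..n`` with a 5'-OH.

Cleavage site ``i`` lies between residues ``i`` and ``i+1``, so an ``n``-nt
RNA has ``n-1`` sites and ``c_i`` pairs with ``y_{n-i}``.  For an intact
neutral mass ``M`` the termini bookkeeping forces the complementarity
identity ``c_i(0) + y_{n-i}(0) = M + H2O``.

Noncovalent ligand adducts (here neomycin B) survive backbone cleavage and
partition onto either side: a fragment carrying ``m`` intact ligand molecules
weighs ``m`` ligand masses more, with no proton transfer at the
neutral-species level.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

from .constants import (
    HPO3_MASS,
    MONOISOTOPIC_MASS,
    NEOMYCIN_B_FORMULA,
    NUCLEOSIDE_FORMULA,
    PROTON_MASS,
    WATER_MASS,
    formula_mass,
)

__all__ = [
    "RNASequence",
    "Ligand",
    "FragmentSpecies",
    "NEOMYCIN_B",
    "neutral_mass",
    "fragment_ladder",
    "ion_mz",
    "neutral_from_mz",
    "ladder_to_tsv",
]

_NUCLEOSIDE_MASS = {res: formula_mass(f) for res, f in NUCLEOSIDE_FORMULA.items()}


@dataclass(frozen=True)
class RNASequence:
    """An unmodified RNA oligonucleotide with OH termini on both ends.

    Parameters
    ----------
    residues : str
        Sequence over the alphabet ``{A, C, G, U}``, 5' to 3'.
    name : str
        Free-text identifier.
    """

    residues: str
    name: str = ""
    five_prime_terminus: Literal["OH"] = "OH"
    three_prime_terminus: Literal["OH"] = "OH"

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("RNA sequence must have length >= 2")
        for pos, res in enumerate(self.residues, start=1):
            if res not in NUCLEOSIDE_FORMULA:
                raise ValueError(
                    f"unknown residue {res!r} at position {pos} "
                    f"(alphabet is A, C, G, U)"
                )
        if self.five_prime_terminus != "OH" or self.three_prime_terminus != "OH":
            raise ValueError("only OH termini are supported")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item):
        return self.residues[item]

    @classmethod
    def from_string(cls, residues: str, name: str = "") -> "RNASequence":
        """Build from an inline string; T is normalized to U with a warning."""
        seq = residues.strip().upper().replace(" ", "")
        if "T" in seq:
            warnings.warn(
                "sequence contains T; normalizing to U (RNA alphabet)",
                stacklevel=2,
            )
            seq = seq.replace("T", "U")
        return cls(residues=seq, name=name)

    @classmethod
    def from_fasta(cls, path_or_handle) -> "RNASequence":
        """Read a single-record FASTA file (DNA-style T normalized to U)."""
        if isinstance(path_or_handle, (str,)):
            records = list(SeqIO.parse(path_or_handle, "fasta"))
        else:
            records = list(SeqIO.parse(io.TextIOWrapper(path_or_handle)
                                       if isinstance(path_or_handle, io.BufferedReader)
                                       else path_or_handle, "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
        rec = records[0]
        return cls.from_string(str(rec.seq), name=rec.id)


@dataclass(frozen=True)
class Ligand:
    """A noncovalently bound small-molecule ligand.

    The neutral monoisotopic mass is derived from the elemental composition;
    a ``neutral_monoisotopic_mass`` supplied explicitly is validated against
    the composition to < 1e-4 Da.
    """

    name: str
    elemental_composition: dict[str, int]
    neutral_monoisotopic_mass: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        computed = formula_mass(self.elemental_composition)
        if self.neutral_monoisotopic_mass is None:
            object.__setattr__(self, "neutral_monoisotopic_mass", computed)
        elif abs(self.neutral_monoisotopic_mass - computed) > 1e-4:
            raise ValueError(
                f"ligand mass {self.neutral_monoisotopic_mass} inconsistent with "
                f"composition mass {computed:.6f} (|diff| > 1e-4 Da)"
            )


#: Default ligand: neomycin B free base.
NEOMYCIN_B = Ligand(name="neomycin B", elemental_composition=NEOMYCIN_B_FORMULA)


@dataclass(frozen=True)
class FragmentSpecies:
    """A c or y CAD fragment carrying ``ligand_count`` intact ligand adducts."""

    ion_type: Literal["c", "y"]
    index: int
    ligand_count: int
    neutral_mass: float
    charge: int = 0

    def __post_init__(self) -> None:
        if self.ion_type not in ("c", "y"):
            raise ValueError("ion_type must be 'c' or 'y'")
        if self.index < 1:
            raise ValueError("fragment index must be >= 1")
        if self.ligand_count < 0:
            raise ValueError("ligand_count must be >= 0")
        if self.charge < 0:
            raise ValueError("charge must be >= 0 (0 = neutral)")

    @property
    def label(self) -> str:
        return f"{self.ion_type}{self.index}({self.ligand_count})"


def neutral_mass(seq: RNASequence | str) -> float:
    """Neutral monoisotopic mass of a 5'-OH/3'-OH oligoribonucleotide.

    Additive over residues with one phosphodiester linkage (+HPO3, -H2O) per
    internal bond: ``M = sum(nucleosides) + (n-1) * (HPO3 - H2O)``.
    """
    if isinstance(seq, str):
        seq = RNASequence(seq)
    total = sum(_NUCLEOSIDE_MASS[res] for res in seq.residues)
    n_link = len(seq) - 1
    return total + n_link * (HPO3_MASS - WATER_MASS)


def _prefix_suffix_masses(seq: RNASequence) -> tuple[list[float], list[float]]:
    """Neutral masses of c_i(0) (i=1..n-1) and y_j(0) (j=1..n-1)."""
    n = len(seq)
    res_masses = [_NUCLEOSIDE_MASS[r] for r in seq.residues]
    link = HPO3_MASS - WATER_MASS
    c_masses = []
    acc = 0.0
    for i in range(n - 1):
        acc += res_masses[i] + (link if i > 0 else 0.0)
        # 5' fragment with a 3'-phosphate at the cleaved end
        c_masses.append(acc + HPO3_MASS)
    y_masses = []
    acc = 0.0
    for j in range(n - 1):
        acc += res_masses[n - 1 - j] + (link if j > 0 else 0.0)
        # 3' fragment with a plain 5'-OH
        y_masses.append(acc)
    return c_masses, y_masses


def fragment_ladder(
    seq: RNASequence | str,
    ligand: Ligand = NEOMYCIN_B,
    m_max: int = 0,
) -> list[FragmentSpecies]:
    """All c_i(m) and y_j(m) neutral fragment species of a CAD cleavage ladder.

    Parameters
    ----------
    seq : RNASequence or str
    ligand : Ligand
        Adduct whose intact neutral mass is added ``m`` times.
    m_max : int
        Highest ligand count per fragment (0..m_max), typically the precursor
        stoichiometry (up to 3 observed).

    Returns
    -------
    list of FragmentSpecies
        Exactly ``2 * (n-1) * (m_max+1)`` species.
    """
    if isinstance(seq, str):
        seq = RNASequence(seq)
    if m_max < 0:
        raise ValueError("m_max must be >= 0")
    c_masses, y_masses = _prefix_suffix_masses(seq)
    lig = ligand.neutral_monoisotopic_mass
    out: list[FragmentSpecies] = []
    for m in range(m_max + 1):
        adduct = m * lig
        for i, mass in enumerate(c_masses, start=1):
            out.append(FragmentSpecies("c", i, m, mass + adduct))
        for j, mass in enumerate(y_masses, start=1):
            out.append(FragmentSpecies("y", j, m, mass + adduct))
    return out


def ion_mz(frag: FragmentSpecies | float, z: int, proton_mass: float = PROTON_MASS) -> float:
    """m/z of a deprotonated (negative-mode) ion at charge ``z``.

    ``m/z = (neutral_mass - z * proton_mass) / z``; the proton mass constant
    follows the charged-species convention (electron mass folded in).
    """
    if z < 1:
        raise ValueError("charge z must be >= 1")
    mass = frag.neutral_mass if isinstance(frag, FragmentSpecies) else float(frag)
    return (mass - z * proton_mass) / z


def neutral_from_mz(mz: float, z: int, proton_mass: float = PROTON_MASS) -> float:
    """Inverse of :func:`ion_mz`: neutral mass from negative-mode m/z and charge."""
    if z < 1:
        raise ValueError("charge z must be >= 1")
    return mz * z + z * proton_mass


def ladder_to_tsv(
    ladder: Sequence[FragmentSpecies],
    path,
    charges: Iterable[int] = (),
) -> None:
    """Export a fragment ladder as TSV with optional m/z columns per charge."""
    charges = list(charges)
    header = ["ion_type", "index", "m", "neutral_mass"] + [f"mz_z{z}" for z in charges]
    lines = ["\t".join(header)]
    for f in ladder:
        row = [f.ion_type, str(f.index), str(f.ligand_count), f"{f.neutral_mass:.6f}"]
        row += [f"{ion_mz(f, z):.6f}" for z in charges]
        lines.append("\t".join(row))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
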