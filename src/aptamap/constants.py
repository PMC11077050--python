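"""Physical constants and shared chemical reference data.

Monoisotopic atomic masses (Da) are taken from the IUPAC/CODATA recommended
values at >= 7 decimal places.  All mass arithmetic in the package is
monoisotopic; an average-mass mode is deliberately not provided, since peak
matching operates on deconvoluted monoisotopic species.
"""

from __future__ import annotations

MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.9737615120,
}

#: Proton mass in Da (charged-species convention: the electron mass is folded
#: into the deprotonation bookkeeping, so negative-ion m/z uses m - z*PROTON).
PROTON_MASS: float = 1.0072764669


def formula_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass of an elemental composition, e.g. {"C": 9, "H": 13, ...}."""
    try:
        return sum(MONOISOTOPIC_MASS[el] * count for el, count in formula.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown element {exc.args[0]!r} in formula") from None


def add_formulas(*formulas: dict[str, int]) -> dict[str, int]:
    """Element-wise sum of compositions (counts may be negative for losses)."""
    out: dict[str, int] = {}
    for f in formulas:
        for el, n in f.items():
            out[el] = out.get(el, 0) + n
    return {el: n for el, n in out.items() if n != 0}


#: Nucleoside (free 5'-OH / 3'-OH ribonucleoside) elemental compositions.
NUCLEOSIDE_FORMULA: dict[str, dict[str, int]] = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 4},
    "C": {"C": 9, "H": 13, "N": 3, "O": 5},
    "G": {"C": 10, "H": 13, "N": 5, "O": 5},
    "U": {"C": 9, "H": 12, "N": 2, "O": 6},
}

WATER_FORMULA = {"H": 2, "O": 1}
HPO3_FORMULA = {"H": 1, "P": 1, "O": 3}

WATER_MASS: float = formula_mass(WATER_FORMULA)
HPO3_MASS: float = formula_mass(HPO3_FORMULA)

#: Neomycin B, the aminoglycoside ligand of the neomycin-sensing riboswitch.
#: The free base composition; sulfate counter-ions of the salt are not
#: observed as adducts and are ignored.
NEOMYCIN_B_FORMULA: dict[str, int] = {"C": 23, "H": 46, "N": 6, "O": 13}

#: Neomycin-sensing riboswitch aptamer constructs (all chemically synthesized
#: with 5'-OH and 3'-OH termini).  RNA2 is the aptamer with the highest
#: regulatory factor in yeast reporter assays; RNA3/RNA4 carry lower-stem
#: mutations, RNA5 an upper-stem point mutation, and RNA1 is the shorter
#: NMR construct lacking the lower stem.
APTAMER_SEQUENCES: dict[str, str] = {
    "RNA1": "GGCUGCUUGUCCUUUAAUGGUCCAGUC",
    "RNA2": "CCGGCAUAGCUUGUCCUUUAAUGGUCCUAUGUCGAAAAUG",
    "RNA3": "CCGUCAUAGCUUGUCCUUUAAUGGUCCUAUGACGAAAAUG",
    "RNA4": "CCCUGAUAGCUUGUCCUUUAAUGGUCCUAUCUGGAAAAUG",
    "RNA5": "CCGGCAUAGCUUCUCCUUUAAUGGUCCUAUGUCGAAAAUG",
}
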