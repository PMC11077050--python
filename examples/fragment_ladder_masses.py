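"""Compute the c/y CAD fragment ladder of the riboswitch aptamer.

Builds the 40-nt neomycin-sensing aptamer sequence, computes its neutral
monoisotopic mass and the full c/y fragment ladder with 0-1 neomycin B
adducts, and prints a few landmark species with negative-mode m/z values.
"""

from aptamap import (
    APTAMER_SEQUENCES,
    NEOMYCIN_B,
    RNASequence,
    fragment_ladder,
    ion_mz,
    neutral_mass,
)

seq = RNASequence(APTAMER_SEQUENCES["RNA2"], name="RNA2")
mass = neutral_mass(seq)
print(f"{seq.name}: {len(seq)} nt, neutral monoisotopic mass {mass:.4f} Da")
print(f"neomycin B adduct adds {NEOMYCIN_B.neutral_monoisotopic_mass:.4f} Da")

ladder = fragment_ladder(seq, NEOMYCIN_B, m_max=1)
print(f"ladder: {len(ladder)} species (2 series x 39 sites x 2 ligand counts)")

by_label = {f.label: f for f in ladder}
for label in ("c1(0)", "c5(1)", "y39(0)", "y20(1)"):
    frag = by_label[label]
    print(
        f"  {label:8s} neutral {frag.neutral_mass:12.4f} Da   "
        f"m/z(z=5) {ion_mz(frag, 5):10.4f}"
    )

# complementary pair bookkeeping: c1 + y39 = intact mass + H2O
pair_sum = by_label["c1(0)"].neutral_mass + by_label["y39(0)"].neutral_mass
print(f"c1(0) + y39(0) - M = {pair_sum - mass:.4f} Da (one water: 18.0106)")
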