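"""Recover binding-motif occupancies from a simulated 1:2 CAD dataset.

Simulates a site-percentage profile for the aptamer-neomycin B 1:2 complex
(motif A saturated, B at 80%, C at 20%; 5-point site noise), builds the
per-ligand cumulative traces, fits one sigmoidal transition per configured
binding region, and prints per-motif occupancies with propagated errors.
Each ligand in the precursor corresponds to 100%, so the three motifs (plus
any unassigned amplitude) should total ~200%.
"""

from aptamap import RNA2_REGIONS, quantify_occupancies, rna2_scenario, simulate_profile

scenario = rna2_scenario(m_total=2, noise_sigma=5.0, seed=1)
profile, truth = simulate_profile(scenario)
analysis = quantify_occupancies(profile, RNA2_REGIONS)

print("ground truth:", truth.motif_occupancies)
for occ in analysis.occupancies:
    flag = "  (overoccupied)" if occ.overoccupied else ""
    print(f"motif {occ.motif}: {occ.occupancy:6.1f}% +- {occ.error:4.1f}%{flag}")
print(f"unassigned amplitude: {analysis.unassigned_total:.1f}%")

norm = analysis.normalization
print(
    f"normalization: total {norm.observed_total:.1f}% vs expected "
    f"{norm.expected_total:.0f}% -> {'pass' if norm.passed else 'FAIL'} "
    f"(deviation {norm.deviation:.1f}, tolerance {norm.tolerance:.1f})"
)
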