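"""From a deconvoluted peak list to a site-percentage profile.

Renders a simulated 1:1 dataset down to a CSV peak list (with 30 decoy
peaks), reads it back, matches peaks against the theoretical c/y ladder
with the acquisition filters (S/N > 3, < 5 ppm), and rebuilds the
site-specific fragment percentages.  The decoys stay unassigned; the
complementarity check confirms that c and y fragments account for the same
ligand molecules at every cleavage site.
"""

import tempfile
from pathlib import Path

from aptamap import (
    NEOMYCIN_B,
    complementarity_check,
    fragment_ladder,
    match_peaks,
    read_peaklist,
    rna2_scenario,
    simulate_peaklist,
    simulate_profile,
    site_percentages,
)

scenario = rna2_scenario(m_total=1, noise_sigma=5.0, seed=2)
df = simulate_peaklist(scenario, decoys=30)
path = Path(tempfile.mkdtemp()) / "peaks.csv"
df.to_csv(path, index=False)
print(f"wrote {len(df)} peaks ({30} decoys) to {path}")

peaks = read_peaklist(path, dialect="neutral_mass")
ladder = fragment_ladder(scenario.seq, NEOMYCIN_B, m_max=1)
result = match_peaks(peaks, ladder, ppm_tol=5.0, snr_min=3.0)
print(
    f"assigned {len(result.assignments)}, unassigned {len(result.unassigned)}, "
    f"ambiguous {len(result.ambiguous)}"
)

profile = site_percentages(result.assignments, n=len(scenario.seq), m_total=1)
report = complementarity_check(profile)
print(
    f"complementarity: RMS {report.rms:.2f} points, worst site "
    f"{report.worst_site()} ({report.max_abs:.2f} points)"
)

# compare with the directly simulated profile (identical by construction)
direct, _ = simulate_profile(scenario)
print("profile matches direct simulation:",
      bool(abs(profile.pct_c[10, 1] - direct.pct_c[10, 1]) < 1e-9))
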