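# Methods

## Fragment chemistry and mass bookkeeping

CAD of RNA cleaves the phosphodiester backbone into c/y pairs (McLuckey
nomenclature): c_i covers residues 1..i and carries a 3′-phosphate at the
cleaved end; y_j covers the last j residues with a plain 5′-OH. For the
OH/OH-terminated oligonucleotides handled here,

    M(oligo)  = Σ nucleosides + (n−1)(HPO3 − H2O)
    c_i(0)    = M(prefix_i) + HPO3
    y_j(0)    = M(suffix_j)

which forces the complementarity identity `c_i(0) + y_{n−i}(0) = M + H2O`
exactly; with m_total intact noncovalent ligand adducts (no proton transfer
at the neutral-species level) it generalizes to
`c_i(m) + y_{n−i}(m_total−m) = M + m_total·L + H2O`. Monoisotopic atomic
masses are hard-coded at ≥7 decimals; an independent elemental oracle
(pyteomics) verifies all species to <1e-4 Da in the test suite. Negative-ion
m/z uses `(M − z·m_p)/z` with the proton mass 1.0072765 Da (electron folded
in); the constant is configurable. The c/y termini assignment is the one
consistent with the complementarity bookkeeping the analysis relies on; if
an a/w-type series were ever intended, the site-profile logic is unchanged
but masses would differ — only c/y is implemented. No internal fragments,
neutral losses (beyond the downstream ligand-loss channel), modified
residues, or isotope patterns.

## From peaks to site profiles

Input is deconvoluted centroid data (isotope deconvolution is upstream).
Peaks failing S/N > 3 are dropped; survivors are assigned to the nearest
ladder species within 5 ppm. A peak with two candidates inside tolerance
whose ppm errors differ by <1 ppm is flagged ambiguous and excluded —
the conservative choice, biasing against spurious site signal. Abundances
are signal height divided by charge (detector response is
charge-proportional); the same species observed at several charge states is
summed after normalization (switchable in principle — the alternative of a
single charge state per fragment was not needed). When the neutral-mass
dialect lacks charge annotation, charge 1 is used with a warning.

Site percentages follow the per-site normalization
`pct_c(i,m) = 100·a(c_i(m)) / Σ_m' a(c_i(m'))` (likewise y, keyed by site
`i = n − j`). Sites without fragments stay missing (never zero-filled) and
fits consume only observed sites.

## Traces and the sigmoid model

The quantity fitted per ligand rank k is the cumulative trace
`T_k(i) = Σ_{m≥k} pct_c(i,m)` — the percentage of complexes with at least k
ligands 5′ of site i. It equals `Σ_{m≤m_total−k} pct_y(i,m)` through
complementarity; where both series exist the two estimates are combined by
unweighted mean (abundance weighting is an option). T_k runs 0→100 % and is
the exact quantity that the manual procedure — following 0–100 % traces and
stitching two partial traces at an overlap site — approximates; the
stitched construction is retained as a fidelity mode, with the crossover at
the site minimizing the disagreement of the two component traces.
Noise-free, the component traces bracket T_k from below and above and meet
in the shared plateau.

Transitions are modelled as `f(x) = b0 + Σ_j A_j·s((x−x0_j)/w_j)` with
A_j ≥ 0 and, for cumulative traces, b0 fixed at 0 (they start at 0 by
construction; free baseline is used for raw exact-count traces). Two shapes
are provided behind one contract:

* **truncated logistic** (default): a logistic renormalized to reach exactly
  0 at x0−3w and 1 at x0+3w. Binding transitions have finite support —
  percentages are exactly zero before the first binding region — and the
  synthetic generator's ramps use the same family, making noise-free round
  trips exact. This exactness is what the conservation checks (totals of
  100 %/300 % to <1e-6) rest on; a pure logistic can never satisfy them on
  finite-support data.
* **logistic**: the textbook form, for unstructured fitting.

Fits use `scipy.optimize.least_squares` (TRF, analytic Jacobian,
tolerances 1e-13). With no initial guess, a deterministic multistart places
midpoints at data quantiles (all k-combinations of 7 quantiles); with a
region configuration, midpoints are initialized at and bounded to each
region's cleavage-site interval, amplitudes start from flanking plateau
differences, and widths are bounded by span/3 so a transition cannot
stretch across the domain and absorb a neighbour's rise. Non-convergence
after the multistart budget is flagged, never silent. The residual standard
deviation is the dof-corrected RMS residual; parameter covariance is
σ²(JᵀJ)⁺. Model selection, where the transition count is free, minimizes
AICc with ties broken toward fewer transitions. A transition is converted
to a residue span by the documented ±2w rule.

## Regions, motifs, and occupancy

Binding regions (contiguous residue stretches) and their grouping into
motifs come from user JSON configuration — the pairing derives from
predicted 3-D structure, which is out of scope. A region covering residues
a..b corresponds to the half-open site interval (a−1, b] (cleavage site i
lies between residues i and i+1; a rise from site s1 to s2 indicates
binding to residues s1+1..s2). Transitions are assigned by midpoint
containment (span-overlap would double-count between adjacent regions);
unassigned transitions are preserved and counted in the normalization
check. Occupancy of a motif is the sum of its regions' amplitudes over all
traces; errors propagate as root-sum-square (independent-error assumption —
the original scheme is unstated). Overoccupancy (>100 %: two ligands on one
motif in a fraction of complexes) is reported, never clipped. The
normalization check compares Σ occupancies + unassigned against
m_total × 100 % with a default tolerance of 3× the propagated error
(floored at 1e-6 so exact data is not failed on round-off).

The shipped default configuration encodes the aptamer's six regions —
0 (residues 6–7) and III (31–37) forming lower-stem motif B, I (8–11) and
II (19–23) forming hairpin-loop/bulge motif A, IV (13–16) and V (25–29)
forming upper-stem motif C.

In the full pipeline each per-ligand trace gets one transition per
configured region, followed by conservative backward elimination: a
transition is dropped only when its amplitude is statistically
indistinguishable from zero (A < SE) *and* removing it lowers AICc. Without
elimination, zero-amplitude transitions inflate their region by the
non-negativity floor under noise; aggressive elimination is worse, because
a dropped real transition hands its rise to a neighbouring region. Both
failure modes were measured on synthetic data before settling on this rule.

## The synthetic-data generator

The generator defines the study conditions for all quantitative tests.

**Configurations.** A 1:m precursor carries exactly m ligands over the
configured motifs with marginal expectations equal to the occupancies
(>100 % ⇒ a guaranteed ligand plus a fractional chance of a second). The
joint distribution is realized by Madow systematic (PPS) sampling: exact
marginals, exact total, and a closed-form distribution over at most
(#motifs+1) distinct configurations, enumerated exactly (the brute-force
oracle) or sampled Monte-Carlo; the two routes agree within 3 SE at 1e5
draws (tested). The ordering of motifs follows their 5′ region; the joint
law beyond the fixed marginals is a modelling choice, not a physical claim.

**Retention.** A ligand on motif M lands on the c-side of site i with
probability G_M(i): 0 before the motif's 5′ region, a finite-support
sigmoidal ramp across each region (width = min(ramp_width, span/6), the
truncated-logistic family above), a plateau at the split fraction f_M
between the motif's two regions, 1 after its 3′ region. Per configuration,
the c-side ligand count is a sum of independent Bernoullis, convolved
exactly. This minimal mechanism reproduces the observed sigmoidal
site-percentage shapes and mid-motif plateaus; it is a test harness, not
gas-phase physics. Defaults: ramp_width 1.0 site; split fractions
f_A = 0.6 (the ~60/40 split of the hairpin-loop motif's regions seen in 1:1
data), f_B = 14/54 (placing the post-upper-stem plateau of the 1:1 trace at
60 %), f_C = 0.5 (no constraining observation). Default occupancies per
stoichiometry are the reported values for the aptamer (1:1 — A 46 %, B
54 %; 1:2 — A 100 %, B 80 %, C 20 %; 1:3 — all 100 %), plus an
overoccupied 1:3 variant (B 125 %, A = C = 87.5 %) emulating the lower-stem
mutant.

**Noise.** Experimental fits show residual standard deviations of ~5
percentage points; the default noise_sigma is 5. Because percentages at a
site must sum to 100 exactly, i.i.d. noise per point is replaced by
zero-sum Gaussian noise per (site, series): i.i.d. draws are mean-removed
and rescaled so each point keeps SD = σ while the sum stays exact. c and y
series are independent, so complementary percentages disagree with RMS
√2·σ. Rows that leave [0, 100] are projected back onto the scaled
probability simplex (nearest valid vector). An optional ligand-loss channel
(≤2 %, the observed minor-channel bound) moves mass from m to m−1
independently in c and y, breaking complementarity by O(loss). Noise is
homoscedastic and site-independent; the true site-to-site correlation
structure of experimental noise is unknown and assumed away.

**Peak lists.** A profile can be rendered to a deconvoluted peak list:
exact ladder masses, intensity ∝ percentage × charge (charge-proportional
detector response, so normalization recovers the percentages), S/N fields
consistent with intensities, plus decoy peaks ≥25 ppm from every true
species. Round trips through matching and site-percentaging reproduce the
profile exactly at σ = 0.

## Estimator accuracy at the study conditions

On 100-replicate batches at σ = 5 the pipeline recovers mean motif
occupancies within the ±9-point uncertainty quoted for the experimental
analysis, with three known systematic effects measured on synthetic data:
the A ≥ 0 floor inflates near-zero transitions slightly at the expense of
large ones; allocation between the adjacent regions 0 and I (one flat site
between them) trades a few points; and the 0/100 percentage bounds make
plateau noise asymmetric. Net biases reach about −7 points on motif A and
+6 on motif B in the 1:2/1:3 scenarios (well within the quoted
uncertainty); the replicate scatter matches the propagated errors within a
factor of 2. Mean occupancies are non-decreasing with stoichiometry up to a
5-point fit-error allowance.

## Problem sizes and determinism

All simulations are seeded (`numpy.random.default_rng`); fits are
deterministic given data. The validation suite uses 40-nt sequences
(39 sites), 20–60 replicates for distributional unit checks, and 100
replicates for the headline recovery runs in the acceptance script —
sizes at which the enumerated-configuration oracle is exact and a full run
completes in minutes on one CPU.

## Scope limits

Instrument operation, raw-profile peak picking, isotope deconvolution,
structure prediction, K_D fitting, NOESY/HSQC assignment, and kinetic
modelling of gas-phase ligand migration are all upstream or out of scope.
The NMR module consumes an assigned chemical-shift table, not spectra;
range endpoints default to 0–1, 1–3, 3–4.5 equivalents with nearest-point
(non-interpolating) endpoint selection. Passing synthetic-recovery tests
demonstrates correctness of the bookkeeping and estimator under the stated
noise model, not that real spectra meet that model.
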