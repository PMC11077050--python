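"""Synthetic CAD datasets with known ground truth.

The generator emulates the statistical structure the occupancy analysis
assumes, so that parameter recovery can be tested end to end:

1. **Ligand configurations.**  A precursor of stoichiometry 1:m carries
   exactly ``m`` ligands distributed over the configured binding motifs with
   marginal expectations equal to the motif occupancies (values above 100%
   put two ligands on one motif in a fraction of complexes).  The joint
   distribution is realized by Madow systematic sampling: it has exact
   marginals, an exact total, and a closed-form distribution over at most
   ``#motifs + 1`` distinct configurations, which is enumerated exactly (the
   brute-force oracle) and can also be sampled.

2. **Gas-phase retention.**  For backbone cleavage at site ``i``, a ligand
   on motif ``M`` ends up on the c-side with probability ``G_M(i)``: 0
   before the motif's 5' region, a finite-support sigmoidal ramp across each
   region, a plateau at the split fraction ``f_M`` between the motif's two
   regions, and 1 after its 3' region.  This is a minimal mechanism that
   reproduces the observed sigmoidal site-percentage shapes; it is a test
   harness, not a physical claim.

3. **Noise.**  Site percentages receive zero-sum Gaussian noise per
   (site, series): i.i.d. draws are mean-centered and rescaled so every
   point keeps standard deviation ``noise_sigma`` (default 5 percentage
   points, the residual level of experimental fits) while each series still
   sums to exactly 100%.  c and y series get independent noise, so
   complementary percentages disagree with RMS ``sqrt(2) * noise_sigma``.
   An optional ligand-loss channel (<2%) moves fragment mass from m to m-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import APTAMER_SEQUENCES
from .motif_occupancy import RegionDef, RNA2_REGIONS, validate_regions
from .occupancy_profile import SiteProfile
from .rna_mass import Ligand, NEOMYCIN_B, RNASequence, fragment_ladder, ion_mz
from .sigmoid_fit import TRUNCATION_HALF_WIDTH, sigmoid_shape

__all__ = [
    "Scenario",
    "GroundTruth",
    "enumerate_configurations",
    "sample_configurations",
    "retention_curve",
    "expected_surfaces",
    "simulate_profile",
    "monte_carlo_surfaces",
    "simulate_peaklist",
    "simulate_precursor_peaklist",
    "rna2_scenario",
    "overoccupied_1to3_scenario",
    "RNA2_SPLIT_FRACTIONS",
    "RNA2_OCCUPANCIES",
]

#: Default c-side split fractions between each motif's 5' and 3' regions,
#: chosen so the simulated 1:1 aptamer profile reproduces the published
#: trace shape (the c(1)/y(0) trace reaches ~60% after the upper-stem
#: region): motif A splits ~60/40 across regions I/II, motif B ~26/74
#: across regions 0/III, motif C has no constraining observation (50/50).
RNA2_SPLIT_FRACTIONS: dict[str, float] = {"A": 0.6, "B": 14.0 / 54.0, "C": 0.5}

#: Reported motif occupancies (percent) of the RNA 2 aptamer-neomycin B
#: complexes per stoichiometry: 1:1 A/B roughly equal (46/54), 1:2 motif A
#: saturated with B ~80 and C ~20, 1:3 all three motifs fully occupied.
RNA2_OCCUPANCIES: dict[int, dict[str, float]] = {
    1: {"A": 46.0, "B": 54.0, "C": 0.0},
    2: {"A": 100.0, "B": 80.0, "C": 20.0},
    3: {"A": 100.0, "B": 100.0, "C": 100.0},
}


@dataclass(frozen=True)
class Scenario:
    """Ground-truth configuration for one synthetic CAD dataset."""

    seq: RNASequence
    m_total: int
    regions: tuple[RegionDef, ...]
    occupancies: Mapping[str, float]
    split_fraction: Mapping[str, float] = field(default_factory=dict)
    ramp_width: float = 1.0
    noise_sigma: float = 5.0
    loss_fraction: float = 0.0
    seed: int = 0
    ligand: Ligand = NEOMYCIN_B

    def __post_init__(self) -> None:
        if self.m_total < 1:
            raise ValueError("m_total must be >= 1")
        validate_regions(self.regions, n=len(self.seq))
        motifs = {r.motif for r in self.regions}
        for motif, occ in self.occupancies.items():
            if motif not in motifs:
                raise ValueError(f"occupancy given for unknown motif {motif!r}")
            if occ < 0:
                raise ValueError("occupancies must be non-negative")
        total = sum(self.occupancies.values())
        if abs(total - self.m_total * 100.0) > 1e-9:
            raise ValueError(
                f"occupancies sum to {total}, expected m_total*100 = {self.m_total * 100}"
            )
        for motif, f in self.split_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"split fraction for motif {motif!r} outside [0, 1]")
        if not 0.0 <= self.loss_fraction <= 0.02:
            raise ValueError("loss_fraction must be in [0, 0.02]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.ramp_width <= 0:
            raise ValueError("ramp_width must be > 0")

    @property
    def motif_order(self) -> list[str]:
        """Motifs in order of first region appearance (5' to 3')."""
        seen: list[str] = []
        for r in sorted(self.regions, key=lambda r: r.start):
            if r.motif not in seen:
                seen.append(r.motif)
        return seen

    def motif_regions(self, motif: str) -> list[RegionDef]:
        return sorted((r for r in self.regions if r.motif == motif), key=lambda r: r.start)


@dataclass
class GroundTruth:
    """Exact quantities behind a simulated profile."""

    configurations: list[tuple[dict[str, int], float]]
    expected_pct_c: np.ndarray
    expected_pct_y: np.ndarray
    motif_occupancies: dict[str, float]
    region_amplitudes: dict[str, float]


def enumerate_configurations(
    occupancies: Mapping[str, float],
    m_total: int,
    motif_order: Sequence[str] | None = None,
) -> list[tuple[dict[str, int], float]]:
    """Exact distribution of per-motif ligand counts under Madow sampling.

    ``occupancies`` are in percent; motif ``M`` receives a guaranteed
    ``floor(occ/100)`` ligands, and the fractional parts are realized by
    systematic (PPS) sampling, whose distribution is piecewise constant in
    the uniform offset and therefore enumerable exactly.
    """
    motifs = list(motif_order) if motif_order is not None else list(occupancies)
    q = np.array([occupancies.get(m, 0.0) / 100.0 for m in motifs])
    base = np.floor(q + 1e-12).astype(int)
    resid = q - base
    n_extra = m_total - int(base.sum())
    if abs(resid.sum() - n_extra) > 1e-9:
        raise ValueError("occupancies inconsistent with m_total")
    if n_extra == 0:
        return [({m: int(b) for m, b in zip(motifs, base)}, 1.0)]
    cum = np.concatenate([[0.0], np.cumsum(resid)])
    breakpoints = sorted({0.0, 1.0, *[c % 1.0 for c in cum[1:-1]]})
    configs: dict[tuple[int, ...], float] = {}
    for lo, hi in zip(breakpoints, breakpoints[1:]):
        if hi - lo < 1e-12:
            continue
        u = (lo + hi) / 2.0
        extra = np.floor(cum[1:] - u) - np.floor(cum[:-1] - u)
        counts = tuple((base + extra.astype(int)).tolist())
        configs[counts] = configs.get(counts, 0.0) + (hi - lo)
    return [
        ({m: c for m, c in zip(motifs, counts)}, prob)
        for counts, prob in sorted(configs.items())
    ]


def sample_configurations(
    occupancies: Mapping[str, float],
    m_total: int,
    n_draws: int,
    rng: np.random.Generator,
    motif_order: Sequence[str] | None = None,
) -> list[tuple[dict[str, int], int]]:
    """Monte-Carlo draws from the same configuration distribution."""
    configs = enumerate_configurations(occupancies, m_total, motif_order)
    probs = np.array([p for _, p in configs])
    probs = probs / probs.sum()
    idx = rng.choice(len(configs), size=n_draws, p=probs)
    counts = np.bincount(idx, minlength=len(configs))
    return [(configs[i][0], int(counts[i])) for i in range(len(configs))]


def _region_ramp(region: RegionDef, ramp_width: float, sites: np.ndarray) -> np.ndarray:
    lo, hi = region.site_interval
    x0 = (lo + hi) / 2.0
    half = min(TRUNCATION_HALF_WIDTH * ramp_width, (hi - lo) / 2.0)
    w = half / TRUNCATION_HALF_WIDTH
    return sigmoid_shape((sites - x0) / w, "truncated_logistic")


def retention_curve(
    scenario: Scenario, motif: str, sites: np.ndarray | None = None
) -> np.ndarray:
    """Probability G_M(i) that a ligand on ``motif`` sits on the c-side of site i."""
    if sites is None:
        sites = np.arange(1, len(scenario.seq), dtype=float)
    regions = scenario.motif_regions(motif)
    if len(regions) == 1:
        return _region_ramp(regions[0], scenario.ramp_width, sites)
    if len(regions) == 2:
        f = scenario.split_fraction.get(motif, 0.5)
        return f * _region_ramp(regions[0], scenario.ramp_width, sites) + (
            1.0 - f
        ) * _region_ramp(regions[1], scenario.ramp_width, sites)
    raise ValueError(f"motif {motif!r} has {len(regions)} regions; 1 or 2 supported")


def _apply_loss(pct: np.ndarray, loss: float) -> np.ndarray:
    """Move a fraction ``loss`` of each m>=1 percentage down to m-1."""
    if loss <= 0:
        return pct
    out = pct * (1.0 - loss)
    out[:, 0] = pct[:, 0]
    out[:, :-1] += loss * pct[:, 1:]
    return out


def expected_surfaces(scenario: Scenario) -> tuple[np.ndarray, np.ndarray, list]:
    """Exact noiseless pct_c / pct_y surfaces by configuration enumeration.

    For each enumerated configuration the c-side ligand count at a site is a
    sum of independent Bernoulli draws (one per ligand), whose distribution
    is computed by exact convolution; surfaces are the probability-weighted
    mixture, times 100.
    """
    n_sites = len(scenario.seq) - 1
    mt = scenario.m_total
    sites = np.arange(1, n_sites + 1, dtype=float)
    curves = {m: retention_curve(scenario, m, sites) for m in scenario.motif_order}
    configs = enumerate_configurations(
        scenario.occupancies, mt, motif_order=scenario.motif_order
    )
    pct_c = np.zeros((n_sites, mt + 1))
    for counts, prob in configs:
        pmf = np.zeros((n_sites, mt + 1))
        pmf[:, 0] = 1.0
        placed = 0
        for motif, cnt in counts.items():
            g = curves[motif]
            for _ in range(cnt):
                new = np.zeros_like(pmf)
                new[:, : placed + 1] = pmf[:, : placed + 1] * (1.0 - g[:, None])
                new[:, 1 : placed + 2] += pmf[:, : placed + 1] * g[:, None]
                pmf = new
                placed += 1
        pct_c += prob * pmf
    pct_c *= 100.0
    pct_y = pct_c[:, ::-1].copy()  # y-side count is m_total - c-side count
    pct_c = _apply_loss(pct_c, scenario.loss_fraction)
    pct_y = _apply_loss(pct_y, scenario.loss_fraction)
    return pct_c, pct_y, configs


def _zero_sum_noise(rng: np.random.Generator, rows: int, cols: int, sigma: float) -> np.ndarray:
    """Zero-row-sum Gaussian noise with per-point standard deviation sigma."""
    if sigma <= 0 or cols < 2:
        return np.zeros((rows, cols))
    eps = rng.normal(0.0, sigma, size=(rows, cols))
    eps -= eps.mean(axis=1, keepdims=True)
    return eps * math.sqrt(cols / (cols - 1))


def _project_rows_to_simplex(rows: np.ndarray, total: float = 100.0) -> np.ndarray:
    """Euclidean projection of each row onto {p >= 0, sum(p) = total}."""
    k = rows.shape[1]
    srt = np.sort(rows, axis=1)[:, ::-1]
    css = np.cumsum(srt, axis=1) - total
    idx = np.arange(1, k + 1)
    cond = srt - css / idx > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(len(rows)), rho] / (rho + 1)
    return np.maximum(rows - theta[:, None], 0.0)


def _noisy_percentages(
    true_pct: np.ndarray, rng: np.random.Generator, sigma: float
) -> np.ndarray:
    noisy = true_pct + _zero_sum_noise(rng, *true_pct.shape, sigma)
    if np.all(noisy >= 0.0):
        return noisy
    # nearest valid percentage vector: project onto the probability simplex
    # (scaled to 100) so sums stay exact and no value goes negative
    return _project_rows_to_simplex(noisy)


def ground_truth_region_amplitudes(scenario: Scenario) -> dict[str, float]:
    """Total trace amplitude (summed over T_1..T_m) attributable to each region."""
    out: dict[str, float] = {}
    for motif in scenario.motif_order:
        q = scenario.occupancies.get(motif, 0.0)
        regions = scenario.motif_regions(motif)
        if len(regions) == 1:
            out[regions[0].id] = q
        else:
            f = scenario.split_fraction.get(motif, 0.5)
            out[regions[0].id] = q * f
            out[regions[1].id] = q * (1.0 - f)
    return out


def simulate_profile(
    scenario: Scenario, seed: int | None = None
) -> tuple[SiteProfile, GroundTruth]:
    """Simulate one observed SiteProfile plus its exact ground truth.

    Deterministic for a fixed seed (defaults to ``scenario.seed``).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    pct_c, pct_y, configs = expected_surfaces(scenario)
    truth = GroundTruth(
        configurations=configs,
        expected_pct_c=pct_c.copy(),
        expected_pct_y=pct_y.copy(),
        motif_occupancies=dict(scenario.occupancies),
        region_amplitudes=ground_truth_region_amplitudes(scenario),
    )
    obs_c = _noisy_percentages(pct_c, rng, scenario.noise_sigma)
    obs_y = _noisy_percentages(pct_y, rng, scenario.noise_sigma)
    profile = SiteProfile(
        n=len(scenario.seq), m_total=scenario.m_total, pct_c=obs_c, pct_y=obs_y
    )
    return profile, truth


def monte_carlo_surfaces(
    scenario: Scenario, n_draws: int = 100_000, seed: int | None = None
) -> np.ndarray:
    """Monte-Carlo estimate of the expected pct_c surface (sampling oracle).

    Draws configurations and per-ligand Bernoulli c-side placements instead
    of enumerating/convolving; agrees with :func:`expected_surfaces` within
    sampling error and serves as its independent cross-check.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n_sites = len(scenario.seq) - 1
    mt = scenario.m_total
    sites = np.arange(1, n_sites + 1, dtype=float)
    curves = {m: retention_curve(scenario, m, sites) for m in scenario.motif_order}
    counts_hist = np.zeros((n_sites, mt + 1))
    for config, n_cfg in sample_configurations(
        scenario.occupancies, mt, n_draws, rng, scenario.motif_order
    ):
        if n_cfg == 0:
            continue
        c_side = np.zeros((n_cfg, n_sites), dtype=int)
        for motif, cnt in config.items():
            if cnt:
                c_side += rng.binomial(cnt, curves[motif][None, :], size=(n_cfg, n_sites))
        for m in range(mt + 1):
            counts_hist[:, m] += (c_side == m).sum(axis=0)
    return 100.0 * counts_hist / n_draws


def simulate_peaklist(
    scenario: Scenario,
    intensity_scale: float = 1.0e5,
    decoys: int = 0,
    charges: Sequence[int] = (4, 5, 6),
    dialect: str = "neutral_mass",
    seed: int | None = None,
    decoy_min_ppm: float = 25.0,
    noise_floor_fraction: float = 1.0e-3,
) -> pd.DataFrame:
    """Render a simulated profile down to a deconvoluted peak list.

    Each fragment species with nonzero site percentage becomes one peak at
    its exact theoretical mass, at a randomly chosen charge state, with
    intensity proportional to (percentage x charge x intensity_scale); the
    charge factor mimics charge-proportional detector response so that
    charge-normalized abundances recover the percentages.  ``decoys`` random
    peaks at least ``decoy_min_ppm`` away from every ladder species are
    appended.  Round-trips through peak matching and site percentaging
    reproduce the simulated profile (exactly at noise_sigma = 0).
    """
    if decoys < 0:
        raise ValueError("decoys must be >= 0")
    rng = np.random.default_rng(
        (scenario.seed if seed is None else seed) + 977
    )
    profile, _truth = simulate_profile(scenario, seed=seed)
    ladder = fragment_ladder(scenario.seq, scenario.ligand, scenario.m_total)
    by_key = {(f.ion_type, f.index, f.ligand_count): f for f in ladder}
    n = len(scenario.seq)
    noise_floor = noise_floor_fraction * intensity_scale

    rows = []
    for series, arr in (("c", profile.pct_c), ("y", profile.pct_y)):
        for site in range(1, n):
            for m in range(scenario.m_total + 1):
                pct = arr[site - 1, m]
                if not pct > 1e-12:
                    continue
                index = site if series == "c" else n - site
                frag = by_key[(series, index, m)]
                z = int(rng.choice(charges))
                intensity = pct / 100.0 * intensity_scale * z
                rows.append(
                    {
                        "mass": frag.neutral_mass,
                        "mz": ion_mz(frag, z),
                        "z": z,
                        "intensity": intensity,
                        "snr": intensity / z / noise_floor,
                    }
                )

    masses = np.array([f.neutral_mass for f in ladder])
    lo, hi = masses.min() * 0.95, masses.max() * 1.02
    made = 0
    while made < decoys:
        mass = rng.uniform(lo, hi)
        if np.min(np.abs(mass - masses) / masses) * 1e6 < decoy_min_ppm:
            continue
        z = int(rng.choice(charges))
        intensity = rng.uniform(0.02, 0.2) * intensity_scale
        rows.append(
            {
                "mass": mass,
                "mz": ion_mz(mass, z),
                "z": z,
                "intensity": intensity,
                "snr": intensity / z / noise_floor,
            }
        )
        made += 1

    df = pd.DataFrame(rows, columns=["mass", "mz", "z", "intensity", "snr"])
    if dialect == "neutral_mass":
        return df[["mass", "z", "intensity", "snr"]]
    if dialect == "mz_charge":
        return df[["mz", "z", "intensity", "snr"]]
    raise ValueError(f"unknown dialect {dialect!r}")


def simulate_precursor_peaklist(
    seq: RNASequence | str,
    weights: Mapping[int, float],
    ligand: Ligand = NEOMYCIN_B,
    charges: Sequence[int] = (12, 13),
    intensity_scale: float = 1.0e5,
    seed: int = 0,
) -> pd.DataFrame:
    """Peak list of intact precursor stoichiometries with given weight fractions."""
    from .rna_mass import neutral_mass as _nm

    if isinstance(seq, str):
        seq = RNASequence(seq)
    rng = np.random.default_rng(seed)
    base = _nm(seq)
    rows = []
    for m, w in weights.items():
        if w <= 0:
            continue
        z = int(rng.choice(charges))
        mass = base + m * ligand.neutral_monoisotopic_mass
        intensity = w * intensity_scale * z
        rows.append(
            {"mass": mass, "mz": ion_mz(mass, z), "z": z,
             "intensity": intensity, "snr": 100.0}
        )
    return pd.DataFrame(rows, columns=["mass", "mz", "z", "intensity", "snr"])


def rna2_scenario(
    m_total: int,
    noise_sigma: float = 5.0,
    seed: int = 0,
    loss_fraction: float = 0.0,
    occupancies: Mapping[str, float] | None = None,
) -> Scenario:
    """The neomycin-sensing riboswitch aptamer study conditions.

    Regions and motifs follow the aptamer's configured binding map
    (:data:`aptamap.motif_occupancy.RNA2_REGIONS`); default occupancies are
    the reported per-stoichiometry values (:data:`RNA2_OCCUPANCIES`).
    """
    if occupancies is None:
        try:
            occupancies = RNA2_OCCUPANCIES[m_total]
        except KeyError:
            raise ValueError(f"no default occupancies for m_total={m_total}") from None
    return Scenario(
        seq=RNASequence(APTAMER_SEQUENCES["RNA2"], name="RNA2"),
        m_total=m_total,
        regions=RNA2_REGIONS,
        occupancies=dict(occupancies),
        split_fraction=dict(RNA2_SPLIT_FRACTIONS),
        noise_sigma=noise_sigma,
        loss_fraction=loss_fraction,
        seed=seed,
    )


def overoccupied_1to3_scenario(noise_sigma: float = 5.0, seed: int = 0) -> Scenario:
    """A 1:3 scenario with the lower-stem motif B overoccupied at 125%.

    Emulates the lower-stem mutant construct whose motif B binds two ligands
    in ~25% of the 1:3 complexes; motifs A and C share the remainder of the
    300% total equally (87.5% each).
    """
    return Scenario(
        seq=RNASequence(APTAMER_SEQUENCES["RNA3"], name="RNA3"),
        m_total=3,
        regions=RNA2_REGIONS,
        occupancies={"A": 87.5, "B": 125.0, "C": 87.5},
        split_fraction=dict(RNA2_SPLIT_FRACTIONS),
        noise_sigma=noise_sigma,
        seed=seed,
    )
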