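"""Ground-truth generator: configurations, surfaces, noise, and peak lists."""

import numpy as np
import pytest

from aptamap.motif_occupancy import RegionDef
from aptamap.occupancy_profile import build_traces, site_percentages
from aptamap.rna_mass import RNASequence, fragment_ladder
from aptamap.spectrum_io import match_peaks, read_peaklist
from aptamap.synthetic_data import (
    Scenario,
    enumerate_configurations,
    expected_surfaces,
    monte_carlo_surfaces,
    overoccupied_1to3_scenario,
    retention_curve,
    rna2_scenario,
    simulate_peaklist,
    simulate_profile,
)


class TestEnumerateConfigurations:
    def test_probabilities_sum_to_one_and_counts_to_m_total(self):
        configs = enumerate_configurations({"A": 100.0, "B": 80.0, "C": 20.0}, 2)
        assert sum(p for _, p in configs) == pytest.approx(1.0)
        for counts, _ in configs:
            assert sum(counts.values()) == 2

    @pytest.mark.parametrize(
        "occ,m_total",
        [
            ({"A": 46.0, "B": 54.0}, 1),
            ({"A": 100.0, "B": 80.0, "C": 20.0}, 2),
            ({"A": 87.5, "B": 125.0, "C": 87.5}, 3),
            ({"A": 100.0, "B": 100.0, "C": 100.0}, 3),
        ],
    )
    def test_marginals_match_occupancies_exactly(self, occ, m_total):
        configs = enumerate_configurations(occ, m_total)
        for motif, target in occ.items():
            marginal = sum(c.get(motif, 0) * p for c, p in configs)
            assert marginal == pytest.approx(target / 100.0, abs=1e-12)

    def test_overoccupancy_yields_double_counts(self):
        configs = enumerate_configurations({"A": 87.5, "B": 125.0, "C": 87.5}, 3)
        assert any(c["B"] == 2 for c, _ in configs)

    def test_inconsistent_total_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            enumerate_configurations({"A": 50.0}, 1)


class TestScenario:
    def test_occupancy_sum_validated(self, rna2):
        with pytest.raises(ValueError, match="occupancies sum"):
            Scenario(
                seq=rna2, m_total=1,
                regions=(RegionDef("I", 8, 11, "A"),),
                occupancies={"A": 90.0},
            )

    def test_loss_fraction_bounds(self):
        with pytest.raises(ValueError, match="loss_fraction"):
            rna2_scenario(1, loss_fraction=0.05)


class TestRetentionAndSurfaces:
    def test_retention_curve_two_step(self, rna2):
        """Single motif at 100%: G rises to f across region 1, then to 1."""
        sc = Scenario(
            seq=rna2, m_total=1,
            regions=(RegionDef("I", 8, 11, "A"), RegionDef("II", 19, 23, "A")),
            occupancies={"A": 100.0},
            split_fraction={"A": 0.6},
            noise_sigma=0.0,
        )
        sites = np.arange(1.0, 40.0)
        g = retention_curve(sc, "A", sites)
        assert np.all(g[sites <= 7] == 0.0)
        assert np.all(g[(sites >= 11) & (sites <= 18)] == pytest.approx(0.6))
        assert np.all(g[sites >= 23] == 1.0)
        # and the 1:1 trace is exactly 100 * G
        profile, _ = simulate_profile(sc)
        (trace,) = build_traces(profile)
        assert np.allclose(trace.values, 100.0 * g, atol=1e-9)

    def test_zero_before_first_region(self):
        """No binding before residue 6 -> c(1) percentages zero at sites 1-5."""
        profile, _ = simulate_profile(rna2_scenario(1, noise_sigma=0.0))
        assert np.all(profile.pct_c[:5, 1] == 0.0)
        assert np.all(profile.pct_y[:5, 0] == 0.0)

    def test_complementarity_exact_at_sigma_zero(self):
        pct_c, pct_y, _ = expected_surfaces(rna2_scenario(2, noise_sigma=0.0))
        assert np.allclose(pct_c, pct_y[:, ::-1], atol=1e-12)

    def test_seed_determinism(self):
        sc = rna2_scenario(1, noise_sigma=5.0, seed=11)
        p1, _ = simulate_profile(sc)
        p2, _ = simulate_profile(sc)
        assert np.array_equal(p1.pct_c, p2.pct_c)
        p3, _ = simulate_profile(sc, seed=12)
        assert not np.array_equal(p1.pct_c, p3.pct_c)

    def test_enumeration_matches_monte_carlo(self):
        """Exact convolution surfaces vs a sampling oracle, within 3 SE."""
        sc = overoccupied_1to3_scenario(noise_sigma=0.0)
        exact, _, _ = expected_surfaces(sc)
        n_draws = 40_000
        mc = monte_carlo_surfaces(sc, n_draws=n_draws, seed=5)
        p = exact / 100.0
        se = 100.0 * np.sqrt(np.maximum(p * (1 - p), 1e-12) / n_draws)
        assert np.all(np.abs(mc - exact) <= 3.0 * se + 1e-9)

    def test_loss_channel_moves_mass_down(self):
        sc = rna2_scenario(2, noise_sigma=0.0, loss_fraction=0.02)
        lossy, _, _ = expected_surfaces(sc)
        clean, _, _ = expected_surfaces(rna2_scenario(2, noise_sigma=0.0))
        assert np.all(lossy[:, 2] <= clean[:, 2] + 1e-12)
        assert np.allclose(lossy.sum(axis=1), 100.0, atol=1e-9)


class TestNoiseModel:
    def test_rows_sum_to_100_and_stay_in_bounds(self):
        profile, _ = simulate_profile(rna2_scenario(3, noise_sigma=5.0), seed=8)
        for arr in (profile.pct_c, profile.pct_y):
            assert np.allclose(arr.sum(axis=1), 100.0, atol=1e-9)
            assert arr.min() >= 0.0 and arr.max() <= 100.0 + 1e-9

    def test_interior_point_noise_level(self):
        """Per-point noise SD equals noise_sigma away from the 0/100 bounds."""
        sc = rna2_scenario(1, noise_sigma=5.0)
        _, truth = simulate_profile(sc)
        interior = np.all(
            (truth.expected_pct_c > 20) & (truth.expected_pct_c < 80), axis=1
        )
        devs = []
        for seed in range(60):
            profile, _ = simulate_profile(sc, seed=seed)
            devs.append(
                (profile.pct_c[interior] - truth.expected_pct_c[interior]).ravel()
            )
        sd = float(np.std(np.concatenate(devs)))
        assert sd == pytest.approx(5.0, rel=0.15)


class TestSimulatePeaklist:
    def test_noise_free_roundtrip_exact(self, rna2, ligand, tmp_path):
        sc = rna2_scenario(1, noise_sigma=0.0)
        df = simulate_peaklist(sc, decoys=0)
        path = tmp_path / "frags.csv"
        df.to_csv(path, index=False)
        peaks = read_peaklist(path, "neutral_mass")
        ladder = fragment_ladder(rna2, ligand, m_max=1)
        res = match_peaks(peaks, ladder)
        profile = site_percentages(res.assignments, n=40, m_total=1)
        expected, _ = simulate_profile(sc)
        obs_defined = ~np.isnan(profile.pct_c)
        assert np.allclose(
            profile.pct_c[obs_defined], expected.pct_c[obs_defined], atol=1e-9
        )

    def test_decoys_do_not_change_assignment_count(self, rna2, ligand):
        from aptamap.spectrum_io import Peak

        sc = rna2_scenario(1, noise_sigma=0.0)
        ladder = fragment_ladder(rna2, ligand, m_max=1)

        def n_assigned(decoys):
            df = simulate_peaklist(sc, decoys=decoys)
            peaks = [
                Peak(r.mass, r.intensity, charge=int(r.z), snr=r.snr)
                for r in df.itertuples(index=False)
            ]
            return len(match_peaks(peaks, ladder).assignments)

        assert n_assigned(50) == n_assigned(0)

    def test_intensity_scale_invariance(self, rna2, ligand):
        from aptamap.spectrum_io import Peak

        sc = rna2_scenario(1, noise_sigma=0.0)
        ladder = fragment_ladder(rna2, ligand, m_max=1)
        profiles = []
        for scale in (1e5, 1e6):
            df = simulate_peaklist(sc, intensity_scale=scale)
            peaks = [
                Peak(r.mass, r.intensity, charge=int(r.z), snr=r.snr)
                for r in df.itertuples(index=False)
            ]
            res = match_peaks(peaks, ladder)
            profiles.append(site_percentages(res.assignments, 40, 1))
        d0 = ~np.isnan(profiles[0].pct_c)
        assert np.allclose(profiles[0].pct_c[d0], profiles[1].pct_c[d0], atol=1e-9)

    def test_negative_decoys_rejected(self):
        with pytest.raises(ValueError, match="decoys"):
            simulate_peaklist(rna2_scenario(1), decoys=-1)


class TestRecovery:
    def test_mean_occupancies_recovered_within_printed_uncertainty(self):
        """End-to-end recovery across seeded replicates of the aptamer
        scenarios: mean motif occupancies within the +-9 points the
        experimental analysis quotes, and replicate scatter within a factor
        2 of the propagated fit errors."""
        from aptamap.motif_occupancy import RNA2_REGIONS
        from aptamap.pipeline import quantify_occupancies

        for m_total in (1, 2):
            sc = lambda: rna2_scenario(m_total, noise_sigma=5.0)
            truth = sc().occupancies
            recovered = {m: [] for m in truth}
            errors = {m: [] for m in truth}
            for seed in range(1, 31):
                profile, _ = simulate_profile(sc(), seed=seed)
                ana = quantify_occupancies(profile, RNA2_REGIONS)
                for o in ana.occupancies:
                    recovered[o.motif].append(o.occupancy)
                    errors[o.motif].append(o.error)
            for motif, target in truth.items():
                mean = np.mean(recovered[motif])
                assert abs(mean - target) <= 9.0, (m_total, motif, mean)
                sd = np.std(recovered[motif])
                mean_err = np.mean(errors[motif])
                if target > 0:
                    assert 0.5 * sd <= max(mean_err, 1.0) <= 4.0 * sd
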