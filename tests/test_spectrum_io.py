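"""Peak-list parsing, ppm matching, and stoichiometry distributions."""

import numpy as np
import pandas as pd
import pytest

from aptamap.rna_mass import NEOMYCIN_B, fragment_ladder, ion_mz, neutral_mass
from aptamap.spectrum_io import (
    Peak,
    match_peaks,
    abundance_table,
    read_peaklist,
    stoichiometry_distribution,
)
from aptamap.synthetic_data import rna2_scenario, simulate_peaklist


def _write(tmp_path, text, name="peaks.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPeaklist:
    def test_neutral_mass_dialect(self, tmp_path):
        path = _write(tmp_path, "mass,intensity,snr\n1000.0,50,12\n2000.0,30,8\n900.5,1,4\n")
        peaks = read_peaklist(path, "neutral_mass")
        assert len(peaks) == 3
        assert peaks[0].neutral_mass == 1000.0
        assert peaks[0].charge is None

    def test_mz_charge_dialect_recovers_neutral(self, tmp_path):
        mz = ion_mz(1000.0, 1)
        path = _write(tmp_path, f"mz,z,intensity\n{mz:.10f},1,50\n")
        (peak,) = read_peaklist(path, "mz_charge")
        assert peak.neutral_mass == pytest.approx(1000.0, abs=1e-6)
        assert peak.charge == 1

    def test_negative_intensity_names_row(self, tmp_path):
        path = _write(tmp_path, "mass,intensity\n1000.0,5\n1100.0,-2\n")
        with pytest.raises(ValueError, match="row 3"):
            read_peaklist(path, "neutral_mass")

    def test_missing_field_and_unknown_dialect(self, tmp_path):
        path = _write(tmp_path, "mass,intensity\n1000.0,\n")
        with pytest.raises(ValueError, match="row 2"):
            read_peaklist(path, "neutral_mass")
        with pytest.raises(ValueError, match="dialect"):
            read_peaklist(path, "weird")

    def test_tsv_separator_sniffed(self, tmp_path):
        path = _write(tmp_path, "mass\tintensity\n1000.0\t5\n", name="peaks.tsv")
        assert len(read_peaklist(path, "neutral_mass")) == 1


@pytest.fixture(scope="module")
def ladder(rna2, ligand):
    return fragment_ladder(rna2, ligand, m_max=1)


class TestMatchPeaks:
    def test_exact_match(self, ladder):
        target = next(f for f in ladder if f.label == "c5(1)")
        res = match_peaks([Peak(target.neutral_mass, 10.0, charge=2, snr=50)], ladder)
        assert len(res.assignments) == 1
        a = res.assignments[0]
        assert a.fragment.label == "c5(1)"
        assert a.ppm_error == 0.0
        assert a.normalized_abundance == 5.0

    def test_out_of_tolerance_unassigned(self, ladder):
        target = ladder[10].neutral_mass
        peak = Peak(target * (1 + 10e-6), 10.0, charge=1, snr=50)
        res = match_peaks([peak], ladder, ppm_tol=5.0)
        assert res.assignments == [] and len(res.unassigned) == 1

    def test_snr_filter(self, ladder):
        peak = Peak(ladder[0].neutral_mass, 10.0, charge=1, snr=2.0)
        res = match_peaks([peak], ladder, snr_min=3.0)
        assert res.assignments == [] and res.n_snr_rejected == 1

    def test_ambiguous_peak_excluded(self):
        from aptamap.rna_mass import FragmentSpecies

        twins = [
            FragmentSpecies("c", 1, 0, 1000.000),
            FragmentSpecies("c", 2, 0, 1000.001),  # 1 ppm apart
        ]
        res = match_peaks([Peak(1000.0005, 5.0, charge=1, snr=9)], twins, ppm_tol=5.0)
        assert res.assignments == [] and len(res.ambiguous) == 1

    def test_empty_ladder_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            match_peaks([Peak(1000.0, 1.0)], [])

    def test_order_independent(self, ladder, rng):
        chosen = [ladder[i] for i in rng.choice(len(ladder), size=25, replace=False)]
        peaks = [
            Peak(f.neutral_mass * (1 + rng.uniform(-2e-6, 2e-6)), 10.0, charge=1, snr=9)
            for f in chosen
        ]
        res1 = match_peaks(peaks, ladder)
        res2 = match_peaks(list(reversed(peaks)), ladder)
        key = lambda a: (a.fragment.label, a.peak.neutral_mass)
        assert sorted(map(key, res1.assignments)) == sorted(map(key, res2.assignments))

    def test_filter_monotonicity(self, ladder, rng):
        idx = rng.choice(len(ladder), size=30, replace=False)
        peaks = [
            Peak(
                ladder[i].neutral_mass * (1 + rng.normal(0, 2e-6)),
                10.0,
                charge=1,
                snr=float(rng.uniform(1, 20)),
            )
            for i in idx
        ]
        base = len(match_peaks(peaks, ladder, ppm_tol=5, snr_min=3).assignments)
        assert len(match_peaks(peaks, ladder, ppm_tol=5, snr_min=6).assignments) <= base
        assert len(match_peaks(peaks, ladder, ppm_tol=2, snr_min=3).assignments) <= base

    def test_decoy_spiked_list_counts(self, rna2, ligand):
        """20 true peaks + 5 decoys >= 25 ppm away -> exactly 20 assignments."""
        ladder = fragment_ladder(rna2, ligand, m_max=1)
        rng = np.random.default_rng(7)
        chosen = rng.choice(len(ladder), size=20, replace=False)
        peaks = [Peak(ladder[i].neutral_mass, 10.0, charge=1, snr=9) for i in chosen]
        masses = np.array([f.neutral_mass for f in ladder])
        added = 0
        while added < 5:
            m = rng.uniform(masses.min(), masses.max())
            if np.min(np.abs(m - masses) / masses) * 1e6 >= 25:
                peaks.append(Peak(m, 10.0, charge=1, snr=9))
                added += 1
        res = match_peaks(peaks, ladder, ppm_tol=5.0)
        assert len(res.assignments) == 20

    def test_charge_states_summed_after_normalization(self, ladder):
        f = ladder[3]
        peaks = [
            Peak(f.neutral_mass, 10.0, charge=2, snr=9),
            Peak(f.neutral_mass, 30.0, charge=6, snr=9),
        ]
        res = match_peaks(peaks, ladder)
        table = abundance_table(res.assignments)
        assert len(table) == 1
        assert table["abundance"].iloc[0] == pytest.approx(10.0)  # 5 + 5
        assert table["n_peaks"].iloc[0] == 2


class TestStoichiometryDistribution:
    def test_single_species(self, rna2, ligand):
        peaks = [Peak(neutral_mass(rna2), 40.0, charge=10, snr=9)]
        frac = stoichiometry_distribution(peaks, rna2, ligand, m_range=(0, 1, 2))
        assert frac[0] == 1.0 and frac[1] == 0.0

    def test_equal_normalized_abundances(self, rna2, ligand):
        m0 = neutral_mass(rna2)
        m1 = m0 + ligand.neutral_monoisotopic_mass
        peaks = [
            Peak(m0, 20.0, charge=10, snr=9),
            Peak(m1, 24.0, charge=12, snr=9),
        ]
        frac = stoichiometry_distribution(peaks, rna2, ligand, m_range=(0, 1))
        assert frac[0] == pytest.approx(0.5) and frac[1] == pytest.approx(0.5)

    def test_generated_mixture_roundtrip(self, rna2, ligand, tmp_path):
        from aptamap.synthetic_data import simulate_precursor_peaklist

        weights = {0: 0.2, 1: 0.5, 2: 0.3}
        df = simulate_precursor_peaklist(rna2, weights, ligand, seed=3)
        path = tmp_path / "precursors.csv"
        df[["mass", "z", "intensity", "snr"]].to_csv(path, index=False)
        peaks = read_peaklist(path, "neutral_mass")
        frac = stoichiometry_distribution(peaks, rna2, ligand, m_range=(0, 1, 2))
        for m, w in weights.items():
            assert frac[m] == pytest.approx(w, abs=1e-9)

    def test_no_match_is_error(self, rna2, ligand):
        with pytest.raises(ValueError, match="no precursor"):
            stoichiometry_distribution(
                [Peak(1234.5, 10.0, charge=1, snr=9)], rna2, ligand, m_range=(0, 1)
            )


class TestMzml:
    def test_minimal_mzml_centroids(self, tmp_path):
        """Centroid arrays from a minimal mzML document become Peaks."""
        import base64
        import struct
        import zlib

        from aptamap.spectrum_io import read_mzml_centroids

        mzs = [500.25, 801.5, 1203.75]
        ints = [10.0, 20.0, 30.0]

        def enc(values):
            raw = struct.pack(f"<{len(values)}d", *values)
            return base64.b64encode(raw).decode()

        doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r1">
    <spectrumList count="1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{len(mzs)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(enc(mzs))}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{enc(mzs)}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(enc(ints))}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{enc(ints)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""
        path = tmp_path / "tiny.mzML"
        path.write_text(doc)
        peaks = read_mzml_centroids(path)
        assert [p.neutral_mass for p in peaks] == pytest.approx(mzs)
        assert [p.intensity for p in peaks] == pytest.approx(ints)
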