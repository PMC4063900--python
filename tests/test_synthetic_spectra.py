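"""Isotopic distributions and the 2D spectrum simulator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pyteomics import mass as pmass

from oligoims import peptide_mass as pm
from oligoims import synthetic_spectra as syn


def oracle_isotopic_distribution(composition):
    """Independent brute-force oracle: multiply per-atom isotope polynomials
    one atom at a time, tracking abundance and mass moment per neutron count."""
    dist = {0: (1.0, 0.0)}  # neutron offset -> (abundance, mass moment)
    for element, count in composition.items():
        isotopes = [
            (num, m, ab)
            for num, (m, ab) in pmass.nist_mass[element].items()
            if num != 0 and ab > 0
        ]
        base = min(num for num, _, _ in isotopes)
        for _ in range(int(count)):
            new = {}
            for offset, (ab, mom) in dist.items():
                for num, iso_mass, iso_ab in isotopes:
                    key = offset + num - base
                    a, m = new.get(key, (0.0, 0.0))
                    new[key] = (a + ab * iso_ab, m + mom * iso_ab + ab * iso_ab * iso_mass)
            dist = new
    total = sum(a for a, _ in dist.values())
    out = sorted((k, a / total, m / a) for k, (a, m) in dist.items() if a > 0)
    return (
        np.array([m for _, _, m in out]),
        np.array([a for _, a, _ in out]),
    )


class TestIsotopicDistribution:
    def test_single_isotope_element_gives_one_peak(self):
        pat = syn.isotopic_distribution(pmass.Composition(formula="F10"), 0.0)
        assert len(pat.masses) == 1
        assert pat.abundances[0] == pytest.approx(1.0)

    def test_c2_matches_binomial_closed_form(self):
        r = pmass.nist_mass["C"][13][1]  # 13C natural abundance
        pat = syn.isotopic_distribution(pmass.Composition(formula="C2"), 0.0)
        expected = np.array([(1 - r) ** 2, 2 * r * (1 - r), r**2])
        assert np.allclose(pat.abundances, expected, atol=1e-12)

    def test_ab40_matches_brute_force_oracle(self, ab40_composition):
        pat = syn.isotopic_distribution(ab40_composition, 0.0)
        o_masses, o_ab = oracle_isotopic_distribution(ab40_composition)
        k = min(len(pat.masses), len(o_masses))
        tv = 0.5 * (
            np.abs(pat.abundances[:k] - o_ab[:k]).sum()
            + pat.abundances[k:].sum() + o_ab[k:].sum()
        )
        assert tv < 1e-9
        # mass centroids agree wherever the peaks carry measurable abundance
        # (below ~1e-12 the centroids are dominated by floating-point underflow)
        keep = o_ab[:k] > 1e-12
        assert np.allclose(pat.masses[:k][keep], o_masses[:k][keep], atol=1e-6)

    def test_abundances_sum_to_one_after_pruning(self, ab40_composition):
        for prune in (0.0, 1e-6, 1e-3, 0.05):
            pat = syn.isotopic_distribution(ab40_composition, prune)
            assert pat.abundances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_peak_spacing_near_neutron_mass(self, ab40_composition):
        pat = syn.isotopic_distribution(pm.oligomer_composition(ab40_composition, 3, 2), 1e-4)
        gaps = np.diff(pat.masses)
        assert np.all(np.abs(gaps - 1.0033) < 0.01)

    def test_unknown_element_rejected(self):
        comp = pmass.Composition()
        comp["Zz"] = 3
        with pytest.raises(ValueError, match="Zz"):
            syn.isotopic_distribution(comp, 0.0)


class TestEnvelopePeaks:
    @given(z=st.integers(min_value=1, max_value=12), n=st.integers(1, 3))
    def test_spacing_times_z_is_one_neutron(self, ab40_composition, z, n):
        comp = pm.oligomer_composition(ab40_composition, n, 0)
        pat = syn.isotopic_distribution(comp, 1e-4)
        peaks = syn.envelope_mz_peaks(pat, z)
        spacing = np.diff(peaks[:, 0])
        assert np.all(np.abs(spacing * z - 1.0033) / 1.0033 < 0.005)

    def test_monomer_and_dimer_overlap_at_distinct_spacings(self, ab40_composition):
        # monomer 4+ and dimer 8+ share the same m/z region but differ in
        # envelope spacing by a factor of two
        mono = syn.envelope_mz_peaks(syn.isotopic_distribution(ab40_composition, 1e-4), 4)
        dim = syn.envelope_mz_peaks(
            syn.isotopic_distribution(pm.oligomer_composition(ab40_composition, 2, 0), 1e-4), 8
        )
        assert abs(np.median(np.diff(mono[:, 0])) - 1.0033 / 4) < 0.002
        assert abs(np.median(np.diff(dim[:, 0])) - 1.0033 / 8) < 0.002
        assert abs(np.mean(mono[:, 0]) - np.mean(dim[:, 0])) < 2.0


class TestRenderSpectrum:
    def test_empty_scenarios_yield_zero_matrix(self):
        spec = syn.render_spectrum([], (1000, 1001), (5, 6), noise_sd=0.0)
        assert np.all(spec.intensities == 0)

    def test_drift_profile_recovers_configured_gaussian(self, ab40_composition):
        sc = syn.make_scenario(
            ab40_composition, pm.OligomerSpecies(1, 0, 4), [(6.3, 0.3, 1.0)]
        )
        spec = syn.render_spectrum([sc], (1080, 1087), (4, 9), noise_sd=0.0)
        prof = spec.drift_profile()
        t = spec.drift_axis
        total = prof.sum()
        mean = np.dot(t, prof) / total
        sigma = np.sqrt(np.dot((t - mean) ** 2, prof) / total)
        assert mean == pytest.approx(6.3, abs=1e-3)
        assert sigma == pytest.approx(0.3, abs=1e-3)

    def test_total_intensity_conserved(self, ab40_composition):
        sc = syn.make_scenario(
            ab40_composition,
            pm.OligomerSpecies(1, 0, 4),
            [(6.3, 0.3, 0.7), (7.5, 0.4, 0.5)],
            total_intensity=2.5,
        )
        spec = syn.render_spectrum([sc], (1080, 1087), (4, 10), noise_sd=0.0)
        assert spec.intensities.sum() == pytest.approx(2.5 * 1.2, rel=1e-3)

    def test_seeding_contract(self, ab40_composition):
        sc = syn.make_scenario(
            ab40_composition, pm.OligomerSpecies(1, 0, 4), [(6.3, 0.3, 1.0)]
        )
        kwargs = dict(mz_range=(1080, 1087), drift_range=(4, 9), noise_sd=0.05)
        a = syn.render_spectrum([sc], seed=11, **kwargs)
        b = syn.render_spectrum([sc], seed=11, **kwargs)
        c = syn.render_spectrum([sc], seed=12, **kwargs)
        assert np.array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_uncovered_species_rejected_by_name(self, ab40_composition):
        sc = syn.make_scenario(
            ab40_composition, pm.OligomerSpecies(2, 1, 8), [(6.3, 0.3, 1.0)]
        )
        with pytest.raises(ValueError, match="cDIM8"):
            syn.render_spectrum([sc], (400, 402), (4, 9), noise_sd=0.0)


class TestSpectrumIO:
    def _small_spectrum(self, ab40_composition):
        sc = syn.make_scenario(
            ab40_composition, pm.OligomerSpecies(1, 0, 4), [(6.3, 0.3, 1.0)]
        )
        return syn.render_spectrum(
            [sc], (1081, 1087), (5.0, 7.6), noise_sd=0.02, seed=3
        )

    def test_round_trip_lossless(self, tmp_path, ab40_composition):
        spec = self._small_spectrum(ab40_composition)
        path = tmp_path / "spec.tsv"
        syn.write_spectrum(path, spec)
        back = syn.read_spectrum(path)
        assert np.allclose(back.mz_axis, spec.mz_axis, atol=1e-12)
        assert np.allclose(back.drift_axis, spec.drift_axis, atol=1e-12)
        assert np.allclose(back.intensities, spec.intensities, rtol=1e-10)
        assert back.metadata["seed"] == 3

    def test_negative_intensity_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#seed=1\n1000.0\t5.0\t1.0\n1000.0\t5.05\t-2.0\n")
        with pytest.raises(ValueError, match="line 3"):
            syn.read_spectrum(path)

    def test_header_only_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("#seed=1\n#scenario=none\n")
        with pytest.raises(ValueError, match="no data rows"):
            syn.read_spectrum(path)
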