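"""Shared-center Gaussian decomposition of before/after drift profiles."""

import numpy as np
import pytest

from oligoims import drift_decomposition as dec
from .conftest import gaussian


T = np.arange(5.0, 13.0 + 1e-9, 0.05)


def two_component_pair(amp_b=(1.0, 1.0), amp_a=(1.0, 1.0), centers=(7.4, 10.2),
                       widths=(0.4, 0.4), snr=None, seed=0):
    rng = np.random.default_rng(seed)
    profs = []
    for cond, amps in (("before", amp_b), ("after", amp_a)):
        y = sum(a * gaussian(T, c, w) for a, c, w in zip(amps, centers, widths))
        if snr:
            y = np.clip(y + rng.normal(0, y.max() / snr, len(T)), 0, None)
        profs.append(dec.DriftProfile(T, y, cond))
    return profs


class TestSharedFit:
    def test_identical_noiseless_profiles_recovered(self):
        before, after = two_component_pair()
        fit = dec.fit_shared_mixture(before, after, n_components=2)
        assert np.allclose(fit.centers, [7.4, 10.2], rtol=1e-4)
        assert np.allclose(np.atleast_2d(fit.widths)[0], 0.4, rtol=1e-4)
        assert np.allclose(fit.amplitudes[0], fit.amplitudes[1], rtol=1e-6)
        assert np.allclose(fit.fractions, 0.5, atol=1e-6)

    def test_amplitude_shift_recovered_at_snr_50(self):
        """Condition B halves one component and doubles the other: the
        amplitude ratios come back within 5% at signal-to-noise 50."""
        before, after = two_component_pair(
            amp_b=(1.0, 1.0), amp_a=(0.5, 2.0), snr=50, seed=42
        )
        fit = dec.fit_shared_mixture(before, after, n_components=2)
        ratio = fit.amplitudes[1] / fit.amplitudes[0]
        assert ratio[0] == pytest.approx(0.5, rel=0.05)
        assert ratio[1] == pytest.approx(2.0, rel=0.05)

    def test_single_component_reduces_to_moment_matching(self):
        y = 2.0 * gaussian(T, 8.3, 0.6)
        p = dec.DriftProfile(T, y, "before")
        q = dec.DriftProfile(T, 0.7 * y, "after")
        fit = dec.fit_shared_mixture(p, q, n_components=1)
        assert fit.centers[0] == pytest.approx(8.3, abs=1e-3)
        assert np.atleast_2d(fit.widths)[0][0] == pytest.approx(0.6, rel=1e-3)
        assert fit.amplitudes[1][0] / fit.amplitudes[0][0] == pytest.approx(0.7, rel=1e-6)

    def test_mismatched_grids_rejected(self):
        p = dec.DriftProfile(T, np.ones_like(T), "before")
        q = dec.DriftProfile(T[:-1], np.ones(len(T) - 1), "after")
        with pytest.raises(ValueError, match="grid"):
            dec.fit_shared_mixture(p, q, n_components=1)

    def test_joint_rescaling_leaves_fractions_unchanged(self):
        before, after = two_component_pair(amp_b=(0.6, 1.0), amp_a=(1.0, 0.3))
        fit1 = dec.fit_shared_mixture(before, after, n_components=2)
        scaled = [
            dec.DriftProfile(p.times, 50.0 * p.intensities, p.condition)
            for p in (before, after)
        ]
        fit2 = dec.fit_shared_mixture(scaled[0], scaled[1], n_components=2)
        assert np.allclose(fit1.fractions, fit2.fractions, atol=1e-6)

    def test_zero_amplitude_component_leaves_residual_unchanged(self):
        before, after = two_component_pair(amp_b=(1.0, 0.8), amp_a=(1.0, 0.0))
        fit2 = dec.fit_shared_mixture(before, after, n_components=2)
        assert fit2.amplitudes[1][1] == pytest.approx(0.0, abs=1e-9)
        # removing the component the after-profile does not use changes nothing
        only = dec.SharedGaussianMixture(n_components=1).fit(
            T, after.intensities[:, None]
        )
        assert only.residual_rms_[0] == pytest.approx(fit2.residual_rms[1], abs=1e-9)

    def test_shared_residual_at_least_unconstrained(self):
        before, after = two_component_pair(
            amp_b=(1.0, 0.5), amp_a=(0.4, 1.2), snr=80, seed=7
        )
        shared = dec.fit_shared_mixture(before, after, n_components=2)
        rss_shared = float(np.sum(shared.residual_rms**2))
        rss_free = 0.0
        for p in (before, after):
            est = dec.SharedGaussianMixture(n_components=2).fit(
                p.times, p.intensities[:, None]
            )
            rss_free += float(est.residual_rms_[0] ** 2)
        assert rss_shared >= rss_free - 1e-12
        # the generating centers coincide, so the penalty for sharing is tiny
        assert rss_shared <= rss_free * 1.5 + 1e-12

    def test_deterministic_under_fixed_seed(self):
        before, after = two_component_pair(amp_a=(0.5, 2.0), snr=30, seed=5)
        f1 = dec.fit_shared_mixture(before, after, n_components=2, random_state=3)
        f2 = dec.fit_shared_mixture(before, after, n_components=2, random_state=3)
        assert np.array_equal(f1.centers, f2.centers)
        assert np.array_equal(f1.amplitudes, f2.amplitudes)


class TestPopulationShift:
    def test_equal_amplitudes_give_zero_deltas(self):
        before, after = two_component_pair()
        report = dec.population_shift_report(
            dec.fit_shared_mixture(before, after, n_components=2)
        )
        assert np.allclose(report.delta_fraction, 0.0, atol=1e-9)
        assert report.attrs["shift_direction"] == "none"

    def test_compact_gain_detected(self):
        # population moves into the early-drift (compact) component
        before, after = two_component_pair(amp_b=(1.0, 1.0), amp_a=(2.0, 0.5))
        report = dec.population_shift_report(
            dec.fit_shared_mixture(before, after, n_components=2)
        )
        assert report.iloc[0].delta_fraction > 0
        assert report.iloc[1].delta_fraction < 0
        assert report.attrs["shift_direction"] == "toward compact"

    def test_component_absent_after_has_zero_fraction(self):
        before, after = two_component_pair(
            amp_b=(0.8, 1.0, 0.6), amp_a=(1.0, 0.9, 0.0),
            centers=(6.5, 8.8, 11.0), widths=(0.35, 0.4, 0.45),
        )
        fit = dec.fit_shared_mixture(before, after, n_components=3)
        report = dec.population_shift_report(fit)
        assert report.iloc[2][f"fraction_after"] == pytest.approx(0.0, abs=1e-6)

    def test_empty_condition_fractions_undefined(self):
        before, _ = two_component_pair()
        empty = dec.DriftProfile(T, np.zeros_like(T), "after")
        fit = dec.fit_shared_mixture(before, empty, n_components=2)
        assert np.all(np.isnan(fit.fractions[1]))
        report = dec.population_shift_report(fit)
        assert report.attrs["shift_direction"] == "undefined"


class TestModelSelection:
    def test_single_gaussian_pair_selects_one(self):
        y = gaussian(T, 8.0, 0.5)
        p = dec.DriftProfile(T, y, "before")
        q = dec.DriftProfile(T, 0.6 * y, "after")
        assert dec.select_n_components(p, q, n_max=3) == 1

    def test_well_separated_pair_selects_two(self):
        before, after = two_component_pair(amp_a=(0.5, 2.0), snr=100, seed=1)
        assert dec.select_n_components(before, after, n_max=3) == 2

    def test_pure_noise_selects_one_and_flags(self):
        rng = np.random.default_rng(0)
        p = dec.DriftProfile(T, np.abs(rng.normal(0, 1, len(T))), "before")
        q = dec.DriftProfile(T, np.abs(rng.normal(0, 1, len(T))), "after")
        est = dec.SharedGaussianMixture(n_components="auto", n_max=3).fit(
            T, np.column_stack([p.intensities, q.intensities])
        )
        assert est.n_components_ == 1
        assert est.ill_conditioned_
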