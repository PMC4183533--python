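"""FXL relaxation bookkeeping and SPGR signal synthesis."""

import numpy as np
import pytest

from dcevox.mr_signal import (
    ScanParameters,
    blood_r1,
    composite_r1,
    elemental_r1,
    invert_spgr,
    sample_time_course,
    spgr_signal,
)


@pytest.fixture(scope="module")
def scan():
    return ScanParameters()


class TestElementalR1:
    def test_reference_arithmetic(self, scan):
        # one 2 um^2 element in a (250 um)^2 voxel at 1 mM
        r = elemental_r1(1.0, 2.0e-6, 0.0625, scan)
        assert r == pytest.approx((0.5 + 4.7) * 3.2e-5, rel=1e-12)

    def test_baseline(self, scan):
        assert elemental_r1(0.0, 2.0e-6, 0.0625, scan) == pytest.approx(0.5 * 3.2e-5)

    def test_relaxivity_zero_removes_concentration_dependence(self):
        scan0 = ScanParameters(r1=0.0)
        assert elemental_r1(5.0, 1e-6, 0.0625, scan0) == elemental_r1(
            0.0, 1e-6, 0.0625, scan0
        )


class TestBloodR1:
    def test_values(self, scan):
        assert blood_r1(0.0, scan) == pytest.approx(0.5)
        assert blood_r1(1.0, scan) == pytest.approx(5.2)

    def test_linearity(self, scan):
        cp = np.linspace(0.0, 2.0, 9)
        r = blood_r1(cp, scan)
        assert np.allclose(np.diff(r, 2), 0.0)


class TestCompositeR1:
    def test_all_baseline_gives_half_per_second(self, scan, reference_domain,
                                                reference_mesh):
        d, m = reference_domain, reference_mesh
        rates = elemental_r1(np.zeros(len(m.triangles)), m.element_areas,
                             d.tile_area, scan)
        # weights sum to the meshed EES fraction; complete the partition with
        # the domain's vp and veis
        ve_mesh = m.element_areas.sum() / d.tile_area
        total = composite_r1(rates, d.vp_achieved, blood_r1(0.0, scan),
                             1.0 - ve_mesh - d.vp_achieved, scan)
        assert total == pytest.approx(0.5, rel=1e-9)

    def test_reference_arithmetic(self, scan):
        # ve = 0.39 at C = 1 mM, vp = 0.03 at Cp = 2 mM, rest baseline
        rates = np.array([0.39 * (0.5 + 4.7 * 1.0)])
        total = composite_r1(rates, 0.03, blood_r1(2.0, scan), 0.58, scan, ve=0.39)
        assert total == pytest.approx(0.39 * 5.2 + 0.03 * 9.9 + 0.58 * 0.5)

    def test_merging_equal_concentration_elements_is_neutral(self, scan):
        a = elemental_r1(np.array([1.5, 1.5]), np.array([1e-6, 3e-6]), 0.0625, scan)
        b = elemental_r1(np.array([1.5]), np.array([4e-6]), 0.0625, scan)
        assert composite_r1(a, 0.0, 0.0, 0.0, scan) == pytest.approx(
            composite_r1(b, 0.0, 0.0, 0.0, scan)
        )

    def test_fraction_sum_enforced(self, scan):
        with pytest.raises(ValueError):
            composite_r1(np.array([0.1]), 0.4, 1.0, 0.4, scan, ve=0.39)


class TestSPGR:
    def test_reference_value(self, scan):
        assert spgr_signal(0.5, scan) == pytest.approx(0.01100, abs=5e-6)

    def test_saturation_limit(self, scan):
        assert spgr_signal(1e6, scan) == pytest.approx(np.sin(np.radians(25.0)))

    def test_round_trip(self, scan):
        for r1 in (0.3, 0.5, 2.0, 10.0):
            assert invert_spgr(spgr_signal(r1, scan), scan) == pytest.approx(
                r1, abs=1e-10
            )

    def test_monotone_in_r1(self, scan):
        r1 = np.linspace(0.1, 20.0, 500)
        si = spgr_signal(r1, scan)
        assert (np.diff(si) > 0).all()

    def test_saturated_signal_not_invertible(self, scan):
        with pytest.raises(ValueError):
            invert_spgr(np.sin(np.radians(25.0)) * 1.001, scan)


class TestSampling:
    def test_sample_count_at_1p6_s(self, scan):
        times = np.arange(0.0, 660.0001, 0.05)
        r1 = np.full_like(times, 0.5)
        sig = sample_time_course(r1, times, 1.6, scan)
        assert len(sig.si) == 413

    def test_resolution_equal_to_duration(self, scan):
        times = np.arange(0.0, 660.0001, 0.05)
        sig = sample_time_course(np.full_like(times, 0.5), times, 660.0, scan)
        assert len(sig.si) == 2

    def test_constant_r1_gives_constant_signal(self, scan):
        times = np.arange(0.0, 100.0001, 0.05)
        sig = sample_time_course(np.full_like(times, 0.8), times, 3.2, scan)
        assert np.ptp(sig.si) == 0.0

    def test_too_fine_resolution_rejected(self, scan):
        times = np.arange(0.0, 10.0001, 0.5)
        with pytest.raises(ValueError):
            sample_time_course(np.full_like(times, 0.5), times, 0.1, scan)

    def test_noise_toggle_off_by_default_and_seeded_when_on(self, scan):
        times = np.arange(0.0, 100.0001, 0.05)
        r1 = np.full_like(times, 0.8)
        clean = sample_time_course(r1, times, 3.2, scan)
        assert np.ptp(clean.si) == 0.0
        rng = np.random.default_rng(5)
        noisy = sample_time_course(r1, times, 3.2, scan, noise_std=1e-4, rng=rng)
        assert np.ptp(noisy.si) > 0.0
        rng2 = np.random.default_rng(5)
        again = sample_time_course(r1, times, 3.2, scan, noise_std=1e-4, rng=rng2)
        np.testing.assert_array_equal(noisy.si, again.si)

    def test_signal_csv_writer(self, scan, tmp_path):
        from dcevox.mr_signal import save_signal_csv

        times = np.arange(0.0, 10.0001, 0.1)
        sig = sample_time_course(np.full_like(times, 0.6), times, 1.6, scan)
        path = tmp_path / "sig.csv"
        save_signal_csv(sig, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "t_s,SI"
        assert len(lines) == len(sig.si) + 1

    def test_nearest_sample_extraction(self, scan):
        times = np.arange(0.0, 10.0001, 0.5)
        r1 = 0.5 + 0.01 * np.arange(len(times))
        sig = sample_time_course(r1, times, 1.6, scan)
        # t = 1.6 s must pick the stored step at 1.5 s (nearest)
        from dcevox.mr_signal import spgr_signal as fwd

        assert sig.si[1] == pytest.approx(fwd(r1[3], scan))


def test_scan_parameter_validation():
    with pytest.raises(ValueError):
        ScanParameters(TR=0.0)
    with pytest.raises(ValueError):
        ScanParameters(flip_angle_deg=95.0)
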