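"""Shear-wave propagation: speed recovery, linearity, symmetry, energy."""

import numpy as np
import pytest

from nlswei.phantom import make_test_fixture
from nlswei.wavesim import ExcitationSpec, WaveRecord, extract_profiles, simulate_wave


def homog_record(mu, width=60.0, height=20.0, duration=12.0, amplitude=0.1):
    ph = make_test_fixture("homogeneous", width=width, height=height, mu0=mu)
    exc = ExcitationSpec(center_x=0.0, amplitude=amplitude)
    return simulate_wave(None, ph, exc, record_duration=duration)


def tof_speed_between(rec, x1, x2, y):
    """Arrival-time oracle: front (half-rise of |du/dt|) at two positions."""
    prof = extract_profiles(rec, [x1, x2], y=y)
    taus = []
    for xp in (x1, x2):
        v = np.abs(np.gradient(prof[xp]))
        p = np.argmax(v[: int(0.9 * len(v))])
        th = 0.5 * v[p]
        below = np.nonzero(v[:p + 1] < th)[0]
        k = below[-1]
        frac = (th - v[k]) / max(1e-30, v[k + 1] - v[k])
        taus.append((k + frac) * rec.dt)
    return (x2 - x1) / (taus[1] - taus[0])


class TestSpeedRecovery:
    @pytest.mark.parametrize("mu,c", [(1.0, 1.0), (4.0, 2.0), (10.0, 3.162),
                                      (40.0, 6.325)])
    def test_homogeneous_speed_within_3pct(self, mu, c):
        dur = min(30.0, 4.0 + 25.0 / c)
        rec = homog_record(mu, duration=dur)
        est = tof_speed_between(rec, 8.0, 20.0, y=10.0)
        assert est == pytest.approx(c, rel=0.03)

    def test_record_metadata(self):
        rec = homog_record(4.0, duration=5.0)
        assert rec.dt == 0.125
        assert rec.dx == pytest.approx(0.2)
        assert np.all(rec.displacement_y[0] == 0.0)
        assert np.isfinite(rec.displacement_y).all()


class TestLinearityAndSymmetry:
    def test_displacement_linear_in_amplitude(self):
        a = homog_record(4.0, duration=6.0, amplitude=0.1)
        b = homog_record(4.0, duration=6.0, amplitude=0.2)
        ref = np.abs(a.displacement_y).max()
        assert np.abs(b.displacement_y - 2 * a.displacement_y).max() < 1e-6 * ref

    def test_zero_amplitude_gives_zero_record(self):
        rec = homog_record(4.0, duration=4.0, amplitude=0.0)
        assert np.all(rec.displacement_y == 0.0)

    def test_mirror_symmetry_about_push(self):
        rec = homog_record(4.0, duration=8.0)
        # probe exact mirror cell centers (columns sit at +-(0.1 + 0.2 k))
        prof = extract_profiles(rec, [10.1, -10.1], y=10.0)
        ref = np.abs(prof[10.1]).max()
        assert np.abs(prof[10.1] - prof[-10.1]).max() < 1e-6 * ref

    def test_peak_times_ordered_with_distance(self):
        rec = homog_record(4.0, duration=12.0)
        prof = extract_profiles(rec, [8.0, 11.1], y=10.0)
        t = rec.times
        t1 = t[np.argmax(np.abs(np.gradient(prof[8.0])))]
        t2 = t[np.argmax(np.abs(np.gradient(prof[11.1])))]
        assert t2 > t1


class TestEnergyAndErrors:
    def test_energy_bounded_after_push(self):
        """Without damping the post-push displacement amplitude must not
        grow (discrete stability at the chosen CFL number)."""
        rec = homog_record(4.0, duration=10.0)
        rms = np.sqrt((rec.displacement_y ** 2).mean(axis=(1, 2)))
        i0 = np.searchsorted(rec.times, 2.0)
        assert rms[-1] < 1.5 * rms[i0:].max()

    def test_excitation_outside_domain_rejected(self):
        ph = make_test_fixture("homogeneous", width=20, height=10)
        with pytest.raises(ValueError):
            simulate_wave(None, ph, ExcitationSpec(center_x=30.0), 2.0)

    def test_profile_outside_extent_rejected(self):
        rec = homog_record(4.0, duration=3.0)
        with pytest.raises(ValueError):
            extract_profiles(rec, [200.0], y=10.0)

    def test_layered_fixture_speeds_differ(self):
        """Layer speeds follow c = sqrt(mu/rho); probed away from the
        interface (head waves refracted from the fast layer arrive first
        near it and bias the slow layer's apparent speed)."""
        ph = make_test_fixture("layered", width=60, height=24, mu0=4.0,
                               mu0_top=16.0)
        rec = simulate_wave(None, ph, ExcitationSpec(center_x=0.0), 12.0)
        c_top = tof_speed_between(rec, 8.0, 16.0, y=21.0)
        c_bot = tof_speed_between(rec, 6.0, 10.0, y=2.0)
        assert c_top == pytest.approx(4.0, rel=0.15)
        assert c_bot == pytest.approx(2.0, rel=0.15)


class TestPsvEngine:
    def test_psv_arrival_consistent_with_scalar_engine(self):
        """The vector P-SV engine and the scalar engine agree on the shear
        front arrival in a homogeneous block (validation cross-check)."""
        ph = make_test_fixture("homogeneous", width=40, height=12, mu0=4.0,
                               grid_spacing=0.4)
        exc = ExcitationSpec(center_x=0.0)
        sh = simulate_wave(None, ph, exc, 8.0, spacing=0.4, engine="sh")
        psv = simulate_wave(None, ph, exc, 8.0, spacing=0.4, engine="psv")
        c_sh = tof_speed_between(sh, 6.0, 14.0, y=6.0)
        c_psv = tof_speed_between(psv, 6.0, 14.0, y=6.0)
        assert c_psv == pytest.approx(c_sh, rel=0.15)


def test_record_roundtrip(tmp_path):
    rec = homog_record(4.0, duration=3.0)
    path = tmp_path / "rec.npz"
    rec.save(path)
    back = WaveRecord.load(path)
    assert back.dt == rec.dt
    assert np.allclose(back.displacement_y, rec.displacement_y, atol=1e-4)
    assert np.array_equal(back.label, rec.label)
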