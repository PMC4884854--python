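"""Reconstruction pipeline: directional filter, TOF, modulus and contrast."""

import numpy as np
import pytest

from nlswei.swei import (_nanmedian_filter, contrast, directional_filter,
                         modulus_map, tof_speed, SpeedMap)
from nlswei.wavesim import WaveRecord


def plane_wave_record(direction=+1, ny=3, nt=128, nx=128, dt=0.125, dx=0.2):
    """Synthetic monochromatic plane wave, commensurate with the window."""
    t = np.arange(nt) * dt
    x = np.arange(nx) * dx
    k = 2 * np.pi / (nx * dx / 8)        # 8 wavelengths across the aperture
    w = 2 * np.pi / (nt * dt / 10)       # 10 periods in the record
    u = np.sin(k * x[None, :, None] - direction * w * t[:, None, None])
    u = np.repeat(u, ny, axis=2)
    return WaveRecord(displacement_y=u, dt=dt, x=x, y=np.arange(ny) * dx)


def pulse_record(c=2.0, ny=5, nt=160, nx=150, dt=0.125, dx=0.2, t0=0.8):
    """Gaussian pulse sweeping rightward at speed c (mm/ms)."""
    t = np.arange(nt) * dt
    x = np.arange(nx) * dx
    u = np.exp(-((t[:, None] - t0 - x[None, :] / c) / 0.25) ** 2)
    return WaveRecord(displacement_y=np.repeat(u[:, :, None], ny, axis=2),
                      dt=dt, x=x, y=np.arange(ny) * dx)


class TestDirectionalFilter:
    def test_forward_wave_passes(self):
        rec = plane_wave_record(+1)
        out = directional_filter(rec, "forward", pad=False)
        core = np.s_[8:-20, 8:-8, :]   # away from the taper/edges
        err = np.abs(out.displacement_y[core] - rec.displacement_y[core]).max()
        assert err < 0.05 * np.abs(rec.displacement_y).max()

    def test_backward_wave_suppressed_20db(self):
        rec = plane_wave_record(-1)
        out = directional_filter(rec, "forward", pad=False)
        core = np.s_[8:-20, 8:-8, :]
        ratio = (np.abs(out.displacement_y[core]).max()
                 / np.abs(rec.displacement_y).max())
        assert 20 * np.log10(ratio) < -20.0

    def test_standing_wave_splits_linearly(self):
        fwd = plane_wave_record(+1)
        bwd = plane_wave_record(-1)
        both = WaveRecord(displacement_y=fwd.displacement_y + bwd.displacement_y,
                          dt=fwd.dt, x=fwd.x, y=fwd.y)
        out = directional_filter(both, "forward", pad=False)
        core = np.s_[8:-20, 8:-8, :]
        err = np.abs(out.displacement_y[core] - fwd.displacement_y[core]).max()
        assert err < 0.07 * np.abs(fwd.displacement_y).max()

    def test_too_short_record_rejected(self):
        rec = WaveRecord(displacement_y=np.zeros((4, 4, 1)), dt=0.125,
                         x=np.arange(4) * 0.2, y=np.array([0.0]))
        with pytest.raises(ValueError):
            directional_filter(rec)


class TestTofSpeed:
    def test_exact_linear_arrivals_recovered(self):
        sm = tof_speed(pulse_record(c=2.0))
        assert np.nanmean(sm.speed) == pytest.approx(2.0, rel=2e-3)
        assert np.nanstd(sm.speed) < 0.01

    def test_layered_speeds_recovered_away_from_interface(self):
        # piecewise arrival speeds 2 and 4 mm/ms along x
        nt, nx, ny, dt, dx = 200, 200, 5, 0.125, 0.2
        t = np.arange(nt) * dt
        x = np.arange(nx) * dx
        tau = np.where(x < 20, x / 2.0, 10.0 + (x - 20) / 4.0)
        u = np.exp(-((t[:, None] - 1.0 - tau[None, :]) / 0.25) ** 2)
        rec = WaveRecord(displacement_y=np.repeat(u[:, :, None], ny, axis=2),
                         dt=dt, x=x, y=np.arange(ny) * dx)
        sm = tof_speed(rec)
        left = sm.speed[(x > 5) & (x < 15)]
        right = sm.speed[(x > 25) & (x < 35)]
        assert np.nanmean(left) == pytest.approx(2.0, rel=0.05)
        assert np.nanmean(right) == pytest.approx(4.0, rel=0.05)

    def test_degenerate_columns_masked_not_raised(self):
        rec = pulse_record()
        rec.displacement_y[:, :, :] = 0.0   # no wave at all
        sm = tof_speed(rec)
        assert not sm.valid.all()

    def test_median_filter_idempotent_on_constant_map(self):
        a = np.full((40, 30), 3.0)
        a[5, 5] = np.nan
        out = _nanmedian_filter(a, 11)
        assert np.nanmax(np.abs(out - 3.0)) < 1e-12


class TestModulusAndContrast:
    def test_modulus_formula(self):
        sm = SpeedMap(speed=np.array([[2.0, 2.449]]),
                      valid=np.array([[True, True]]),
                      x=np.array([0.0, 0.2]), y=np.array([0.0]))
        gm = modulus_map(sm, 1000.0)
        assert gm.modulus[0, 0] == pytest.approx(4.0)
        # 2.449 m/s is the paper-scale 6 kPa speed
        assert gm.modulus[0, 1] == pytest.approx(6.0, rel=1e-3)

    def test_masked_cells_stay_masked(self):
        sm = SpeedMap(speed=np.array([[2.0, np.nan]]),
                      valid=np.array([[True, False]]),
                      x=np.array([0.0, 0.2]), y=np.array([0.0]))
        gm = modulus_map(sm, 1000.0)
        assert not gm.valid[0, 1]
        assert np.isnan(gm.modulus[0, 1])

    def test_nonpositive_density_rejected(self):
        sm = SpeedMap(speed=np.ones((2, 2)), valid=np.ones((2, 2), bool),
                      x=np.arange(2.0), y=np.arange(2.0))
        with pytest.raises(ValueError):
            modulus_map(sm, 0.0)

    def test_contrast_values(self):
        assert contrast(6.0, 4.0) == pytest.approx(0.5)
        assert contrast(5.0, 5.0) == 0.0
        # the rounded reported ROI moduli give 1.41; the printed 1.45 came
        # from unrounded values
        assert contrast(41.0, 17.0) == pytest.approx(1.41, abs=0.005)
        with pytest.raises(ValueError):
            contrast(1.0, 0.0)
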