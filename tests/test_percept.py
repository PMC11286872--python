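"""Receptive fields, percept rendering, and phosphene quantification."""

import numpy as np
import pytest

from cortisim.electrodes import Electrode, current_field
from cortisim.percept import (EllipseStats, OMEGA_OFF, build_rf,
                              fit_gaussian_size, quantify_ellipse,
                              render_percept, render_sequence,
                              render_spatial_field, unit_temporal_drive)
from cortisim.retinotopy import cortex_to_visual
from cortisim.temporal import PulseTrain, TemporalParams

TRAIN = PulseTrain(amplitude=1.0, pulse_width=0.25, frequency=50,
                   train_duration=0.2)


def _grid(half=1.0, spacing=0.02):
    x = np.arange(-half, half + spacing, spacing)
    return x, x.copy()


class TestBuildRF:
    def test_zero_separation_subunits_coincide(self, sheet_ecc3):
        iy, ix = np.unravel_index(np.argmin(np.abs(sheet_ecc3.delta_onoff)),
                                  sheet_ecc3.shape)
        sheet_ecc3.delta_onoff[iy, ix] = 0.0
        rf = build_rf(sheet_ecc3, iy, ix)
        np.testing.assert_allclose(rf.on, rf.off)
        assert rf.cell_class == "complex"

    def test_simple_cell_classification(self, sheet_ecc3):
        iy, ix = np.unravel_index(np.argmax(np.abs(sheet_ecc3.delta_onoff)
                                            / sheet_ecc3.sigma_rf),
                                  sheet_ecc3.shape)
        rf = build_rf(sheet_ecc3, iy, ix)
        if abs(rf.delta) > rf.sigma_long / 2:
            assert rf.cell_class == "simple"

    def test_subunits_unit_mass(self, sheet_ecc3):
        rf = build_rf(sheet_ecc3, 10, 10)
        dx = rf.x[1] - rf.x[0]
        assert rf.on.sum() * dx * dx == pytest.approx(1.0, abs=1e-3)
        assert rf.off.sum() * dx * dx == pytest.approx(1.0, abs=1e-3)


class TestRenderSpatial:
    def test_zero_current_zero_field(self, sheet_ecc3):
        x, y, f = render_spatial_field(sheet_ecc3,
                                       np.zeros(sheet_ecc3.shape))
        assert np.all(f == 0)

    def test_point_source_centroid(self, sheet_ecc3):
        """A point source renders a percept centered on its RF position."""
        cur = np.zeros(sheet_ecc3.shape)
        iy, ix = sheet_ecc3.shape[0] // 2, sheet_ecc3.shape[1] // 2
        cur[iy, ix] = 10.0
        x, y, f = render_spatial_field(sheet_ecc3, cur)
        mass = np.abs(f)
        cx = (mass * x[None, :]).sum() / mass.sum()
        cy = (mass * y[:, None]).sum() / mass.sum()
        z = sheet_ecc3.z[iy, ix]
        assert abs(complex(cx, cy) - z) < 0.1

    def test_onoff_weighting_ratio(self, sheet_ecc3):
        """All-ON vs all-OFF sheets give peak intensities in ratio 1:0.8."""
        import copy
        cur = np.zeros(sheet_ecc3.shape)
        cur[30:40, 30:40] = 5.0
        s_on = copy.deepcopy(sheet_ecc3)
        s_on.w_onoff = np.ones_like(s_on.w_onoff)
        s_on.delta_onoff = np.zeros_like(s_on.delta_onoff)
        s_off = copy.deepcopy(sheet_ecc3)
        s_off.w_onoff = np.zeros_like(s_off.w_onoff)
        s_off.delta_onoff = np.zeros_like(s_off.delta_onoff)
        _, _, f_on = render_spatial_field(s_on, cur)
        _, _, f_off = render_spatial_field(s_off, cur)
        ratio = np.abs(f_off).max() / np.abs(f_on).max()
        assert ratio == pytest.approx(OMEGA_OFF, rel=1e-6)
        assert f_off.min() < 0          # OFF drive renders dark

    def test_coarse_grid_rejected(self, sheet_ecc3):
        cur = np.ones(sheet_ecc3.shape)
        big = np.arange(-3, 3, 1.0)
        with pytest.raises(ValueError, match="too coarse"):
            render_spatial_field(sheet_ecc3, cur, grid=(big, big))


class TestRenderPercept:
    def test_separability_frames_proportional(self, sheet_ecc3, params):
        """Pre-compression frames differ only by a scalar over time."""
        cur = np.zeros(sheet_ecc3.shape)
        cur[40, 40] = 1e-3    # small drive keeps compression linear
        mov = render_percept(sheet_ecc3, cur, TRAIN, params, frame_dt=50.0)
        nz = [i for i in range(mov.frames.shape[0])
              if np.abs(mov.frames[i]).max() > 1e-12]
        i, j = nz[len(nz) // 3], nz[2 * len(nz) // 3]
        fi, fj = mov.frames[i], mov.frames[j]
        mask = np.abs(fi) > 1e-9 * np.abs(fi).max()
        ratios = fj[mask] / fi[mask]
        assert ratios.std() / abs(ratios.mean()) < 1e-6

    def test_sequence_single_entry_matches_render(self, sheet_ecc3, params):
        el = Electrode(id="a", position=complex(sheet_ecc3.x.mean(),
                                                sheet_ecc3.y.mean()),
                       rad_e=0.25)
        cur = current_field(el, sheet_ecc3, 20.0)
        m1 = render_percept(sheet_ecc3, cur, TRAIN, params, frame_dt=50.0)
        m2 = render_sequence(sheet_ecc3, [(cur, TRAIN, 0.0)], params,
                             frame_dt=50.0)
        n = min(m1.frames.shape[0], m2.frames.shape[0])
        np.testing.assert_allclose(m1.frames[:n], m2.frames[:n], atol=1e-12)

    def test_simultaneous_superposition(self, sheet_ecc3, params):
        c1 = np.zeros(sheet_ecc3.shape)
        c2 = np.zeros(sheet_ecc3.shape)
        c1[30, 30] = 1e-3
        c2[50, 50] = 1e-3
        both = render_sequence(sheet_ecc3, [(c1, TRAIN, 0.0),
                                            (c2, TRAIN, 0.0)],
                               params, frame_dt=50.0)
        # compose each source's drive on the same grid and compress the sum
        from cortisim.percept import compress
        parts = [render_spatial_field(sheet_ecc3, c, grid=(both.x, both.y))[2]
                 for c in (c1, c2)]
        d = unit_temporal_drive(TRAIN, params)
        dv = np.where(both.times <= d.time[-1], d.at(both.times), 0.0)
        pre = (parts[0] + parts[1])[None, :, :] * dv[:, None, None]
        expect = compress(pre, params.s_in, params.p_div, params.s_out)
        np.testing.assert_allclose(both.frames, expect, atol=1e-12)

    def test_sequential_dominance_with_fast_slow_stage(self):
        """50 ms-per-electrode schedules: with the fast (25 ms) slow-stage
        time constant each electrode's drive carries > 80% of the total at
        its own peak time."""
        p = TemporalParams(tau2=25.0)
        tr = PulseTrain(amplitude=1.0, pulse_width=0.1, frequency=200,
                        train_duration=0.05)
        d = unit_temporal_drive(tr, p)
        t = np.arange(0, 600, 2.0)
        drives = []
        for onset in (0.0, 100.0, 200.0):
            tv = t - onset
            drives.append(np.where((tv >= 0) & (tv <= d.time[-1]),
                                   d.at(tv), 0.0))
        drives = np.array(drives)
        total = drives.sum(axis=0)
        for k in range(3):
            ipk = int(np.argmax(drives[k]))
            assert drives[k, ipk] / total[ipk] > 0.8


class TestQuantifyEllipse:
    def test_disk_area(self):
        x, y = _grid(1.5, 0.02)
        rr = np.hypot(x[None, :], y[:, None])
        frame = np.where(rr <= 1.0, 5.0, 0.0)
        st = quantify_ellipse(frame, x, y, theta_draw=1.0)
        assert st.area == pytest.approx(np.pi, rel=0.02)
        assert st.major == pytest.approx(st.minor, rel=0.02)
        assert abs(st.centroid) < 0.01

    def test_axis_aligned_ellipse(self):
        x, y = _grid(1.5, 0.01)
        e = (x[None, :] / 1.0) ** 2 + (y[:, None] / 0.25) ** 2 <= 1.0
        st = quantify_ellipse(e.astype(float) * 3.0, x, y, theta_draw=1.0)
        assert st.major == pytest.approx(2.0, rel=0.02)
        assert st.minor == pytest.approx(0.5, rel=0.03)
        assert abs(st.orientation) < 0.05
        assert st.mean_diameter == pytest.approx(1.25, rel=0.02)

    def test_dark_regions_count(self):
        x, y = _grid(1.0, 0.02)
        rr = np.hypot(x[None, :], y[:, None])
        frame = np.where(rr <= 0.5, -3.0, 0.0)   # darker than background
        st = quantify_ellipse(frame, x, y, theta_draw=1.0)
        assert not st.empty
        assert st.area == pytest.approx(np.pi * 0.25, rel=0.03)

    def test_empty_sentinel_not_exception(self):
        x, y = _grid()
        st = quantify_ellipse(np.zeros((y.size, x.size)), x, y, 1.0)
        assert st.empty and st.area == 0.0 and np.isnan(st.major)


class TestGaussianFit:
    def test_recovers_sigma(self):
        x, y = _grid(2.0, 0.02)
        rr2 = x[None, :] ** 2 + y[:, None] ** 2
        frame = 4.0 * np.exp(-rr2 / (2 * 0.3 ** 2))
        assert fit_gaussian_size(frame, x, y) == pytest.approx(0.3, rel=0.01)

    def test_amplitude_invariance(self):
        x, y = _grid(2.0, 0.02)
        rr2 = x[None, :] ** 2 + y[:, None] ** 2
        frame = np.exp(-rr2 / (2 * 0.4 ** 2))
        s1 = fit_gaussian_size(frame, x, y)
        s5 = fit_gaussian_size(5 * frame, x, y)
        assert s5 == pytest.approx(s1, rel=1e-6)

    def test_two_lobe_bounded(self):
        # two lobes of sigma 0.2 separated by 1 deg: fitted size between
        # the lobe sigma and the separation
        x, y = _grid(2.0, 0.02)
        g = lambda cx: np.exp(-((x[None, :] - cx) ** 2 + y[:, None] ** 2)
                              / (2 * 0.2 ** 2))
        frame = g(-0.5) + g(0.5)
        s = fit_gaussian_size(frame, x, y)
        assert 0.2 < s < 1.0

    def test_empty_returns_nan(self):
        x, y = _grid()
        assert np.isnan(fit_gaussian_size(np.zeros((y.size, x.size)), x, y))
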