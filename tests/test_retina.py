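import dataclasses
import logging

import numpy as np
import pytest
import scipy.signal

from viscade import retina as R
from viscade import stimuli as S
from viscade.fitting import fraction_variance_explained
from viscade.signals import run_chunked, wrap_video


def dense_gauss(frame2d, sigma):
    from viscade.filters import _dense_gauss_taps

    t = _dense_gauss_taps(sigma)
    out = scipy.signal.convolve2d(frame2d, t[:, None], mode="same")
    return scipy.signal.convolve2d(out, t[None, :], mode="same")


def dense_exp(trace, tau, dt):
    lam = np.exp(-dt / tau)
    n = max(1, int(np.ceil(np.log(1e-12) / np.log(lam))))
    h = (1 - lam) * lam ** np.arange(n)
    return np.apply_along_axis(lambda s: np.convolve(s, h)[: len(s)], 0, trace)


class TestOPL:
    def test_balanced_surround_cancels_luminance(self):
        p = R.OPLParams(w_surround=1.0)
        v = wrap_video(np.full((1200, 6, 6), 0.7), dt=1e-3)
        out = R.opl_stage(v, p)
        # settle for > 10 * max(tau) then check steady state
        assert np.abs(out.values[:, :, -1]).max() < 1e-6 * p.lambda_opl * 0.7

    def test_no_surround_dc_gain(self):
        p = R.OPLParams(w_surround=0.0, lambda_opl=3.0)
        v = wrap_video(np.full((1200, 6, 6), 0.5), dt=1e-3)
        out = R.opl_stage(v, p)
        assert abs(out.values[0, 0, -1, 3, 3] - 3.0 * 0.5) < 1e-6

    def test_step_matches_dense_cascade_oracle(self):
        p = R.OPLParams(sigma_center=1.0, tau_center=0.02, sigma_surround=2.0,
                        tau_surround=0.06, w_surround=0.8, lambda_opl=2.0)
        dt = 1e-3
        frames = np.zeros((400, 21, 21))
        frames[50:] = 1.0
        v = wrap_video(frames, dt)
        out = R.opl_stage(v, p).values[0, 0]
        # dense oracle: sampled kernels, same cascade structure
        c = np.stack([dense_gauss(f, p.sigma_center) for f in frames])
        c = dense_exp(c, p.tau_center, dt)
        s = np.stack([dense_gauss(f, p.sigma_surround) for f in c])
        s = dense_exp(s, p.tau_surround, dt)
        oracle = p.lambda_opl * (c - p.w_surround * s)
        # compare away from spatial borders (different boundary handling)
        err = np.abs(out - oracle)[:, 8:-8, 8:-8].max()
        assert err < 1e-3
        # transient overshoot, then decay toward lambda*(1-w)*step
        center = out[:, 10, 10]
        steady = p.lambda_opl * (1 - p.w_surround) * 1.0
        assert center.max() > 1.5 * steady
        assert abs(center[-1] - steady) < 0.05 * steady

    def test_rejects_multichannel(self):
        from viscade.signals import VideoTensor

        v = VideoTensor(np.zeros((1, 3, 10, 4, 4)) + 0.1, dt=1e-3)
        with pytest.raises(ValueError, match="single-channel"):
            R.opl_stage(v, R.OPLParams())


class TestBipolar:
    def test_linear_fixed_point(self):
        p = R.BipolarParams(g_leak=10.0, lambda_bip=0.0)
        v = wrap_video(np.full((3000, 4, 4), 2.0), dt=1e-3)
        out = R.bipolar_stage(v, p)
        assert abs(out.values[0, 0, -1, 2, 2] - 2.0 / 10.0) < 1e-3

    def test_gain_drops_and_peak_advances_with_contrast(self):
        # drive amplitude stands for lambda_opl * contrast at a unit-gain
        # operating point, so the pooled V^2 actually moves the conductance
        p = R.BipolarParams()
        dt = 1e-3
        t = np.arange(3000) * dt
        results = {}
        for contrast in (0.1, 0.8):
            drive = 30.0 * contrast * np.sin(2 * np.pi * 2.0 * t)
            v = wrap_video(
                np.broadcast_to(drive[:, None, None], (3000, 4, 4)).copy(), dt
            )
            trace = R.bipolar_stage(v, p).values[0, 0, :, 2, 2]
            seg = trace[2500:3000]  # one steady-state cycle at 2 Hz
            amp = (seg.max() - seg.min()) / 2.0
            results[contrast] = (amp / contrast, int(np.argmax(seg)))
        gain_lo, peak_lo = results[0.1]
        gain_hi, peak_hi = results[0.8]
        assert gain_hi < 0.95 * gain_lo
        assert peak_hi < peak_lo  # phase advance

    def test_euler_step_refinement(self):
        p = R.BipolarParams()
        dt = 1e-3
        t = np.arange(1000) * dt
        drive = 5.0 * np.sin(2 * np.pi * 3.0 * t)
        coarse_in = wrap_video(
            np.broadcast_to(drive[:, None, None], (1000, 3, 3)).copy(), dt
        )
        t10 = np.arange(10000) * (dt / 10)
        fine_drive = 5.0 * np.sin(2 * np.pi * 3.0 * t10)
        fine_in = wrap_video(
            np.broadcast_to(fine_drive[:, None, None], (10000, 3, 3)).copy(), dt / 10
        )
        coarse = R.bipolar_stage(coarse_in, p).values[0, 0, :, 1, 1]
        fine = R.bipolar_stage(fine_in, p).values[0, 0, 9::10, 1, 1]
        amp = np.abs(fine).max()
        assert np.abs(coarse - fine).max() < 1e-2 * amp

    def test_rejects_nonpositive_g_leak(self):
        with pytest.raises(ValueError, match="g_leak"):
            R.BipolarParams(g_leak=0.0)

    def test_sublinear_gain_over_contrast_ladder(self):
        p = R.BipolarParams()
        dt = 1e-3
        t = np.arange(2500) * dt
        gains = []
        for contrast in (0.05, 0.1, 0.2, 0.4, 0.8):
            drive = 30.0 * contrast * np.sin(2 * np.pi * 2.0 * t)
            v = wrap_video(drive[:, None, None].copy(), dt)
            trace = R.bipolar_stage(v, p).values[0, 0, :, 0, 0]
            seg = trace[1500:]
            gains.append((seg.max() - seg.min()) / (2 * contrast))
        assert all(g2 <= g1 + 1e-12 for g1, g2 in zip(gains, gains[1:]))

    def test_linear_superposition_without_gain_control(self, rng):
        p = R.BipolarParams(lambda_bip=0.0)
        a = rng.standard_normal((300, 3, 3))
        b = rng.standard_normal((300, 3, 3))
        dt = 1e-3
        out_a = R.bipolar_stage(wrap_video(a, dt), p).values
        out_b = R.bipolar_stage(wrap_video(b, dt), p).values
        out_ab = R.bipolar_stage(wrap_video(a + b, dt), p).values
        assert np.abs(out_ab - (out_a + out_b)).max() < 1e-5


class TestGanglion:
    def test_value_at_threshold(self):
        p = R.GanglionParams(sign=1, v0=0.2, lambda_g=50.0, i0=30.0)
        v = wrap_video(np.full((1, 1, 1), 0.2), dt=1e-3)
        out = R.ganglion_current(v, p)
        assert out.values.ravel()[0] == 30.0

    def test_linear_branch(self):
        p = R.GanglionParams(sign=1, v0=0.2, lambda_g=50.0, i0=30.0)
        v = wrap_video(np.full((1, 1, 1), 1.2), dt=1e-3)
        assert abs(R.ganglion_current(v, p).values.ravel()[0] - 80.0) < 1e-12

    def test_asymptote(self):
        p = R.GanglionParams(sign=1, v0=0.0, lambda_g=50.0, i0=30.0)
        u = -1e6 * p.i0 / p.lambda_g
        v = wrap_video(np.full((1, 1, 1), u), dt=1e-3)
        assert R.ganglion_current(v, p).values.ravel()[0] < 1e-5 * p.i0

    def test_c1_continuity(self):
        p = R.GanglionParams(sign=1, v0=0.1, lambda_g=40.0, i0=20.0)
        eps = 1e-7
        vals = []
        for u in (p.v0 - eps, p.v0 + eps):
            v = wrap_video(np.full((1, 1, 1), u), dt=1e-3)
            vals.append(R.ganglion_current(v, p).values.ravel()[0])
        slope = (vals[1] - vals[0]) / (2 * eps)
        assert abs(slope - p.lambda_g) < 1e-3 * p.lambda_g

    def test_off_sign_flips(self):
        p_off = R.GanglionParams(sign=-1, v0=0.0, lambda_g=10.0, i0=5.0)
        v = wrap_video(np.full((1, 1, 1), -1.0), dt=1e-3)
        assert R.ganglion_current(v, p_off).values.ravel()[0] == 15.0

    def test_rejects_bad_i0(self):
        with pytest.raises(ValueError, match="i0"):
            R.GanglionParams(i0=0.0)


class TestLIF:
    def test_closed_form_isi(self):
        p = R.LIFParams(g_l=10.0, v_thresh=1.0, v_reset=0.0, tau_refr=0.005,
                        sigma_noise=0.0)
        dt = 1e-4
        current = 25.0
        v = wrap_video(np.full((20000, 1, 1), current), dt)
        spikes, _ = R.lif_spikes(v, p)
        times = np.nonzero(spikes.values[0, 0, :, 0, 0])[0]
        isis = np.diff(times) * dt
        expect = p.tau_refr + (1.0 / p.g_l) * np.log(
            (current - p.g_l * p.v_reset) / (current - p.g_l * p.v_thresh)
        )
        assert len(times) > 10
        assert np.abs(isis - expect).max() <= dt + 1e-12

    def test_zero_current_no_spikes(self):
        p = R.LIFParams(sigma_noise=0.0)
        v = wrap_video(np.zeros((500, 2, 2)), dt=1e-3)
        spikes, _ = R.lif_spikes(v, p)
        assert not spikes.values.any()

    def test_seed_determinism(self):
        p = R.LIFParams(sigma_noise=2.0, seed=11)
        v = wrap_video(np.full((800, 3, 3), 40.0), dt=1e-3)
        a, _ = R.lif_spikes(v, p)
        b, _ = R.lif_spikes(v, p)
        assert (a.values == b.values).all()

    def test_refractory_spacing(self):
        p = R.LIFParams(g_l=10.0, tau_refr=0.01, sigma_noise=0.0)
        dt = 1e-3
        v = wrap_video(np.full((2000, 1, 1), 500.0), dt)
        spikes, _ = R.lif_spikes(v, p)
        times = np.nonzero(spikes.values[0, 0, :, 0, 0])[0]
        assert np.diff(times).min() * dt >= p.tau_refr


class TestRetinaModel:
    def test_chirp_run(self):
        stim = S.chirp(S.ChirpSpec(dt=2e-3, shape=(5, 5), t_pre=0.3,
                                   t_pulse=0.9, t_freq=1.0, t_amp=1.0,
                                   t_post=0.2))
        cfg = R.RetinaConfig(dt=2e-3)
        out = R.run_retina(stim, cfg)
        for name, tens in out.stages().items():
            assert np.isfinite(tens.values).all(), name
        # OPL trace crosses zero during the OFF-ON-OFF pulse
        n0 = int(0.3 / 2e-3)
        n1 = int(1.2 / 2e-3)
        pulse_trace = out.i_opl.values[0, 0, n0:n1, 2, 2]
        assert pulse_trace.min() < 0 < pulse_trace.max()

    def test_spiking_disabled(self):
        cfg = R.RetinaConfig(spiking_enabled=False)
        v = wrap_video(np.full((50, 4, 4), 0.5), dt=1e-3)
        out = R.run_retina(v, cfg)
        assert out.spikes_on is None and out.spikes_off is None
        assert out.i_gang_on is not None

    def test_chunked_whole_identical_with_spiking(self, rng):
        stim = wrap_video(0.5 + 0.3 * rng.standard_normal((300, 5, 5)), 1e-3)
        cfg = R.RetinaConfig(lif=R.LIFParams(sigma_noise=2.0, seed=5))
        model = R.RetinaModel(cfg)
        model.reset_state()
        whole = model(stim)
        model.reset_state()
        chunked = run_chunked(model, stim, 64)
        for name, tens in whole.stages().items():
            assert np.abs(tens.values - chunked.stages()[name].values).max() == 0.0, name

    def test_on_off_antisymmetry_on_step(self):
        cfg = R.RetinaConfig(spiking_enabled=False)
        frames = np.full((800, 5, 5), 0.5)
        frames[300:] = 0.8  # luminance increment
        out = R.run_retina(wrap_video(frames, 1e-3), cfg)
        on = out.i_gang_on.values[0, 0, :, 2, 2]
        off = out.i_gang_off.values[0, 0, :, 2, 2]
        base_on, base_off = on[295], off[295]
        k_on = np.argmax(on[300:] > base_on + 0.1 * abs(base_on))
        k_off = np.argmax(off[300:] > base_off + 0.1 * abs(base_off))
        assert on[300:].max() > base_on + 0.1 * abs(base_on)
        # ON responds to the increment before OFF exceeds its baseline
        assert (off[300:].max() <= base_off + 0.1 * abs(base_off)) or k_on < k_off

    def test_variance_explained_per_stage_self(self, rng):
        stim = wrap_video(0.5 + 0.2 * rng.standard_normal((200, 4, 4)), 1e-3)
        cfg = R.RetinaConfig(spiking_enabled=False)
        a = R.run_retina(stim, cfg)
        b = R.run_retina(stim, cfg)
        for name, tens in a.stages().items():
            assert fraction_variance_explained(tens, b.stages()[name]) == pytest.approx(1.0)


class TestSpikeUtilities:
    def test_spike_events_ordering(self):
        raster = np.zeros((1, 1, 10, 2, 2))
        raster[0, 0, 3, 1, 0] = 1
        raster[0, 0, 7, 0, 1] = 1
        from viscade.signals import VideoTensor

        ev = R.spike_events(VideoTensor(raster, dt=0.01))
        assert ev.shape == (2, 4)
        assert ev[0][3] == pytest.approx(0.03)
        assert ev[1][3] == pytest.approx(0.07)
        assert (ev[0][:2] == [1, 0]).all()

    def test_instantaneous_rate_scale(self):
        # a 20 Hz regular train smoothed causally approaches 20 Hz
        raster = np.zeros((1, 1, 4000, 1, 1))
        raster[0, 0, ::50] = 1  # every 50 ms at dt=1 ms
        from viscade.signals import VideoTensor

        rate = R.instantaneous_rate(VideoTensor(raster, dt=1e-3), width=0.5)
        assert abs(rate.values[0, 0, -25, 0, 0] - 20.0) < 2.0


class TestConfigIO:
    def test_minimal_document_warns_per_section(self, tmp_path, caplog):
        path = tmp_path / "minimal.xml"
        path.write_text("<retina/>")
        with caplog.at_level(logging.WARNING, logger="viscade"):
            cfg = R.load_vr_xml(path)
        assert cfg == R.RetinaConfig()
        missing = [r for r in caplog.records if "missing" in r.message]
        assert len(missing) == 4

    def test_attribute_mapping(self, tmp_path):
        path = tmp_path / "c.xml"
        path.write_text(
            '<retina temporal-step__sec="0.002">'
            '<outer-plexiform-layer sigma-center__px="0.5"/>'
            "</retina>"
        )
        cfg = R.load_vr_xml(path)
        assert cfg.opl.sigma_center == 0.5
        assert cfg.dt == 0.002

    def test_radially_varying_ignored_with_warning(self, tmp_path, caplog):
        path = tmp_path / "r.xml"
        path.write_text(
            "<retina><outer-plexiform-layer "
            'radially-varying-sigma-center="0.1" sigma-center__px="1.5"/></retina>'
        )
        with caplog.at_level(logging.WARNING, logger="viscade"):
            cfg = R.load_vr_xml(path)
        assert cfg.opl.sigma_center == 1.5
        assert any("radially-varying" in r.message for r in caplog.records)

    def test_unrecognized_attribute_warned(self, tmp_path, caplog):
        path = tmp_path / "u.xml"
        path.write_text('<retina><spiking-channel frobnication="3"/></retina>')
        with caplog.at_level(logging.WARNING, logger="viscade"):
            R.load_vr_xml(path)
        assert any("frobnication" in r.message for r in caplog.records)

    def test_malformed_number_names_attribute(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text('<retina><contrast-gain-control g-leak__Hz="ten"/></retina>')
        with pytest.raises(ValueError, match="g-leak__Hz"):
            R.load_vr_xml(path)

    def test_ganglion_sign_routing(self, tmp_path):
        path = tmp_path / "g.xml"
        path.write_text(
            "<retina>"
            '<ganglion-layer sign="1" lambda="70"/>'
            '<ganglion-layer sign="-1" lambda="90"/>'
            "</retina>"
        )
        cfg = R.load_vr_xml(path)
        assert cfg.ganglion_on.lambda_g == 70.0
        assert cfg.ganglion_off.lambda_g == 90.0
        assert cfg.ganglion_off.sign == -1

    def test_json_round_trip(self, tmp_path):
        import json

        cfg = R.RetinaConfig(dt=5e-4, bipolar=R.BipolarParams(g_leak=7.0))
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps(R.config_to_dict(cfg)))
        back = R.load_retina_json(path)
        assert back == cfg
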