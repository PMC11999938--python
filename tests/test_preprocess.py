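"""Preprocessing chain: screening, filtering, PCA, envelopes, NMF, windows."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from emgforce import preprocess as pp
from emgforce import sim
from emgforce.errors import (
    DegenerateDecompositionError,
    RecordingUnusableError,
    ValidationError,
)

FS = 1000.0


class TestMinMax:
    def test_direct_evaluation(self):
        out = pp.minmax_normalize(np.array([[2.0, 4.0, 6.0]]))
        assert np.allclose(out, [[0.0, 0.5, 1.0]])

    def test_constant_row_becomes_zero(self):
        out = pp.minmax_normalize(np.array([[3.0, 3.0, 3.0]]))
        assert np.array_equal(out, [[0.0, 0.0, 0.0]])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_idempotence(self, values):
        x = np.array([values])
        once = pp.minmax_normalize(x)
        twice = pp.minmax_normalize(once)
        assert np.allclose(once, twice, atol=1e-12)


class TestScreening:
    def test_clean_recording_untouched(self, healthy_recording):
        report, out = pp.screen_channels(healthy_recording)
        assert report.n_flagged == 0
        assert out is healthy_recording

    def test_flatline_flagged_and_repaired(self, healthy_recording):
        rec = sim.inject_channel_faults(healthy_recording, [(7, "flatline")])
        report, out = pp.screen_channels(rec)
        assert 7 in report.flagged
        assert "variance_floor" in report.reasons[7]
        assert 7 in report.repaired
        assert out.semg[7].var() > 0.0

    def test_saturation_flagged_by_clipping(self, healthy_recording):
        rec = sim.inject_channel_faults(healthy_recording, [(3, "saturation")])
        report, _ = pp.screen_channels(rec)
        assert 3 in report.flagged
        assert "clipping" in report.reasons[3]

    def test_mostly_dead_recording_unusable(self, healthy_recording):
        faults = [(ch, "flatline") for ch in range(40)]
        rec = sim.inject_channel_faults(healthy_recording, faults)
        with pytest.raises(RecordingUnusableError):
            pp.screen_channels(rec)


class TestResample:
    def test_linear_ramp_exact(self):
        grid = sim.GridLayout(1, 2, 2)
        ramp = np.linspace(0, 1, 1000)
        rec = sim.Recording(np.tile(ramp, (4, 1)),
                            sim.ForceTrace(ramp, 1000.0, "constant"),
                            1000.0, grid)
        out = pp.resample_to(rec, 2000.0)
        assert out.n_samples == 2000
        expect = np.interp(np.arange(2000) / 2000.0, np.arange(1000) / 1000.0, ramp)
        assert np.allclose(out.semg[0], expect)
        # midpoints are neighbour means
        assert np.allclose(out.semg[0][1:-1:2],
                           0.5 * (ramp[:-1] + ramp[1:]))

    def test_identity_and_constant(self, healthy_recording):
        assert pp.resample_to(healthy_recording, FS) is healthy_recording
        grid = sim.GridLayout(1, 2, 2)
        const = np.full(500, 0.7)
        rec = sim.Recording(np.tile(const, (4, 1)),
                            sim.ForceTrace(const, 1000.0, "constant"), 1000.0, grid)
        out = pp.resample_to(rec, 1500.0)
        assert np.allclose(out.semg, 0.7)

    def test_downsampling_rejected(self, healthy_recording):
        with pytest.raises(ValidationError):
            pp.resample_to(healthy_recording, FS / 2)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        t = np.arange(4000) / 2000.0
        x = np.sin(2 * np.pi * 100.0 * t)[None, :]
        y = pp.bandpass_filter(x, 2000.0)
        steady = y[0, 1000:3000]
        assert np.abs(steady).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation(self):
        t = np.arange(4000) / 2000.0
        x = np.sin(2 * np.pi * 2.0 * t)[None, :]
        y = pp.bandpass_filter(x, 2000.0)
        # >= 20 dB down (forward-backward doubles the FIR attenuation)
        assert np.abs(y[0, 1000:3000]).max() < 0.1

    def test_zero_in_zero_out_and_low_fs_rejected(self):
        assert np.allclose(pp.bandpass_filter(np.zeros((3, 500)), FS), 0.0)
        with pytest.raises(ValidationError):
            pp.bandpass_filter(np.zeros((3, 500)), 30.0)


class TestPCASpatialFilter:
    def test_common_mode_suppressed(self):
        rng = np.random.default_rng(0)
        common = rng.standard_normal(2000)
        x = np.tile(common, (8, 1)) + 1e-3 * rng.standard_normal((8, 2000))
        y = pp.pca_spatial_filter(x)
        assert y.mean(axis=0).var() < 0.1 * x.mean(axis=0).var()

    def test_oracle_equivalence_small_matrices(self):
        # independent oracle: eigendecomposition of the channel covariance
        rng = np.random.default_rng(1)
        for _ in range(20):
            c = int(rng.integers(3, 9))
            x = rng.standard_normal((c, 200))
            mean = x.mean(axis=1, keepdims=True)
            xc = x - mean
            evals, evecs = np.linalg.eigh(np.cov(xc, bias=True))
            proj = np.delete(evecs, [0, c - 1], axis=1)
            expected = proj @ proj.T @ xc + mean
            assert np.allclose(pp.pca_spatial_filter(x), expected, atol=1e-8)

    def test_variance_not_increased(self, healthy_recording):
        x = healthy_recording.semg[:, :2000]
        y = pp.pca_spatial_filter(x)
        assert y.var() <= x.var() * (1 + 1e-9)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValidationError):
            pp.pca_spatial_filter(np.zeros((2, 100)))


class TestEnvelope:
    def test_bounds_and_shape(self, healthy_recording):
        env = pp.compute_envelope(healthy_recording.semg, FS)
        assert env.values.shape == healthy_recording.semg.shape
        assert env.values.min() >= 0.0
        assert env.values.max() <= 1.0
        # per-channel normalization: every non-constant channel spans [0, 1]
        assert np.allclose(env.values.min(axis=1), 0.0)
        assert np.allclose(env.values.max(axis=1), 1.0)

    def test_constant_zero_channel_all_zeros(self):
        x = np.zeros((4, 1000))
        x[1:] = np.random.default_rng(0).standard_normal((3, 1000))
        env = pp.compute_envelope(x, FS)
        assert np.array_equal(env.values[0], np.zeros(1000))

    def test_triangular_modulation_recovered(self):
        rng = np.random.default_rng(2)
        n = 6000
        modulator = np.concatenate([np.linspace(0.1, 1, n // 2),
                                    np.linspace(1, 0.1, n - n // 2)])
        carrier = rng.standard_normal(n)
        env = pp.compute_envelope((modulator * carrier)[None, :], FS)
        r = np.corrcoef(env.values[0], modulator)[0, 1]
        assert r > 0.95


class TestNMF:
    def test_rank1_exact_recovery(self):
        w = np.abs(np.random.default_rng(0).standard_normal((6, 1)))
        h = np.abs(np.random.default_rng(1).standard_normal((1, 80)))
        v = w @ h
        dec = pp.nmf_decompose(v, rank=1, seed=0, tol=1e-12, max_iter=2000)
        recon = dec.weights.T @ dec.coefficients
        assert np.linalg.norm(v - recon) < 1e-6

    def test_objective_monotone_nonincreasing(self, healthy_recording):
        env = pp.compute_envelope(healthy_recording.semg[:16, :2000], FS)
        dec = pp.nmf_decompose(env, rank=3, seed=1)
        assert np.all(np.diff(dec.objective) <= 1e-10)
        assert np.all(dec.weights >= 0)
        assert np.all(dec.coefficients >= 0)

    def test_planted_two_mode_recovery(self):
        rng = np.random.default_rng(3)
        c, t = 24, 400
        w_true = np.zeros((2, c))
        w_true[0, :8] = rng.uniform(0.5, 1.0, 8)
        w_true[1, 16:] = rng.uniform(0.5, 1.0, 8)
        h_true = np.vstack([np.abs(np.sin(np.linspace(0, 3, t))),
                            np.abs(np.cos(np.linspace(0, 2, t)))])
        v = w_true.T @ h_true + 0.01 * rng.random((c, t))
        dec = pp.nmf_decompose(v, rank=2, seed=4)
        sims = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                a, b = w_true[i], dec.weights[j]
                sims[i, j] = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        best = max(sims[0, 0] + sims[1, 1], sims[0, 1] + sims[1, 0]) / 2
        assert best > 0.9

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            pp.nmf_decompose(np.array([[1.0, -0.1], [0.2, 0.3]]), rank=1)

    def test_intensity_and_primary_mode_definition(self):
        dec = pp.ActivationDecomposition(
            weights=np.array([[1.0, 0.0], [0.0, 1.0]]),
            coefficients=np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]]),
            objective=np.array([0.0]))
        assert np.allclose(dec.intensity, [3.0, 6.0])
        assert dec.primary_mode == 1


class TestChannelSelection:
    @pytest.mark.parametrize("c", list(range(4, 129, 7)) + [128])
    def test_cardinality_quarter(self, c):
        dec = pp.ActivationDecomposition(
            weights=np.random.default_rng(c).random((1, c)),
            coefficients=np.ones((1, 10)), objective=np.array([0.0]))
        sel = pp.select_optimal_channels(dec)
        assert len(sel.indices) == math.ceil(c / 4)
        assert sel.weights.sum() == pytest.approx(1.0)

    def test_argmax_selected_and_tie_break(self):
        dec = pp.ActivationDecomposition(
            weights=np.array([[4.0, 3.0, 2.0, 1.0]]),
            coefficients=np.ones((1, 5)), objective=np.array([0.0]))
        sel = pp.select_optimal_channels(dec)
        assert list(sel.indices) == [0]
        tie = pp.ActivationDecomposition(
            weights=np.array([[2.0, 2.0, 2.0, 2.0, 2.0]]),
            coefficients=np.ones((1, 5)), objective=np.array([0.0]))
        sel2 = pp.select_optimal_channels(tie)
        assert list(sel2.indices) == [0, 1]  # ceil(5/4)=2, lower indices win

    def test_all_zero_weights_rejected(self):
        dec = pp.ActivationDecomposition(
            weights=np.zeros((1, 8)), coefficients=np.ones((1, 5)),
            objective=np.array([0.0]))
        with pytest.raises(DegenerateDecompositionError):
            pp.select_optimal_channels(dec)

    def test_planted_bump_selection(self, noiseless_recording, fast_pre_cfg):
        _, diag = pp.preprocess_recording(noiseless_recording, fast_pre_cfg)
        sel = diag["selection"]
        center = noiseless_recording.meta["activation_center"]
        grid = noiseless_recording.grid
        coords = grid.global_coords()
        g, r, c = center
        center_xy = np.array([r, g * (grid.cols + grid.gap) + c])
        d = np.sqrt(((coords[sel.indices] - center_xy) ** 2).sum(axis=1))
        assert np.mean(d <= 4.0) >= 0.8


class TestCollapse:
    def test_single_channel_is_renormalized_channel(self):
        env = pp.EnvelopeMatrix(
            values=np.vstack([np.linspace(0, 1, 50), np.zeros(50)]),
            fs=FS, channel_ids=np.arange(2),
            x_min=np.zeros(2), x_max=np.ones(2))
        sel = pp.ChannelSelection(indices=np.array([0]), weights=np.array([1.0]))
        out = pp.collapse_to_envelope(env, sel)
        assert np.allclose(out, env.values[0])

    def test_identical_channels_any_weights(self):
        row = np.abs(np.sin(np.linspace(0, 4, 100)))
        env = pp.EnvelopeMatrix(values=np.vstack([row, row]), fs=FS,
                                channel_ids=np.arange(2),
                                x_min=np.zeros(2), x_max=np.ones(2))
        sel = pp.ChannelSelection(indices=np.array([0, 1]),
                                  weights=np.array([0.3, 0.7]))
        out = pp.collapse_to_envelope(env, sel)
        assert np.allclose(out, pp.minmax_normalize(row[None])[0])

    def test_output_spans_unit_interval(self, healthy_recording, fast_pre_cfg):
        _, diag = pp.preprocess_recording(healthy_recording, fast_pre_cfg)
        assert diag["envelope"].min() == pytest.approx(0.0)
        assert diag["envelope"].max() == pytest.approx(1.0)


class TestForceConditioning:
    def test_spike_suppression(self):
        x = np.zeros(1000)
        x[500] = 1.0
        trace = sim.ForceTrace(x, FS, "constant")
        out = pp.smooth_and_normalize_force(trace)
        win = int(0.05 * FS)
        # smoothing spreads the spike over the window before renormalization
        raw_win = np.convolve(x, np.ones(win) / win, mode="same")
        assert raw_win.max() <= 1.0 / win + 1e-12

    def test_smooth_ramp_preserved(self):
        ramp = np.linspace(0, 1, 2000)
        out = pp.smooth_and_normalize_force(sim.ForceTrace(ramp, FS, "constant"))
        interior = slice(100, -100)
        assert np.allclose(out[interior], ramp[interior], atol=0.01)
        assert out.min() == 0.0 and out.max() == 1.0


class TestSegmentation:
    def test_window_count(self):
        env = np.random.default_rng(0).random(10000)
        force = np.random.default_rng(1).random(10000)
        s = pp.segment_samples(env, force, L=500, step=500)
        assert len(s) == 20
        assert s.window_length == 500

    def test_too_short_gives_empty(self):
        s = pp.segment_samples(np.zeros(499), np.zeros(499), L=500, step=500)
        assert len(s) == 0

    def test_constant_force_targets(self):
        env = np.random.default_rng(0).random(2000)
        s = pp.segment_samples(env, np.full(2000, 0.7), L=500, step=500)
        assert np.allclose(s.targets, 0.7)

    def test_nonoverlapping_when_step_equals_length(self):
        env = np.arange(1500, dtype=float)
        s = pp.segment_samples(env, env, L=500, step=500)
        assert np.array_equal(np.concatenate(list(s.windows)), env)


class TestEndToEnd:
    def test_noiseless_envelope_tracks_monotone_force(self, fast_pre_cfg):
        rng = np.random.default_rng(13)
        prof = sim.make_subject_profile("S1", "HC", rng, sim.CHILD_GRID,
                                        noise_sd=0.0)
        force = sim.generate_force_profile(
            "increasing_plateau", 6.0, FS,
            {"ramp_s": 6.0, "plateau_s": 0.0, "amplitude": 0.6})
        rec = sim.generate_recording(prof, force, seed=14)
        _, diag = pp.preprocess_recording(rec, fast_pre_cfg)
        rho = spearmanr(diag["envelope"], diag["force"]).statistic
        assert rho >= 0.95
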