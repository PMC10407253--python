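"""Generator correctness: the synthetic data must honor its own ground truth."""

import numpy as np
import pandas as pd
import pytest

from temsig import synthetic
from temsig.synthetic import SceneSpec, Preset, gen_traces, gen_ktr_movie


class TestTraces:
    def test_noise_free_responder_follows_closed_form(self):
        preset = Preset(name="x", responder_rate=1.0, amplitude=0.4,
                        rise_tau_frames=2.0, rise_delay_frames=1.0,
                        noise_sd=0.0, baseline_sd=0.0, baseline_cn=1.0)
        cn, truth = gen_traces(1, preset, n_frames=20, stimulus_frame=5, seed=0)
        t = np.arange(20.0)
        dt = t - 6.0  # stimulus + 1 frame delay
        expected = 1.0 + 0.4 * np.where(dt > 0, 1 - np.exp(-dt / 2.0), 0.0)
        np.testing.assert_allclose(cn[0], expected, rtol=1e-12)
        assert truth.responder[0]

    def test_non_responders_stay_at_baseline(self):
        preset = Preset(name="x", responder_rate=0.0, noise_sd=0.0)
        cn, truth = gen_traces(5, preset, seed=3)
        assert not truth.responder.any()
        np.testing.assert_allclose(cn - cn[:, :1], 0.0, atol=1e-12)

    @pytest.mark.parametrize("preset,n,expected", [
        ("control", 200, 10),       # round(0.05 * 200)
        ("neutrophil", 200, 100),   # round(0.50 * 200)
        ("control", 30, 2),         # round(1.5) banker's -> 2
    ])
    def test_responder_count_is_exact_not_binomial(self, preset, n, expected):
        for seed in (0, 1, 2):
            _, truth = gen_traces(n, preset, seed=seed)
            assert truth.responder.sum() == expected

    def test_different_seeds_same_count_different_noise(self):
        cn1, t1 = gen_traces(50, "neutrophil", seed=1)
        cn2, t2 = gen_traces(50, "neutrophil", seed=2)
        assert t1.responder.sum() == t2.responder.sum() == 25
        assert not np.allclose(cn1, cn2)

    def test_determinism(self):
        cn1, _ = gen_traces(20, "control", seed=7)
        cn2, _ = gen_traces(20, "control", seed=7)
        np.testing.assert_array_equal(cn1, cn2)


class TestMovie:
    def test_stimulus_timing_matches_protocol(self):
        # 30 frames at 30 s with stimulus at frame 5 = 2.5 min into 15 min
        spec = SceneSpec(n_frames=30, frame_interval_s=30.0, stimulus_frame=5)
        assert spec.stimulus_time_s == 150.0
        assert spec.n_frames * spec.frame_interval_s == 900.0

    def test_noise_free_cn_identity(self, small_movie):
        """C/N measured on the rendered image equals the analytic trace."""
        spec, nuc, ktr, truth = small_movie
        for i in range(truth.n_cells):
            r0, c0 = truth.centroids[i]
            rr = np.arange(nuc.shape[1])[:, None] - r0
            cc = np.arange(nuc.shape[2])[None, :] - c0
            d2 = rr * rr + cc * cc
            nmask = d2 <= truth.nucleus_radius_px[i] ** 2
            cmask = (d2 <= truth.cell_radius_px[i] ** 2) & ~nmask
            for t in range(spec.n_frames):
                measured = ktr[t][cmask].mean() / ktr[t][nmask].mean()
                assert abs(measured - truth.cn[i, t]) / truth.cn[i, t] <= 1e-6

    def test_total_ktr_signal_conserved_over_time(self, small_movie):
        spec, nuc, ktr, truth = small_movie
        totals = []
        for t in range(spec.n_frames):
            totals.append(float(ktr[t].sum()))
        np.testing.assert_allclose(totals, totals[0], rtol=1e-5)

    def test_nuclear_channel_shows_only_nuclei(self, small_movie):
        spec, nuc, _, truth = small_movie
        inside = np.zeros(nuc.shape[1:], dtype=bool)
        for i in range(truth.n_cells):
            r0, c0 = truth.centroids[i]
            rr = np.arange(nuc.shape[1])[:, None] - r0
            cc = np.arange(nuc.shape[2])[None, :] - c0
            inside |= rr * rr + cc * cc <= truth.nucleus_radius_px[i] ** 2
        assert nuc[0][~inside].max() == 0.0
        assert nuc[0][inside].min() > 0.0

    def test_same_seed_bit_identical(self):
        spec = SceneSpec(field_size_px=(256, 256), n_cells=2, n_frames=3,
                         stimulus_frame=1, seed=5)
        a = gen_ktr_movie(spec, "control")
        b = gen_ktr_movie(spec, "control")
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_overcrowded_placement_raises(self):
        spec = SceneSpec(field_size_px=(128, 128), n_cells=50, n_frames=1,
                         stimulus_frame=0, seed=0)
        with pytest.raises(synthetic.PlacementError, match="non-overlapping"):
            gen_ktr_movie(spec, "control")


class TestWavePoints:
    def test_full_attraction_puts_all_points_within_radius(self):
        w1, w2 = synthetic.gen_wave_points(100, 80, hotspot_attraction=1.0,
                                           attract_radius_um=5.0, seed=3)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(w1).query(w2)
        assert len(w2) == 80
        assert (d <= 5.0 + 1e-9).all()

    def test_zero_attraction_matches_uniform_null_median(self):
        """Monte-Carlo oracle: unattracted wave-2 NN distances behave uniformly."""
        rng = np.random.default_rng(0)
        meds_w2, meds_mc = [], []
        for seed in range(8):
            w1, w2 = synthetic.gen_wave_points(150, 150, hotspot_attraction=0.0,
                                               seed=seed)
            from scipy.spatial import cKDTree
            tree = cKDTree(w1)
            meds_w2.append(np.median(tree.query(w2)[0]))
            mc = rng.uniform([0, 0], [1330, 1330], size=(150, 2))
            meds_mc.append(np.median(tree.query(mc)[0]))
        assert abs(np.mean(meds_w2) - np.mean(meds_mc)) / np.mean(meds_mc) < 0.15

    def test_empty_second_wave(self):
        w1, w2 = synthetic.gen_wave_points(10, 0, hotspot_attraction=0.0, seed=1)
        assert w2.shape == (0, 2)
        assert len(w1) == 10


class TestFilopodiaField:
    def test_zero_density_plants_nothing(self):
        img, truth, _ = synthetic.gen_filopodia_field(density_per_um2=0.0, seed=0)
        assert len(truth) == 0
        assert img.shape == (2500, 2500)

    def test_planted_count_is_round_density_times_area(self):
        _, truth, _ = synthetic.gen_filopodia_field(
            field_um=(200, 200), density_per_um2=0.005, seed=1)
        assert len(truth) == 200

    def test_junction_flags_match_mask(self):
        _, truth, jmask = synthetic.gen_filopodia_field(
            field_um=(100, 100), density_per_um2=0.01,
            junction_spot_fraction=0.25, seed=2)
        rr = truth["row_px"].round().astype(int)
        cc = truth["col_px"].round().astype(int)
        assert truth["on_junction"].sum() == round(0.25 * len(truth))
        assert (jmask[rr, cc] == truth["on_junction"]).all()


class TestRatiometricTraces:
    def test_frap_closed_form(self):
        df = synthetic.gen_ratiometric_traces(
            "frap", {"recovery_fraction": 0.7, "noise_sd": 0.0})
        v, t = df["intensity"].to_numpy(), df["time_s"].to_numpy()
        assert v[t < 15].min() == v[t < 15].max() == 1.0
        i_b = np.argmin(np.abs(t - 15.0))
        norm = 100 * (v - v[i_b]) / (v[0] - v[i_b])
        assert abs(norm[-1] - 70.0) < 1.0  # plateau at recovery fraction

    def test_fret_step(self):
        df = synthetic.gen_ratiometric_traces(
            "fret", {"step_factor": 1.5, "step_frame": 10, "noise_sd": 0.0})
        ratio = df["acceptor"] / df["donor"]
        np.testing.assert_allclose(ratio[:10], 1.0, rtol=1e-12)
        np.testing.assert_allclose(ratio[10:], 1.5, rtol=1e-12)

    def test_crosstalk_forward_model(self):
        bleed = [[1.0, 0.02, 0.0], [0.0, 1.0, 0.05], [0.0, 0.0, 1.0]]
        stacks, truth = synthetic.gen_ratiometric_traces(
            "crosstalk", {"bleed": bleed, "noise_sd": 0.0}, seed=1)
        assert stacks.shape[:2] == (3, 3)
        # channel images are exact scalar multiples of the native channel
        ratio = stacks[0, 1].sum() / stacks[0, 0].sum()
        assert abs(ratio - 0.02) < 1e-10

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError, match="unknown kind"):
            synthetic.gen_ratiometric_traces("nope")
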