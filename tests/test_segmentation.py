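"""Tests of the change-point cost, moves, annealer and post-processing."""

import numpy as np
import pytest

from tugsim import AnnealConfig, ChangePointModel, Track
from tugsim.segmentation import (
    _anneal_core,
    _one_seg_resid,
    _two_seg_resid,
    anneal,
    cost,
    eval_piecewise,
    postprocess,
    propose,
    segment_track,
)
from tugsim.synthetic import TrackBlueprint, make_track


class TestEvalPiecewise:
    def test_knot_interpolation_is_exact(self):
        cp_t = [0.0, 2.0, 5.0]
        cp_x = [0.0, 100.0, -40.0]
        assert eval_piecewise(cp_t, cp_x, 2.0) == 100.0
        assert eval_piecewise(cp_t, cp_x, 5.0) == -40.0

    def test_midpoint_of_two_knots(self):
        assert eval_piecewise([0, 10], [0, 800], 5.0) == pytest.approx(400.0)

    def test_collinear_knots_match_single_line(self, rng):
        t = np.sort(rng.uniform(0, 10, 50))
        cp_t = [0.0, 3.0, 7.0, 10.0]
        cp_x = [5.0 * c + 1.0 for c in cp_t]  # all on x = 5t + 1
        assert np.allclose(eval_piecewise(cp_t, cp_x, t), 5.0 * t + 1.0)

    def test_unordered_knots_rejected(self):
        with pytest.raises(ValueError):
            eval_piecewise([0.0, 2.0, 1.0], [0, 0, 0], 0.5)


class TestCost:
    def test_exact_linear_track_costs_zero(self, make_linear_track):
        tr = make_linear_track(v_nm_s=500.0, duration=10.0)
        h = cost(tr, [tr.t[0], tr.t[-1]], [tr.x[0], tr.x[-1]])
        assert h == pytest.approx(0.0, abs=1e-9)

    def test_interior_knot_on_line_costs_mu(self, make_linear_track):
        tr = make_linear_track(v_nm_s=500.0, duration=10.0)
        h = cost(tr, [0.0, 5.0, 10.0], [0.0, 2500.0, 5000.0])
        assert h == pytest.approx(10_000.0)

    def test_matches_bruteforce_residual(self, rng):
        t = 0.1 * np.arange(80)
        x = rng.normal(0, 50, 80)
        tr = Track("n", t, x)
        cp_t = np.array([t[0], 2.35, 5.0, t[-1]])
        cp_x = np.array([10.0, -60.0, 45.0, 0.0])
        f = np.interp(t, cp_t, cp_x)
        expected = np.sum((x - f) ** 2) + 2 * 10_000.0
        assert cost(tr, cp_t, cp_x) == pytest.approx(expected)


class TestIncrementalResiduals:
    """The windowed residual helpers used for incremental dH equal a full
    recomputation of the residual difference."""

    def _random_instance(self, rng):
        t = 0.1 * np.arange(100)
        x = np.cumsum(rng.normal(0, 30, 100))
        return t, x

    def test_one_segment_window(self, rng):
        t, x = self._random_instance(rng)
        s = _one_seg_resid(t, x, 1.0, 20.0, 4.0, -50.0, False)
        mask = (t >= 1.0) & (t < 4.0)
        line = 20.0 + (-50.0 - 20.0) / 3.0 * (t[mask] - 1.0)
        assert s == pytest.approx(np.sum((x[mask] - line) ** 2))

    def test_two_segment_window_includes_final_point(self, rng):
        t, x = self._random_instance(rng)
        ta, tm, tb = 5.0, 7.3, t[-1]
        xa, xm, xb = 0.0, 80.0, x[-1]
        s = _two_seg_resid(t, x, ta, xa, tm, xm, tb, xb, True)
        f = np.interp(t, [ta, tm, tb], [xa, xm, xb])
        mask = t >= ta
        assert s == pytest.approx(np.sum((x[mask] - f[mask]) ** 2))

    def test_incremental_cost_equals_full_recompute_after_anneal(self, rng):
        """H maintained across thousands of incremental updates agrees with
        an independent full evaluation of the final configuration."""
        bp = TrackBlueprint(
            change_times=(0, 4, 8, 12), segment_velocities=(700.0, 0.0, -600.0)
        )
        for seed in range(5):
            tr, _ = make_track(bp, rng, track_id=f"rp{seed}")
            cp_t, cp_x, h = anneal(tr, seed=seed)
            assert h == pytest.approx(cost(tr, cp_t, cp_x), rel=1e-6)


class TestPropose:
    def _setup(self, make_linear_track):
        tr = make_linear_track(duration=10.0)
        cp_t = np.array([0.0, 5.0, 10.0])
        cp_x = np.array([0.0, 4000.0, 8000.0])
        return tr, cp_t, cp_x

    def test_zero_amplitude_shift_is_identity(self, make_linear_track, rng):
        tr, cp_t, cp_x = self._setup(make_linear_track)
        cfg = AnnealConfig(eps_x=0.0, eps_t=0.0, p_shift=1.0, p_add=0.0, p_remove=0.0)
        move, nt, nx = propose(cp_t, cp_x, tr, cfg, rng)
        assert move == "shift"
        assert np.allclose(nt, cp_t) and np.allclose(nx, cp_x)

    def test_add_then_remove_recovers(self, make_linear_track, rng):
        tr, cp_t, cp_x = self._setup(make_linear_track)
        cfg_add = AnnealConfig(p_shift=0.0, p_add=1.0, p_remove=0.0)
        _, nt, nx = propose(cp_t, cp_x, tr, cfg_add, rng)
        if len(nt) == len(cp_t) + 1:
            new = [i for i, tv in enumerate(nt) if tv not in cp_t][0]
            back_t = np.delete(nt, new)
            back_x = np.delete(nx, new)
            assert np.allclose(back_t, cp_t) and np.allclose(back_x, cp_x)

    def test_move_type_frequencies(self, make_linear_track, rng):
        tr, cp_t, cp_x = self._setup(make_linear_track)
        cfg = AnnealConfig()
        moves = [propose(cp_t, cp_x, tr, cfg, rng)[0] for _ in range(10_000)]
        freq = {m: moves.count(m) / len(moves) for m in ("shift", "add", "remove")}
        assert freq["shift"] == pytest.approx(0.8, abs=0.02)
        assert freq["add"] == pytest.approx(0.1, abs=0.01)
        assert freq["remove"] == pytest.approx(0.1, abs=0.01)

    def test_remove_with_no_interior_is_noop(self, make_linear_track, rng):
        tr = make_linear_track()
        cfg = AnnealConfig(p_shift=0.0, p_add=0.0, p_remove=1.0)
        move, nt, nx = propose([0.0, 10.0], [0.0, 8000.0], tr, cfg, rng)
        assert move == "remove" and len(nt) == 2


class TestAnneal:
    def test_noiseless_single_slope_keeps_no_interior_knots(self, make_linear_track):
        tr = make_linear_track(v_nm_s=600.0, duration=12.0)
        cp_t, cp_x, h = anneal(tr, seed=1)
        assert len(cp_t) == 2
        assert h == pytest.approx(0.0, abs=1e-6)

    def test_two_slope_kink_recovered(self, rng):
        """A noiseless kink worth more than mu is located within 2 samples
        on at least 95% of seeds."""
        bp = TrackBlueprint(
            change_times=(0.0, 5.0, 10.0),
            segment_velocities=(800.0, -800.0),
            noise_sd=0.0,
        )
        tr, _ = make_track(bp, rng)
        hits = 0
        for seed in range(20):
            cp_t, _, _ = anneal(tr, seed=seed)
            interior = cp_t[1:-1]
            if len(interior) >= 1 and np.min(np.abs(interior - 5.0)) <= 0.2:
                hits += 1
        assert hits >= 19

    def test_seeded_determinism(self, rng):
        bp = TrackBlueprint(change_times=(0, 4, 8), segment_velocities=(800.0, 0.0))
        tr, _ = make_track(bp, rng)
        a = anneal(tr, seed=33)
        b = anneal(tr, seed=33)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_annealing_improves_cost(self, rng):
        """Final H <= initial H on >= 95% of seeded runs."""
        cfg = AnnealConfig()
        betas, nupd = cfg.betas()
        wins = 0
        total = 20
        for seed in range(total):
            bp = TrackBlueprint(
                change_times=(0, 3.0 + seed % 3, 8, 13),
                segment_velocities=(900.0, 0.0, -700.0),
            )
            tr, _ = make_track(bp, rng, track_id=f"a{seed}")
            _, _, h, h0 = _anneal_core(
                tr.t, tr.x, cfg.n_init_for(tr.duration), cfg.mu_cost, betas,
                nupd, cfg.eps_x, cfg.eps_t_for(0.1), cfg.p_shift, cfg.p_add,
                seed, cfg.max_cp,
            )
            if h <= h0 + 1e-9:
                wins += 1
        assert wins >= 0.95 * total

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            anneal(Track("tiny", [0.0], [0.0]))


class TestExhaustiveOracle:
    """On small tracks, annealing lands within 5% of the exhaustive optimum
    over configurations with <= 2 interior change points at data points."""

    @staticmethod
    def exhaustive_min(tr, mu=10_000.0):
        n = len(tr)
        best = cost(tr, [tr.t[0], tr.t[-1]], [tr.x[0], tr.x[-1]], mu)
        for i in range(1, n - 1):
            cp_t = [tr.t[0], tr.t[i], tr.t[-1]]
            cp_x = [tr.x[0], tr.x[i], tr.x[-1]]
            best = min(best, cost(tr, cp_t, cp_x, mu))
        for i in range(1, n - 2):
            for j in range(i + 1, n - 1):
                cp_t = [tr.t[0], tr.t[i], tr.t[j], tr.t[-1]]
                cp_x = [tr.x[0], tr.x[i], tr.x[j], tr.x[-1]]
                best = min(best, cost(tr, cp_t, cp_x, mu))
        return best

    def test_anneal_matches_exhaustive(self, rng):
        ok = 0
        total = 20
        for seed in range(total):
            v = (600.0, -700.0) if seed % 2 else (900.0, 50.0)
            bp = TrackBlueprint(
                change_times=(0.0, 1.4, 2.9),
                segment_velocities=v,
                noise_sd=25.0,
            )
            tr, _ = make_track(bp, rng, track_id=f"x{seed}")  # 30 samples
            _, _, h = anneal(tr, seed=seed)
            h_star = self.exhaustive_min(tr)
            if h <= 1.05 * h_star:
                ok += 1
        assert ok >= 0.9 * total


class TestPostprocess:
    def _track_from_xt(self, t, x):
        return Track("pp", np.asarray(t, float), np.asarray(x, float))

    def test_slow_segment_is_pause(self):
        t = 0.1 * np.arange(101)
        tr = self._track_from_xt(t, 50.0 * t)  # +50 nm/s
        segs = postprocess(tr, [t[0], t[-1]])
        assert [s.kind for s in segs] == ["pause"]

    def test_short_fast_segment_becomes_pause(self):
        """+800 nm/s for 0.375 s travels 300 nm < 500 nm: reclassified."""
        t = 0.1 * np.arange(5)
        tr = self._track_from_xt(t, 800.0 * t)
        segs = postprocess(tr, [t[0], t[-1]])
        assert [s.kind for s in segs] == ["pause"]

    def test_long_fast_negative_segment_is_run_neg(self):
        t = 0.1 * np.arange(26)
        tr = self._track_from_xt(t, -800.0 * t)  # -2000 nm over 2.5 s
        segs = postprocess(tr, [t[0], t[-1]])
        assert [s.kind for s in segs] == ["run_neg"]

    def test_segments_tile_the_track(self, rng):
        bp = TrackBlueprint(
            change_times=(0, 4, 8, 12), segment_velocities=(800.0, 0.0, -800.0)
        )
        tr, _ = make_track(bp, rng)
        res = segment_track(tr, seed=2)
        segs = res.segments
        assert segs[0].i_start == 0
        assert segs[-1].i_end == len(tr) - 1
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.i_end == b.i_start  # shared boundary, no gaps/overlaps

    def test_zero_extent_knots_merged_forward(self):
        t = 0.1 * np.arange(61)
        x = np.where(t < 3.0, 800.0 * t, 2400.0 - 800.0 * (t - 3.0))
        tr = self._track_from_xt(t, x)
        # two knots inside the same sampling interval create a one-point segment
        segs = postprocess(tr, [t[0], 3.02, 3.08, t[-1]])
        assert [s.kind for s in segs] == ["run_pos", "run_neg"]

    def test_merge_same_kind_option(self):
        t = 0.1 * np.arange(201)
        tr = self._track_from_xt(t, 800.0 * t)
        segs = postprocess(tr, [t[0], 10.0, t[-1]], merge_same_kind=True)
        assert len(segs) == 1 and segs[0].kind == "run_pos"


class TestModelInterface:
    def test_fit_summary_and_predict(self, rng):
        bp = TrackBlueprint(
            change_times=(0, 5, 10, 15), segment_velocities=(800.0, 0.0, -800.0)
        )
        tr, _ = make_track(bp, rng)
        res = ChangePointModel(tr).fit(seed=3)
        df = res.summary()
        assert list(df.kind) == ["run_pos", "pause", "run_neg"]
        pred = res.predict()
        rms = np.sqrt(np.mean((pred - tr.x) ** 2))
        assert rms < 3 * 20.0  # within a few localization SDs
        assert res.cost == pytest.approx(
            ChangePointModel(tr).cost(res.cp_t, res.cp_x), rel=1e-6
        )
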