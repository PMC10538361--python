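"""Sketch construction: draws, MaxTree, exactness contracts, finalization."""

import dataclasses
import math

import numpy as np
import pytest

from setsketch.core import (
    MODE_FULL,
    MODE_ONE_PERM,
    FinalSketch,
    MaxTree,
    SketchParams,
    UntruncatedSketch,
    densify,
    fast_log,
    fast_log_grid,
    finalize,
    fit_parameters,
    item_draw_sequence,
    merge_sketches,
    update_full,
    update_one_perm,
)
from setsketch.hashing import hash_codes, mix64
from setsketch.sketcher import SketchConfig, finalize_sketches, sketch_codes
from setsketch.synthetic import SyntheticPairSpec, _distinct_codes, gen_set_pair


class TestItemDraws:
    def test_deterministic(self):
        v1, i1 = item_draw_sequence(12345, 64)
        v2, i2 = item_draw_sequence(12345, 64)
        assert np.array_equal(v1, v2) and np.array_equal(i1, i2)

    def test_strictly_increasing_and_permutation(self):
        vals, idxs = item_draw_sequence(999, 128)
        assert np.all(np.diff(vals) > 0)
        assert sorted(idxs.tolist()) == list(range(128))

    @pytest.mark.parametrize("w,expect", [(1.0, 1.0), (2.0, 0.5)])
    def test_first_draw_mean_matches_exponential(self, w, expect):
        # m=1, first draw ~ Exp(m*W); mean over many items approaches 1/(mW)
        hashes = _distinct_codes(100_000, 5, stream=4)
        firsts = np.array(
            [item_draw_sequence(int(h), 1, w, count=1)[0][0] for h in hashes[:20000]]
        )
        assert abs(firsts.mean() - expect) < 4 * expect / math.sqrt(len(firsts))

    def test_matches_full_update_registers(self):
        """Applying the draw sequence by hand reproduces the kernel's sketch."""
        m = 32
        s = UntruncatedSketch(m=m, mode=MODE_FULL)
        h = mix64(4242)
        update_full(s, h)
        vals, idxs = item_draw_sequence(h, m)
        manual = np.full(m, np.inf)
        np.minimum.at(manual, idxs, vals)
        assert np.array_equal(s.registers, manual)

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(ValueError):
            item_draw_sequence(1, 8, 0.0)


class TestMaxTree:
    def test_static_max(self):
        regs = np.array([5.0, 3.0, 7.0, 2.0])
        assert MaxTree(regs).max() == 7.0

    def test_decreasing_update(self):
        regs = np.array([5.0, 3.0, 7.0, 2.0])
        tree = MaxTree(regs)
        assert tree.update(4.0, 2) == 5.0

    def test_matches_linear_scan_on_random_updates(self):
        rng = np.random.default_rng(7)
        regs = np.full(64, np.inf)
        tree = MaxTree(regs)
        for _ in range(500):
            i = int(rng.integers(64))
            v = float(min(regs[i], rng.exponential()))
            assert tree.update(v, i) == regs.max()

    def test_rejects_increase_and_bad_index(self):
        tree = MaxTree(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            tree.update(5.0, 0)
        with pytest.raises(IndexError):
            tree.update(0.5, 9)

    def test_internal_node_count(self):
        assert len(MaxTree(np.full(16, np.inf)).internal_nodes) == 15


class TestUpdateContracts:
    def test_first_item_fills_all_registers(self):
        s = UntruncatedSketch(m=64, mode=MODE_FULL)
        iters = s.add_hashes(np.array([mix64(1)], dtype=np.uint64))
        assert iters[0] == 64  # tree max starts at +inf, loop runs m times
        assert np.all(np.isfinite(s.registers))

    def test_idempotence(self):
        codes = _distinct_codes(500, 1)
        once = sketch_codes(codes, SketchConfig(m=64, full_updates=True))
        twice = sketch_codes(np.concatenate([codes, codes]), SketchConfig(m=64, full_updates=True))
        assert np.array_equal(once.registers, twice.registers)

    def test_order_invariance(self):
        codes = _distinct_codes(500, 2)
        cfg = SketchConfig(m=64, full_updates=True)
        shuffled = np.random.default_rng(0).permutation(codes)
        assert np.array_equal(
            sketch_codes(codes, cfg).registers, sketch_codes(shuffled, cfg).registers
        )

    @pytest.mark.parametrize("full_updates", [True, False])
    def test_mergeability_bitwise(self, full_updates):
        codes = _distinct_codes(3000, 3)
        cfg = SketchConfig(m=128, full_updates=full_updates)
        sa = sketch_codes(codes[:2000], cfg)
        sb = sketch_codes(codes[1500:], cfg)
        merged = merge_sketches(sa, sb)
        assert np.array_equal(merged.registers, sketch_codes(codes, cfg).registers)

    def test_merge_idempotent_commutative(self):
        codes = _distinct_codes(200, 4)
        cfg = SketchConfig(m=32, full_updates=True)
        sa = sketch_codes(codes[:150], cfg)
        sb = sketch_codes(codes[100:], cfg)
        assert np.array_equal(merge_sketches(sa, sa).registers, sa.registers)
        assert np.array_equal(
            merge_sketches(sa, sb).registers, merge_sketches(sb, sa).registers
        )

    def test_merge_shape_mismatch_rejected(self):
        a = UntruncatedSketch(m=32, mode=MODE_FULL)
        b = UntruncatedSketch(m=64, mode=MODE_FULL)
        with pytest.raises(ValueError):
            merge_sketches(a, b)

    def test_guarded_fast_log_bitwise_equals_exact(self):
        codes = _distinct_codes(4000, 5)
        fast = sketch_codes(codes, SketchConfig(m=128, full_updates=True))
        exact = sketch_codes(
            codes, dataclasses.replace(SketchConfig(m=128, full_updates=True), use_fast_log=False)
        )
        assert np.array_equal(fast.registers, exact.registers)

    def test_work_decay_constant_tail(self):
        """Mean inner-loop iterations over the last 10% of a long stream stays
        below 3 once the sketch is saturated (m = 1024)."""
        n = 200_000
        s = UntruncatedSketch(m=1024, mode=MODE_FULL)
        hashes = hash_codes(_distinct_codes(n, 6), 0)
        iters = s.add_hashes(hashes)
        assert iters[-n // 10 :].mean() < 3.0


class TestOnePermutation:
    def test_single_register_touched(self):
        s = UntruncatedSketch(m=64, mode=MODE_ONE_PERM)
        update_one_perm(s, mix64(77))
        assert np.isfinite(s.registers).sum() == 1

    def test_same_item_same_register_across_sketches(self):
        h = mix64(123)
        regs = []
        for _ in range(2):
            s = UntruncatedSketch(m=64, mode=MODE_ONE_PERM)
            update_one_perm(s, h)
            regs.append(int(np.flatnonzero(np.isfinite(s.registers))[0]))
        assert regs[0] == regs[1]

    def test_empty_fraction_matches_balls_in_bins(self):
        m, n = 256, 500
        fracs = [
            np.isinf(
                sketch_codes(_distinct_codes(n, s, stream=8), SketchConfig(m=m)).registers
            ).mean()
            for s in range(30)
        ]
        expect = (1 - 1 / m) ** n
        sem = np.std(fracs) / math.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expect) < 4 * max(sem, 1e-3)

    def test_weighted_one_perm_rejected(self):
        with pytest.raises(ValueError, match="full updates"):
            UntruncatedSketch(m=64, mode=MODE_ONE_PERM, weighted=True)


class TestParameterFit:
    def test_eq_ratio_e(self):
        params = fit_parameters(np.array([1.0, math.e]), q=254)
        assert params.b == pytest.approx(math.exp(1 / 254))
        assert params.a * params.b == pytest.approx(math.e)

    def test_q_one_gives_ratio(self):
        # with a single truncation step, the base is the full pooled ratio
        params = fit_parameters(np.array([2.0, 8.0]), q=1, register_width=0)
        assert params.b == pytest.approx(4.0)

    def test_mismatched_q_rejected(self):
        with pytest.raises(ValueError):
            SketchParams(a=1.0, b=1.01, q=17, register_width=8)

    def test_sentinels_excluded(self):
        params = fit_parameters(np.array([np.inf, 1.0, 4.0]), q=254)
        assert params.a * params.b == pytest.approx(4.0)

    def test_degenerate_pool_clamps_with_warning(self):
        with pytest.warns(RuntimeWarning):
            params = fit_parameters(np.array([2.0, 2.0]), q=254)
        assert params.b == pytest.approx(1 + 1e-9)

    def test_all_sentinel_rejected(self):
        with pytest.raises(ValueError):
            fit_parameters(np.array([np.inf, np.inf]))


class TestFinalize:
    def _sketch_with(self, values):
        s = UntruncatedSketch(m=len(values), mode=MODE_FULL)
        s.registers[:] = values
        return s

    def test_pool_extremes_map_to_0_and_q(self):
        vals = np.array([0.001, 0.5, 2.0, 9.0])
        s = self._sketch_with(vals)
        params = fit_parameters(vals)
        final = finalize(s, params)
        assert final.registers[np.argmax(vals)] == 0
        assert final.registers[np.argmin(vals)] == params.q

    def test_sentinel_maps_to_zero(self):
        s = UntruncatedSketch(m=4, mode=MODE_FULL)
        s.registers[:] = [np.inf, 1.0, 2.0, 4.0]
        final = finalize(s, fit_parameters(s.registers))
        assert final.registers[0] == 0
        assert final.empty_mask is not None and final.empty_mask[0]

    def test_fitted_params_rarely_clamp(self):
        codes = _distinct_codes(20_000, 9)
        cfg = SketchConfig(m=1024, full_updates=True)
        finals, params = finalize_sketches([sketch_codes(codes, cfg)], cfg)
        regs = finals[0].registers
        clamped = np.mean((regs == 0) | (regs == params.q + 1))
        assert clamped < 0.01

    def test_finalized_merge_is_elementwise_max(self, finalized_pair):
        a, b, _ = finalized_pair
        merged = merge_sketches(a, b)
        assert np.array_equal(merged.registers, np.maximum(a.registers, b.registers))


class TestDensify:
    def _pair(self, seed):
        cfg = SketchConfig(m=256)
        a, b, truth = gen_set_pair(SyntheticPairSpec(n_a=300, n_b=300, overlap=150, seed=seed))
        finals, _ = finalize_sketches(
            [sketch_codes(a, cfg), sketch_codes(b, cfg)], cfg
        )
        return finals

    def test_no_empty_registers_after(self):
        for f in self._pair(0):
            assert f.densified and (f.empty_mask is None)

    def test_identical_inputs_densify_identically(self):
        f1 = self._pair(3)
        f2 = self._pair(3)
        assert np.array_equal(f1[0].registers, f2[0].registers)

    def test_full_sketch_returned_unchanged(self, finalized_pair):
        a, _, _ = finalized_pair
        assert densify(a) is a

    def test_all_empty_rejected(self):
        s = UntruncatedSketch(m=8, mode=MODE_ONE_PERM)
        s.registers[0] = 1.0
        final = finalize(s, fit_parameters(np.array([0.5, 1.0, 2.0])))
        final.registers[:] = 0
        final = dataclasses.replace(final, empty_mask=np.ones(8, dtype=bool))
        with pytest.raises(ValueError):
            densify(final)


class TestFastLog:
    def test_ratio_bound_on_grid(self):
        xs = np.exp(np.linspace(np.log(1 + 1e-6), np.log(1e30), 500_001))
        ratio = fast_log_grid(xs) / np.log(xs)
        assert 0 < ratio.min() and ratio.max() <= 1.42

    def test_overestimation_guard_bound_below_one(self):
        us = np.exp(np.linspace(np.log(1e-300), np.log(1 - 1e-12), 500_001))
        ratio = fast_log_grid(us) / np.log(us)
        assert ratio.max() <= 1.42 and ratio.min() >= 1.0

    def test_monotone(self):
        xs = np.exp(np.linspace(np.log(1e-10), np.log(1e10), 200_001))
        assert np.all(np.diff(fast_log_grid(xs)) >= 0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fast_log(0.0)
        with pytest.raises(ValueError):
            fast_log(-1.0)
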