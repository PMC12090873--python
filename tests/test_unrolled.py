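"""Iterative unrolling: targets, caching, and the staggered schedule."""

import json
from collections import Counter

import numpy as np
import pytest

from ringseg.config import RunConfig
from ringseg.experiments import tiny_config
from ringseg.polar import BoundaryPolyline, build_polar_grid
from ringseg.semantic import SegNet
from ringseg.synthetic import (
    SyntheticSpec,
    generate_sample,
    ground_truth_boundaries,
    pith_boundary,
)
from ringseg.unrolled import (
    UnrollRecord,
    UnrollState,
    build_records,
    naive_schedule,
    precompute_semantic,
    radial_targets,
    unrolled_schedule,
)


class TestRadialTargets:
    def test_concentric_constant_gap(self, concentric_sample):
        """Boundary on ring k's outer edge, next edge at gap g, step s
        -> d = g/s for every column."""
        _, mask = concentric_sample
        pb = pith_boundary(mask, 360)
        gtb = ground_truth_boundaries(mask, 360, center=pb.center)
        boundary = gtb[0].to_ds(4)          # ring-1 outer edge, ds coords
        p, n = 7.5, 48                      # window of 30 full px
        grid, res = build_polar_grid(boundary, p, n, 128)
        d, valid = radial_targets(res, mask, grid, p, factor=4)
        assert valid.mean() > 0.95
        step_full = (p / n) * 4
        gap_rows = 20.0 / step_full         # rings are 20 full px wide
        assert np.abs(d[valid] - gap_rows).max() <= 1.5

    def test_outermost_ring_absent(self, concentric_sample):
        _, mask = concentric_sample
        pb = pith_boundary(mask, 360)
        gtb = ground_truth_boundaries(mask, 360, center=pb.center)
        boundary = gtb[-1].to_ds(4)
        grid, res = build_polar_grid(boundary, 8.0, 32, 64)
        assert radial_targets(res, mask, grid, 8.0, factor=4) is None

    def test_wedge_columns_target_following_boundary(self):
        """Where the next ring pinches to zero width the target distance
        drops to (near) zero - the next crossing is the coinciding edge."""
        spec = SyntheticSpec(seed=11, n_rings=4, wedging_prob=1.0,
                             mean_ring_width=18.0)
        _, mask = generate_sample(spec)
        pb = pith_boundary(mask, 360)
        gtb = ground_truth_boundaries(mask, 360, center=pb.center)
        found = False
        for k in range(1, mask.n_rings):
            gap = gtb[k].radii - gtb[k - 1].radii
            if (gap <= 0.75).any() and (gap > 4).any():
                boundary = gtb[k - 1].to_ds(4)
                p, n = 9.0, 48
                grid, res = build_polar_grid(boundary, p, n, 180)
                out = radial_targets(res, mask, grid, p, factor=4)
                assert out is not None
                d, valid = out
                gap_res = np.interp(res.angles, gtb[k].angles,
                                    gap, period=2 * np.pi)
                wedge_cols = valid & (gap_res < 0.5)
                wide_cols = valid & (gap_res > 4)
                if wedge_cols.sum() >= 3 and wide_cols.sum() >= 3:
                    step_full = (p / n) * 4
                    assert np.median(d[wedge_cols]) * step_full <= 2.0
                    assert np.median(d[wide_cols]) * step_full >= 3.0
                    found = True
        assert found


class TestSemanticCache:
    def test_warm_cache_skips_forwards(self, tmp_path, simple_sample):
        image, mask = simple_sample
        model = SegNet(base=4, rng=np.random.default_rng(0))
        cfg = tiny_config()
        samples = [("s0", image, mask)]
        c1 = precompute_semantic(samples, model, tmp_path, cfg)

        calls = []
        original = SegNet.__call__

        def spy(self, x):
            calls.append(1)
            return original(self, x)

        SegNet.__call__ = spy
        try:
            c2 = precompute_semantic(samples, model, tmp_path, cfg)
        finally:
            SegNet.__call__ = original
        assert calls == []  # warm cache: zero model forwards
        assert np.allclose(c1["s0"].boundary_logit, c2["s0"].boundary_logit,
                           atol=1e-6)

    def test_corrupted_entry_recomputed(self, tmp_path, simple_sample):
        image, mask = simple_sample
        model = SegNet(base=4, rng=np.random.default_rng(0))
        cfg = tiny_config()
        samples = [("s0", image, mask)]
        precompute_semantic(samples, model, tmp_path, cfg)
        (tmp_path / "s0.npz").write_bytes(b"garbage")
        c = precompute_semantic(samples, model, tmp_path, cfg)
        assert c["s0"].image_ds.shape[0] == 3

    def test_model_change_invalidates(self, tmp_path, simple_sample):
        image, mask = simple_sample
        cfg = tiny_config()
        samples = [("s0", image, mask)]
        m1 = SegNet(base=4, rng=np.random.default_rng(0))
        m2 = SegNet(base=4, rng=np.random.default_rng(9))
        c1 = precompute_semantic(samples, m1, tmp_path, cfg)
        c2 = precompute_semantic(samples, m2, tmp_path, cfg)
        assert not np.allclose(c1["s0"].boundary_logit,
                               c2["s0"].boundary_logit)


class TestSchedule:
    def test_multiset_equivalence_over_3k_epochs(self):
        """Criterion: over 3K epochs with K=3, iterative unrolling
        processes exactly the naive inner-loop multiset of
        (sample, ring, step) triples."""
        k = 3
        sample_rings = {"a": 4, "b": 6, "c": 3}
        records = build_records(sample_rings, k)
        unrolled = Counter(unrolled_schedule(records, k, epochs=3 * k))
        naive = Counter(naive_schedule(sample_rings, k, epochs=3 * k))
        assert unrolled == naive

    def test_each_record_cycles_steps(self):
        k = 3
        rec = UnrollRecord("a", 1, duplicate=2)
        steps = [rec.step(e, k) for e in range(9)]
        assert Counter(steps) == {0: 3, 1: 3, 2: 3}
        assert steps[2] == 0  # resets at its staggered start epoch

    def test_duplicates_occupy_distinct_steps_each_epoch(self):
        k = 3
        records = build_records({"a": 1}, k)
        for epoch in range(6):
            steps = {rec.step(epoch, k) for rec in records}
            assert steps == {0, 1, 2}

    def test_no_record_reads_its_own_epoch_file(self, tmp_path):
        """Boundary files are keyed by epoch parity: a record at epoch e
        reads generation e-1 and writes generation e."""
        gt = BoundaryPolyline(np.array([10.0, 10.0]), np.full(16, 3.0))
        state = UnrollState([UnrollRecord("a", 0, 0)], {("a", 0): gt},
                            tmp_path, k=3)
        rec = state.records[0]
        written = BoundaryPolyline(np.array([10.0, 10.0]), np.full(16, 5.0))
        state.save_boundary(rec, epoch=1, boundary=written)
        # epoch 1 (its own epoch) still resolves the *previous* generation,
        # which is absent -> ground-truth start, never the epoch-1 file
        b = state.boundary_for(rec, epoch=1)
        assert np.allclose(b.radii, 3.0)
        # epoch 2 reads what epoch 1 wrote
        b2 = state.boundary_for(rec, epoch=2)
        assert np.allclose(b2.radii, 5.0)

    def test_missing_file_resets_to_start(self, tmp_path):
        gt = BoundaryPolyline(np.array([10.0, 10.0]), np.full(16, 3.0))
        state = UnrollState([UnrollRecord("a", 0, 0)], {("a", 0): gt},
                            tmp_path, k=3)
        b = state.boundary_for(state.records[0], epoch=2)
        assert np.allclose(b.radii, 3.0)

    def test_outermost_start_excluded_from_records(self):
        records = build_records({"a": 5}, 3)
        rings = {r.ring for r in records}
        assert rings == {0, 1, 2, 3, 4}
        assert len(records) == 5 * 3
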