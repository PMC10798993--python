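"""Entropy scoring, pool bookkeeping, and the iterative loop."""

import numpy as np
import pytest

import lufor.active_learning as al
from lufor.active_learning import (
    ALConfig,
    image_uncertainty,
    pixel_entropy,
    run_al_loop,
    select_for_annotation,
    simulated_annotator,
    split_pools,
)
from lufor.model import ModelConfig, TrainConfig


class TestSplitPools:
    def test_published_counts(self):
        train_ids, test_ids = split_pools(895, 0.8, seed=0)
        assert len(train_ids) == 716 and len(test_ids) == 179

    def test_small_and_floor_cases(self):
        a, b = split_pools(10, 0.5, seed=1)
        assert len(a) == 5 and len(b) == 5
        a, b = split_pools(100, 0.38, seed=1)
        assert len(a) == 38 and len(b) == 62

    def test_disjoint_and_seeded(self):
        a1, b1 = split_pools(50, 0.8, seed=9)
        a2, b2 = split_pools(50, 0.8, seed=9)
        assert set(a1) & set(b1) == set()
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            split_pools(1, 0.8)
        with pytest.raises(ValueError):
            split_pools(10, 1.0)


class TestEntropy:
    def test_one_hot_is_zero(self):
        p = np.zeros((2, 2, 4))
        p[..., 1] = 1.0
        assert (pixel_entropy(p) == 0).all()

    def test_uniform_is_log_k(self):
        for k in (2, 15):
            p = np.full((3, 3, k), 1 / k)
            assert np.allclose(pixel_entropy(p), np.log(k))

    def test_half_half_is_ln2(self):
        p = np.array([[[0.5, 0.5]]])
        assert pixel_entropy(p)[0, 0] == pytest.approx(np.log(2))

    def test_bounds(self, rng):
        p = rng.dirichlet(np.ones(15), size=(8, 8))
        h = pixel_entropy(p)
        assert (h >= 0).all() and (h <= np.log(15) + 1e-12).all()

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError):
            pixel_entropy(np.full((2, 2, 3), 0.5))


class TestImageUncertainty:
    def test_extremes(self):
        k = 15
        zero = np.zeros((4, 4))
        full = np.full((4, 4), np.log(k))
        for agg in ("mean", "max", "fraction_above"):
            assert image_uncertainty(zero, k, agg) == 0.0
        assert image_uncertainty(full, k, "mean") == pytest.approx(1.0)
        assert image_uncertainty(full, k, "mean", "nats") == pytest.approx(np.log(k))

    def test_half_half_mean(self):
        k = 15
        h = np.zeros((2, 4))
        h[0] = np.log(k)
        assert image_uncertainty(h, k, "mean") == pytest.approx(0.5)

    def test_mask_restriction(self):
        k = 4
        h = np.zeros((2, 2))
        h[0, 0] = np.log(k)
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        assert image_uncertainty(h, k, "mean", mask=mask) == pytest.approx(1.0)
        assert image_uncertainty(h, k, "mean", mask=~mask) == 0.0

    def test_unknown_aggregation(self):
        with pytest.raises(ValueError):
            image_uncertainty(np.zeros((2, 2)), 3, "median")


class TestSelection:
    def test_threshold_semantics_strict_inequality(self, tiny_pools, monkeypatch):
        ids = sorted(tiny_pools.unannotated)
        cycle = [0.70, 0.50, 0.61, 0.60]  # 0.60 itself must NOT be selected
        scores = {sid: cycle[i % len(cycle)] for i, sid in enumerate(ids)}
        monkeypatch.setattr(al, "_scene_score", lambda m, rec, c: scores[rec.scene_id])
        cfg = ALConfig(entropy_threshold=0.6)
        sel = select_for_annotation(tiny_pools, model=None, al_config=cfg)
        expected = [sid for sid, s in scores.items() if s > 0.6]
        assert sorted(sel) == sorted(expected)
        assert all(scores[sid] > 0.6 for sid in sel)

    def test_uniform_model_selects_everything(self, tiny_pools, monkeypatch):
        monkeypatch.setattr(al, "_scene_score", lambda m, rec, c: 1.0)
        sel = select_for_annotation(tiny_pools, None, ALConfig(entropy_threshold=0.99))
        assert sorted(sel) == sorted(tiny_pools.unannotated)

    def test_confident_model_selects_nothing(self, tiny_pools, monkeypatch):
        monkeypatch.setattr(al, "_scene_score", lambda m, rec, c: 0.0)
        assert select_for_annotation(tiny_pools, None, ALConfig()) == []


class TestAnnotator:
    def test_move_and_conservation(self, tiny_pools):
        import copy

        pools = copy.deepcopy(tiny_pools)
        before = pools.sizes()
        sid = sorted(pools.unannotated)[0]
        simulated_annotator([sid], pools, cycle=1)
        after = pools.sizes()
        assert after[0] == before[0] + 1 and after[1] == before[1] - 1
        assert after[2] == before[2]
        assert pools.cycle_of_annotation[sid] == 1
        # revealed labels are the clean truth
        assert np.array_equal(pools.annotated[sid].labels,
                              pools.annotated[sid].scene.truth_mask)

    def test_empty_selection_noop(self, tiny_pools):
        import copy

        pools = copy.deepcopy(tiny_pools)
        simulated_annotator([], pools)
        assert pools.sizes() == tiny_pools.sizes()

    def test_unknown_id_rejected(self, tiny_pools):
        import copy

        with pytest.raises(KeyError):
            simulated_annotator(["nope"], copy.deepcopy(tiny_pools))


class TestLoop:
    @pytest.fixture(scope="class")
    def loop_reports(self, tiny_pools):
        import copy

        pools = copy.deepcopy(tiny_pools)
        mc = ModelConfig(depth=2, base_filters=4, seed=0)
        tc = TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3,
                         patch_size=32, seed=0)
        return run_al_loop(pools, mc, tc, ALConfig(n_cycles=2, seed=0))

    def test_report_count_and_fixed_test_set(self, loop_reports, tiny_pools):
        assert len(loop_reports) == 3
        assert all(r.pool_sizes[2] == len(tiny_pools.test) for r in loop_reports)

    def test_pool_monotonicity(self, loop_reports):
        ann = [r.pool_sizes[0] for r in loop_reports]
        una = [r.pool_sizes[1] for r in loop_reports]
        assert ann == sorted(ann)
        assert una == sorted(una, reverse=True)
        totals = [r.pool_sizes[0] + r.pool_sizes[1] for r in loop_reports]
        assert len(set(totals)) == 1

    def test_zero_cycles_single_report(self, tiny_pools):
        import copy

        pools = copy.deepcopy(tiny_pools)
        mc = ModelConfig(depth=2, base_filters=4, seed=1)
        tc = TrainConfig(epochs=1, batch_size=4, learning_rate=1e-3,
                         patch_size=32, seed=1)
        reports = run_al_loop(pools, mc, tc, ALConfig(n_cycles=0, seed=1))
        assert len(reports) == 1 and reports[0].selected_ids == []
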