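"""Selection-rule fidelity: strict confidence flagging, the
more-than-half group consensus, determinism, and loop guards."""

import numpy as np
import pytest

from patchrefine.dral import (
    DRALConfig,
    consensus_removal,
    dral_iteration,
    flag_low_confidence,
    noise_detection_metrics,
    record_uid,
)
from patchrefine.training import TrainConfig


class TestFlagging:
    def test_max_below_threshold_is_flagged(self):
        flags = flag_low_confidence(np.array([[0.40, 0.30, 0.20, 0.10]]), 0.5)
        assert flags.tolist() == [True]

    def test_boundary_is_strict(self):
        flags = flag_low_confidence(np.array([[0.50, 0.30, 0.10, 0.10]]), 0.5)
        assert flags.tolist() == [False]

    def test_two_class_never_flags_at_default_threshold(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet((1, 1), size=50)
        with pytest.warns(UserWarning, match="always >= 0.5"):
            flags = flag_low_confidence(p, 0.5)
        assert not flags.any()

    def test_malformed_probabilities_rejected(self):
        with pytest.raises(ValueError):
            flag_low_confidence(np.array([[0.5, 0.6]]), 0.5)
        with pytest.raises(ValueError):
            flag_low_confidence(np.array([[1.2, -0.2]]), 0.5)


class TestConsensus:
    def _run(self, n_flagged, group_size=8):
        flags = [True] * n_flagged + [False] * (group_size - n_flagged)
        gids = ["g"] * group_size
        return consensus_removal(flags, gids, group_size)

    def test_five_of_eight_removes_whole_group(self):
        assert self._run(5).sum() == 8

    def test_exactly_four_of_eight_removes_only_flagged(self):
        removed = self._run(4)
        assert removed.tolist() == [True] * 4 + [False] * 4

    def test_none_flagged_removes_nothing(self):
        assert self._run(0).sum() == 0

    def test_generalizes_to_groups_of_four(self):
        assert self._run(3, group_size=4).sum() == 4
        assert self._run(2, group_size=4).sum() == 2

    def test_incomplete_group_rejected(self):
        with pytest.raises(ValueError, match="members"):
            consensus_removal([True] * 7, ["g"] * 7, 8)

    def test_partial_groups_use_nominal_size_when_allowed(self):
        """A group thinned by an earlier round still votes against the
        nominal size: 5 of 6 survivors flagged (> 4) removes all 6, while
        4 flagged removes only the flagged ones."""
        removed = consensus_removal(
            [True] * 5 + [False], ["g"] * 6, 8, require_complete=False
        )
        assert removed.all()
        removed = consensus_removal(
            [True] * 4 + [False] * 2, ["g"] * 6, 8, require_complete=False
        )
        assert removed.tolist() == [True] * 4 + [False] * 2

    def test_mixed_groups_handled_independently(self):
        flags = [True] * 5 + [False] * 3 + [True] + [False] * 7
        gids = ["a"] * 8 + ["b"] * 8
        removed = consensus_removal(flags, gids, 8)
        assert removed[:8].all()  # group a: majority -> all removed
        assert removed[8:].sum() == 1  # group b: only the flagged one

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet((1,) * 4, size=64)
        gids = np.repeat([f"g{i}" for i in range(8)], 8)
        a = consensus_removal(flag_low_confidence(p, 0.5), gids, 8)
        b = consensus_removal(flag_low_confidence(p, 0.5), gids, 8)
        np.testing.assert_array_equal(a, b)

    def test_consensus_never_unremoves_flagged_members(self):
        rng = np.random.default_rng(2)
        flags = rng.random(80) < 0.4
        gids = np.repeat([f"g{i}" for i in range(10)], 8)
        removed = consensus_removal(flags, gids, 8)
        assert (removed | ~flags).all()  # flagged implies removed


class _StubNet:
    """Fixed-probability confidence model for exercising the loop plumbing."""

    def __init__(self, probs):
        self._p = np.asarray(probs, dtype=np.float32)
        self.n_classes = self._p.shape[-1]

    def predict_proba(self, X, batch_size=64):
        return np.tile(self._p, (X.shape[0], 1))

    def train_step(self, X, y, lr, momentum=0.9, weight_decay=0.0):
        return 0.0


class TestIteration:
    def test_confident_model_removes_nothing(self, tiny_pool):
        net = _StubNet([0.9, 0.05, 0.03, 0.02])
        val = (np.zeros((8, 3, 32, 32), dtype=np.float32), np.zeros(8, dtype=int))
        reduced, _, row, removed = dral_iteration(
            net, tiny_pool, val, DRALConfig(), TrainConfig(max_epochs=1, steps_per_epoch=1),
            input_side=32,
        )
        assert len(reduced) == len(tiny_pool)
        assert row["n_removed"] == 0 and removed == set()

    def test_uniform_model_aborts_before_emptying_pool(self, tiny_pool):
        net = _StubNet([0.25, 0.25, 0.25, 0.25])
        val = (np.zeros((8, 3, 32, 32), dtype=np.float32), np.zeros(8, dtype=int))
        with pytest.raises(RuntimeError, match="empty"):
            dral_iteration(
                net, tiny_pool, val, DRALConfig(),
                TrainConfig(max_epochs=1, steps_per_epoch=1), input_side=32,
            )

    def test_monotone_shrinkage(self, tiny_pool):
        """Each removal leaves a (weak) subset; sizes never increase."""
        rng = np.random.default_rng(3)

        class Jitter(_StubNet):
            def predict_proba(self, X, batch_size=64):
                # mostly confident, occasionally uncertain
                n = X.shape[0]
                p = np.full((n, 4), 0.02, dtype=np.float64)
                top = rng.random(n)
                conf = np.where(rng.random(n) < 0.1, 0.30, 0.94)
                p[np.arange(n), 0] = conf
                p /= p.sum(axis=1, keepdims=True)
                return p

        net = Jitter(np.zeros(4))
        val = (np.zeros((8, 3, 32, 32), dtype=np.float32), np.zeros(8, dtype=int))
        sizes = [len(tiny_pool)]
        pool = tiny_pool
        for _ in range(3):
            pool, _, row, _ = dral_iteration(
                net, pool, val, DRALConfig(),
                TrainConfig(max_epochs=1, steps_per_epoch=1), input_side=32,
            )
            sizes.append(len(pool))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestConfigAndMetrics:
    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            DRALConfig(max_iterations=0)

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            DRALConfig(confidence_threshold=0.0)

    def test_perfect_removal(self):
        assert noise_detection_metrics({"a", "b"}, {"a", "b"}, 10) == (1.0, 1.0, 1.0)

    def test_empty_removal_has_zero_recall(self):
        p, r, f = noise_detection_metrics(set(), {"a"}, 10)
        assert (p, r, f) == (0.0, 0.0, 0.0)

    def test_partial_overlap(self):
        p, r, f = noise_detection_metrics({"a", "b", "c"}, {"b", "c", "d"}, 10)
        assert p == pytest.approx(2 / 3)
        assert r == pytest.approx(2 / 3)
        assert f == pytest.approx(2 / 3)

    def test_record_uid_distinguishes_orientations(self, tiny_pool):
        uids = {record_uid(r) for r in tiny_pool.records}
        assert len(uids) == len(tiny_pool)
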