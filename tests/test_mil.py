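"""MIL primitives: bag rule, representative selection, pseudo-labels,
EMA teacher, the combined loss, the LR schedule, and the training loop."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from milts.errors import MiltsError, MiltsInputError
from milts.mil import (Bag, TeacherStudentMIL, TeacherStudentState,
                       assign_pseudo_labels, bag_label_oracle, cosine_lr,
                       ema_update, milts_loss, select_representatives)


class TestBagLabelOracle:
    @pytest.mark.parametrize("labels,expected", [
        ([0, 0, 0], 0), ([0, 1, 0], 1), ([], 0), ([1], 1)])
    def test_positive_iff_any_positive_instance(self, labels, expected):
        assert bag_label_oracle(labels) == expected

    def test_non_binary_rejected(self):
        with pytest.raises(MiltsInputError):
            bag_label_oracle([0, 2, 1])


class TestSelectRepresentatives:
    def test_positive_bag_takes_max(self):
        assert select_representatives([0.1, 0.9, 0.5], 1, 1).tolist() == [1]

    def test_negative_bag_takes_min(self):
        assert select_representatives([0.1, 0.9, 0.5], 0, 2).tolist() == [0, 2]

    def test_ties_break_to_lowest_index(self):
        assert select_representatives([0.5, 0.5, 0.5], 1, 1).tolist() == [0]

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
           st.integers(0, 1), st.data())
    def test_agrees_with_full_sort_oracle(self, scores, label, data):
        M = data.draw(st.integers(1, len(scores)))
        got = select_representatives(scores, label, M).tolist()
        order = sorted(range(len(scores)),
                       key=lambda i: (-scores[i], i) if label else (scores[i], i))
        assert got == sorted(order[:M])

    def test_max_and_min_selection_partition_distinct_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(20) / 20.0
        top = select_representatives(scores, 1, 7)
        bottom = select_representatives(scores, 0, 13)
        assert sorted(np.concatenate([top, bottom]).tolist()) == list(range(20))

    def test_invalid_inputs(self):
        with pytest.raises(MiltsInputError):
            select_representatives([0.1, 0.2], 1, 3)
        with pytest.raises(MiltsInputError):
            select_representatives([0.1, float("nan")], 1, 1)


class TestAssignPseudoLabels:
    def test_proportion_0p35_of_100_labels_35(self):
        bag = Bag("s", list(range(100)), label=1)
        scores = np.linspace(0, 1, 100)
        ps = assign_pseudo_labels(bag, scores, 0.35)
        assert ps.M == 35
        assert len(ps.unlabeled_indices) == 65

    def test_partition_covers_all_indices_disjointly(self):
        bag = Bag("s", list(range(17)), label=0)
        ps = assign_pseudo_labels(bag, np.random.default_rng(0).random(17), 0.4)
        union = np.concatenate([ps.labeled_indices, ps.unlabeled_indices])
        assert sorted(union.tolist()) == list(range(17))

    def test_pseudo_label_equals_bag_label(self):
        bag = Bag("s", list(range(6)), label=1)
        ps = assign_pseudo_labels(bag, np.arange(6) / 6, 0.5)
        assert ps.label == 1

    def test_at_least_one_instance_labeled(self):
        bag = Bag("s", list(range(4)), label=0)
        assert assign_pseudo_labels(bag, [0.1, 0.2, 0.3, 0.4], 0.01).M == 1

    def test_empty_bag_rejected(self):
        with pytest.raises(MiltsInputError):
            assign_pseudo_labels(Bag("s", [], label=1), [], 0.35)


class TestEmaUpdate:
    def make_state(self, s, t, alpha):
        return TeacherStudentState(student={"w": np.array([s])},
                                   teacher={"w": np.array([t])},
                                   ema_decay=alpha)

    def test_alpha_one_keeps_teacher(self):
        st_ = ema_update(self.make_state(1.0, 0.0, 1.0))
        assert st_.teacher["w"][0] == 0.0

    def test_alpha_zero_copies_student(self):
        st_ = ema_update(self.make_state(1.0, 0.0, 0.0))
        assert st_.teacher["w"][0] == 1.0

    def test_decay_0p99_moves_one_percent(self):
        st_ = ema_update(self.make_state(1.0, 0.0, 0.99))
        assert st_.teacher["w"][0] == pytest.approx(0.01)
        assert st_.global_step == 1

    def test_shape_mismatch_rejected(self):
        state = TeacherStudentState(student={"w": np.zeros(3)},
                                    teacher={"w": np.zeros(2)})
        with pytest.raises(MiltsInputError):
            ema_update(state)


class TestMiltsLoss:
    def test_hand_computed_example(self):
        loss = milts_loss([0.5], [1], (1.0, 1.0), [0.6], [0.8], 100.0)
        assert loss == pytest.approx(-math.log(0.5) + 100 * 0.2**2, rel=1e-6)
        assert loss == pytest.approx(4.6931, abs=1e-4)

    def test_identical_teacher_student_kills_consistency(self):
        u = [0.3, 0.7, 0.5]
        base = milts_loss([0.9], [1], (1, 1), u, u, 0.0)
        assert milts_loss([0.9], [1], (1, 1), u, u, 1e6) == pytest.approx(base)

    def test_perfect_predictions_drive_loss_to_zero(self):
        loss = milts_loss([1.0, 0.0], [1, 0], (1, 1), [], [], 0.0)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_negative_lambda_and_length_mismatch_rejected(self):
        with pytest.raises(MiltsInputError):
            milts_loss([0.5], [1], (1, 1), [], [], -1.0)
        with pytest.raises(MiltsInputError):
            milts_loss([0.5], [1, 0], (1, 1), [], [], 1.0)

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=10),
           st.lists(st.floats(0.01, 0.99), min_size=1, max_size=10),
           st.floats(0, 1000))
    def test_loss_is_non_negative(self, probs, unl, lam):
        y = [1] * len(probs)
        loss = milts_loss(probs, y, (0.5, 1.5), unl, unl[::-1], lam)
        assert loss >= 0


class TestCosineLr:
    def test_starts_at_base_lr(self):
        assert cosine_lr(0, 1e-2, 1e-4, 100) == pytest.approx(1e-2)

    def test_trough_hits_min_lr_then_restarts(self):
        assert cosine_lr(99, 1e-2, 1e-4, 100) == pytest.approx(1e-4)
        assert cosine_lr(100, 1e-2, 1e-4, 100) == pytest.approx(1e-2)

    def test_half_phase_is_midpoint(self):
        # t = 0.5 halfway through a cycle
        cycle = 101
        assert cosine_lr(50, 1e-2, 1e-4, cycle) == pytest.approx(5.05e-3)


def tiny_bags(seed=0, n_bags=4, n_tiles=6):
    """Bags of random 32x32 patches; positive bags get a dark quadrant."""
    rng = np.random.default_rng(seed)
    bags = []
    for b in range(n_bags):
        label = b % 2
        tiles = []
        for i in range(n_tiles):
            patch = (rng.random((32, 32, 3)) * 80 + 150).astype(np.uint8)
            if label and i < 2:     # witness instances
                patch[8:24, 8:24] = 30
            tiles.append(patch)
        bags.append(Bag(f"b{b}", tiles, label))
    return bags


class TestTrainingLoop:
    def test_teacher_equals_ema_replay_of_student_trajectory(self):
        bags = tiny_bags()
        model = TeacherStudentMIL(epochs=1, batch_size=8, seed=1,
                                  encoder_widths=(4, 8), encoder_side=32,
                                  record_trajectory=True)
        model.fit(bags)
        replay = {k: v.copy() for k, v in model.trajectory_[0][1].items()}
        n_total = sum(len(b) for b in bags)
        spe = -(-n_total // model.batch_size)
        cap = min(model.ema_decay, 1.0 - 1.0 / spe)  # one-epoch horizon cap
        for step, (kind, state) in enumerate(model.trajectory_[1:]):
            assert kind == "step"
            # warm-up EMA schedule: decay grows toward the capped value
            a = min(cap, 1.0 - 1.0 / (step + 1))
            for k in replay:
                replay[k] = a * replay[k] + (1 - a) * state[k]
        final = model.teacher_.get_state()
        for k in replay:
            np.testing.assert_allclose(replay[k], final[k], rtol=1e-5,
                                       atol=1e-7)

    def test_same_seed_runs_are_bit_identical(self):
        kwargs = dict(epochs=2, batch_size=8, seed=3,
                      encoder_widths=(4, 8), encoder_side=32)
        a = TeacherStudentMIL(**kwargs).fit(tiny_bags())
        b = TeacherStudentMIL(**kwargs).fit(tiny_bags())
        assert a.history_[-1]["loss"] == b.history_[-1]["loss"]
        for k, v in a.teacher_.get_state().items():
            np.testing.assert_array_equal(v, b.teacher_.get_state()[k])

    def test_lambda_zero_full_proportion_is_fully_supervised(self):
        model = TeacherStudentMIL(epochs=2, batch_size=8, seed=2,
                                  consistency_weight=0.0,
                                  labeled_proportion=1.0,
                                  encoder_widths=(4, 8), encoder_side=32)
        model.fit(tiny_bags())
        for rec in model.history_:
            assert rec["cons"] == 0.0
        assert model.history_[-1]["wce"] < model.history_[0]["wce"]

    def test_churn_settles_below_first_epoch(self):
        model = TeacherStudentMIL(epochs=4, batch_size=8, seed=4,
                                  encoder_widths=(4, 8), encoder_side=32)
        model.fit(tiny_bags())
        churns = [rec["churn"] for rec in model.history_]
        assert churns[-1] < churns[0]

    def test_single_class_dataset_rejected(self):
        bags = [Bag("a", [np.zeros((32, 32, 3), np.uint8)], 1),
                Bag("b", [np.zeros((32, 32, 3), np.uint8)], 1)]
        with pytest.raises(MiltsInputError):
            TeacherStudentMIL(epochs=1).fit(bags)

    def test_scores_in_unit_interval_and_deterministic(self, tiny_model,
                                                       tiny_cohort):
        from milts.synthetic import cohort_tiles

        tiles = cohort_tiles(tiny_cohort, tiny_cohort.slides[0].slide_id)
        p1 = tiny_model.predict_proba(tiles)
        p2 = tiny_model.predict_proba(tiles)
        assert np.all((p1 >= 0) & (p1 <= 1))
        np.testing.assert_array_equal(p1, p2)

    def test_witness_tiles_score_above_background_in_positive_slides(
            self, tiny_model, tiny_cohort):
        from milts.synthetic import cohort_tiles

        wit_scores, bg_scores = [], []
        for slide in tiny_cohort.slides:
            truth = tiny_cohort.truths[slide.slide_id]
            if truth.label != 1:
                continue
            tiles = cohort_tiles(tiny_cohort, slide.slide_id)
            flags = {(int(r.x), int(r.y)): int(r.witness)
                     for r in truth.tiles.itertuples()}
            probs = tiny_model.predict_proba(tiles)
            for t, p in zip(tiles, probs):
                (wit_scores if flags[(t.x, t.y)] else bg_scores).append(p)
        assert np.mean(wit_scores) > np.mean(bg_scores)
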