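"""Metrics, thresholds, bootstrap, heatmaps and patch correlation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from milts.errors import MiltsInputError
from milts.evaluation import (bootstrap_ci, confusion_metrics,
                              evaluate_scores, matched_patch_correlation,
                              probability_colormap, render_heatmap, roc_auc,
                              youden_threshold)
from milts.tiling import Tile


def brute_force_auc(scores, labels):
    """O(n^2) pairwise concordance oracle, ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            conc += 1.0 if p > q else (0.5 if p == q else 0.0)
    return conc / total


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_three_of_four_pairs_concordant(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    @given(st.integers(0, 10_000))
    def test_agrees_with_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))

    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(20)
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores) + 1, labels)
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(MiltsInputError):
            roc_auc([0.1, 0.2], [1, 1])


def exhaustive_youden(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = (-np.inf, None)
    for t in sorted(set(scores)):
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / labels.sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, t)
    return best[1]


class TestYoudenThreshold:
    def test_clean_separation_picks_lowest_positive_score(self):
        assert youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 0.8

    def test_tie_returns_smallest_candidate(self):
        assert youden_threshold([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.35

    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert youden_threshold(scores, labels) == exhaustive_youden(scores, labels)

    @given(st.integers(0, 2_000))
    def test_youden_point_dominates_other_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        t = youden_threshold(scores, labels)
        best = confusion_metrics(scores, labels, t)
        for other in scores:
            m = confusion_metrics(scores, labels, other)
            assert (best["sensitivity"] + best["specificity"]
                    >= m["sensitivity"] + m["specificity"] - 1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(MiltsInputError):
            youden_threshold([0.5, 0.6], [0, 0])


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0,
                     "f1": 1.0, "mcc": 1.0}

    def test_all_predicted_positive_has_zero_mcc(self):
        m = confusion_metrics([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 0], 0.0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0
        assert m["mcc"] == 0.0

    def test_hand_worked_confusion_table(self):
        # TP=3, FP=1, FN=1, TN=5
        scores = [0.9, 0.9, 0.9, 0.1, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        m = confusion_metrics(scores, labels, 0.5)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6, abs=1e-4)
        assert m["f1"] == pytest.approx(0.75)
        assert m["mcc"] == pytest.approx((3 * 5 - 1 * 1) /
                                         np.sqrt(4 * 4 * 6 * 6))


class TestBootstrapCi:
    def test_perfectly_separated_scores_give_degenerate_ci(self):
        lo, hi = bootstrap_ci([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1],
                              n_resamples=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_is_ordered_and_bounded(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        lo, hi = bootstrap_ci(scores, labels, n_resamples=300, seed=2)
        assert 0 <= lo <= hi <= 1

    def test_seed_reproducible(self):
        scores = np.linspace(0, 1, 30)
        labels = (scores + np.random.default_rng(3).normal(0, 0.4, 30) > 0.5)
        labels = labels.astype(int)
        labels[:2] = [0, 1]
        a = bootstrap_ci(scores, labels, n_resamples=250, seed=9)
        b = bootstrap_ci(scores, labels, n_resamples=250, seed=9)
        assert a == b

    @given(st.integers(0, 5_000))
    def test_internal_rank_auc_equals_public_auc(self, seed):
        from milts.evaluation import _rank_auc

        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 9), size=30)
        labels = rng.integers(0, 2, size=30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert _rank_auc(scores, labels) == pytest.approx(
            roc_auc(scores, labels), abs=1e-12)

    def test_few_resamples_warn(self):
        with pytest.warns(UserWarning):
            bootstrap_ci([0.1, 0.9], [0, 1], n_resamples=50, seed=0)

    def test_report_ci_brackets_auc(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(0, 1, 50), rng.normal(1, 1, 50)]
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        rep = evaluate_scores(scores, labels, n_resamples=300, seed=1)
        assert rep.ci_low <= rep.auc <= rep.ci_high
        assert rep.n == 100


class TestRenderHeatmap:
    def make_tiles(self, prob):
        return [Tile("s", x, y, None, typicality=prob)
                for x in (0, 256) for y in (0, 256)]

    def test_all_high_probability_is_uniform_red_endpoint(self):
        img = render_heatmap(self.make_tiles(1.0), (512, 512))
        red = probability_colormap(np.array([1.0]))[0]
        tissue = img[:16, :16]
        assert (tissue == red).all()
        assert red[0] > red[2]      # red channel dominates blue

    def test_all_low_probability_is_uniform_blue_endpoint(self):
        img = render_heatmap(self.make_tiles(0.0), (512, 512))
        blue = probability_colormap(np.array([0.0]))[0]
        assert (img[:16, :16] == blue).all()
        assert blue[2] > blue[0]

    def test_output_has_requested_thumbnail_dims(self):
        img = render_heatmap(self.make_tiles(0.5), (768, 512), downsample=32)
        assert img.shape == (24, 16, 3)

    def test_untiled_area_stays_white(self):
        tiles = [Tile("s", 0, 0, None, typicality=0.7)]
        img = render_heatmap(tiles, (1024, 1024))
        assert (img[20:, 20:] == 255).all()

    def test_colormap_monotone_in_probability(self):
        ramp = probability_colormap(np.linspace(0, 1, 11)).astype(int)
        redness = ramp[:, 0] - ramp[:, 2]
        assert (np.diff(redness) >= 0).all()

    def test_out_of_bounds_tile_rejected(self):
        with pytest.raises(MiltsInputError):
            render_heatmap([Tile("s", 900, 0, None, typicality=0.5)],
                           (512, 1024))


class TestMatchedPatchCorrelation:
    def test_affine_increasing_reference_gives_plus_one(self):
        pred = np.linspace(0, 1, 200)
        assert matched_patch_correlation(pred, 3 * pred + 1) == pytest.approx(1.0)

    def test_affine_decreasing_reference_gives_minus_one(self):
        pred = np.linspace(0, 1, 200)
        assert matched_patch_correlation(pred, -2 * pred + 5) == pytest.approx(-1.0)

    def test_one_percent_of_thousand_selects_ten_top_patches(self):
        rng = np.random.default_rng(0)
        pred = rng.random(1000)
        ref = pred + rng.normal(0, 0.01, 1000)
        r_top = matched_patch_correlation(pred, ref, 0.01, mode="top")
        k = np.argsort(pred)[-10:]
        from scipy.stats import pearsonr
        assert r_top == pytest.approx(pearsonr(pred[k], ref[k]).statistic)

    def test_too_few_patches_rejected(self):
        with pytest.raises(MiltsInputError):
            matched_patch_correlation([0.5, 0.6], [1.0, 2.0], 0.5, mode="top")
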