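"""Metrics, bootstrap confidence intervals, heatmaps and patch correlation.

AUC is the Mann-Whitney concordance probability (ties count one half);
the operating threshold is chosen by Youden's J = sensitivity +
specificity - 1 over the observed scores; confidence intervals come from
slide-level case resampling with the percentile method.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as spstats
from sklearn.metrics import roc_auc_score

from .errors import MiltsInputError
from .tiling import Tile


@dataclass
class MetricsReport:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    threshold: float
    ci_low: float
    ci_high: float
    n: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _validate_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise MiltsInputError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney concordance, ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _validate_two_class(labels)
    return float(roc_auc_score(labels, scores))


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC via midranks (ties count one half); O(n log n)."""
    ranks = spstats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def youden_threshold(scores, labels) -> float:
    """Smallest observed score maximizing J = sensitivity + specificity - 1.

    A sample is predicted positive iff its score is >= the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _validate_two_class(labels)
    candidates = np.unique(scores)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def confusion_metrics(scores, labels, threshold: float) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, F1 and MCC at a fixed threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(threshold):
        raise MiltsInputError("threshold must be finite")
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    acc = (tp + tn) / len(labels)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "f1": f1, "mcc": float(mcc)}


def bootstrap_ci(scores, labels, n_resamples: int = 2000, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI of the AUC over case resamples.

    Resamples that lose a class are redrawn; seed-reproducible.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _validate_two_class(labels)
    if n_resamples < 100:
        warnings.warn("fewer than 100 bootstrap resamples; CI will be noisy",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(labels)
    aucs = np.empty(n_resamples)
    for i in range(n_resamples):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.min() != lab.max():
                break
        aucs[i] = _rank_auc(scores[idx], lab)
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def evaluate_scores(scores, labels, n_resamples: int = 2000,
                    seed: int = 0) -> MetricsReport:
    """Full metrics report at the Youden threshold with bootstrap CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = roc_auc(scores, labels)
    thr = youden_threshold(scores, labels)
    conf = confusion_metrics(scores, labels, thr)
    lo, hi = bootstrap_ci(scores, labels, n_resamples=n_resamples, seed=seed)
    return MetricsReport(auc=auc, threshold=thr, ci_low=lo, ci_high=hi,
                         n=len(labels), **conf)


def probability_colormap(probs: np.ndarray) -> np.ndarray:
    """Blue -> red colormap over [0, 1], monotone in probability."""
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "blue_red", [(0.16, 0.30, 0.85), (0.87, 0.87, 0.87), (0.85, 0.10, 0.12)])
    rgba = cmap(np.clip(np.asarray(probs, dtype=float), 0, 1))
    return (rgba[..., :3] * 255).astype(np.uint8)


def render_heatmap(tiles: list[Tile], slide_shape: tuple[int, int],
                   downsample: int = 32, side_px: int = 256) -> np.ndarray:
    """Thumbnail heatmap: each tile footprint colored by its probability.

    Non-tissue (untiled) area stays white background.
    """
    h = -(-slide_shape[0] // downsample)
    w = -(-slide_shape[1] // downsample)
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    for t in tiles:
        if t.typicality is None:
            raise MiltsInputError(f"tile ({t.x},{t.y}) has no typicality")
        if not (0 <= t.x <= slide_shape[1] - side_px
                and 0 <= t.y <= slide_shape[0] - side_px):
            raise MiltsInputError(f"tile ({t.x},{t.y}) out of bounds")
        color = probability_colormap(np.array([t.typicality]))[0]
        y0, x0 = t.y // downsample, t.x // downsample
        y1 = -(-(t.y + side_px) // downsample)
        x1 = -(-(t.x + side_px) // downsample)
        img[y0:y1, x0:x1] = color
    return img


def matched_patch_correlation(pred, reference, fraction: float = 0.01,
                              mode: str = "symmetric") -> float:
    """Pearson r between predictions and a paired reference quantification.

    The ceil(fraction * N) patches with the highest predicted probability
    are selected; in ``symmetric`` mode (default) an equal-sized set of the
    lowest-predicted patches is added so the correlation stays defined for
    near-constant references.  ``top`` mode uses only the high set.
    """
    p = np.asarray(pred, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if p.shape != r.shape:
        raise MiltsInputError("prediction and reference grids must align")
    valid = np.isfinite(p) & np.isfinite(r)
    p, r = p[valid], r[valid]
    if not 0 < fraction <= 1:
        raise MiltsInputError("fraction must be in (0, 1]")
    k = int(np.ceil(fraction * p.size))
    order = np.argsort(p, kind="stable")
    sel = set(order[-k:].tolist())
    if mode == "symmetric":
        sel |= set(order[:k].tolist())
    elif mode != "top":
        raise MiltsInputError("mode must be 'symmetric' or 'top'")
    idx = np.fromiter(sel, dtype=int)
    if idx.size < 3:
        raise MiltsInputError("fewer than 3 selected patches")
    return float(spstats.pearsonr(p[idx], r[idx]).statistic)
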