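"""Slide-level feature fusion and classification.

Tile features are fused into one slide token by a learnable class token
plus a single multi-head self-attention block with layer normalization
(no positional encoding, so the fusion is invariant to tile order).  The
token is concatenated with an 11-value trimmed statistical summary of the
tile probabilities — positive fraction, an 8-bin histogram, median and
mean — to form the slide embedding (523-dimensional for a d=512 encoder),
which a two-hidden-layer MLP classifies.  Tiles with extreme typicality
(below 0.2 or above 0.8) are excluded from the statistical summary so it
reflects the central tendency of the ambiguous mid-range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import MiltsInputError
from .nn import SGD, Linear, ReLU, SlideFusionNet, softmax

TRIM_LOW = 0.2
TRIM_HIGH = 0.8
N_STATS = 11


@dataclass
class StatSummary:
    """Trimmed statistics of a slide's tile probabilities (11 values)."""

    positive_fraction: float
    histogram: np.ndarray
    median: float
    mean: float

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([[self.positive_fraction], self.histogram,
                               [self.median, self.mean]])


@dataclass
class SlideEmbedding:
    vector: np.ndarray
    d: int
    slide_id: str = ""
    encoder_id: str = ""


def trimmed_stat_summary(probs) -> StatSummary:
    """Summary statistics on the trimmed probability set S = [0.2, 0.8].

    Falls back to the untrimmed list (with histogram support [0, 1]) when
    every probability is extreme.
    """
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise MiltsInputError("empty probability list")
    trimmed = p[(p >= TRIM_LOW) & (p <= TRIM_HIGH)]
    if trimmed.size:
        support = (TRIM_LOW, TRIM_HIGH)
        sel = trimmed
    else:
        support = (0.0, 1.0)
        sel = p
    hist, _ = np.histogram(sel, bins=8, range=support)
    hist = hist.astype(float)
    hist /= hist.sum()
    return StatSummary(
        positive_fraction=float(np.mean(sel > 0.5)),
        histogram=hist,
        median=float(np.median(sel)),
        mean=float(np.mean(sel)),
    )


def default_n_heads(d: int) -> int:
    """8 attention heads for wide encoders (d >= 64), 2 for the small one."""
    return 8 if d >= 64 and d % 8 == 0 else 2


def fuse_token(features, fuser: SlideFusionNet | None = None,
               seed: int = 0) -> np.ndarray:
    """Fuse (n_tiles, d) features into the d-dim slide token."""
    f = np.asarray(features, dtype=np.float32)
    if f.ndim != 2 or f.shape[0] < 1:
        raise MiltsInputError("features must be a non-empty (n_tiles, d) array")
    d = f.shape[1]
    if fuser is None:
        fuser = SlideFusionNet(d, default_n_heads(d), np.random.default_rng(seed))
    elif fuser.d != d:
        raise MiltsInputError(f"fuser dimension {fuser.d} != feature dimension {d}")
    return np.asarray(fuser.fuse(f, train=False), dtype=float)


def build_embedding(token, stats: StatSummary | np.ndarray,
                    slide_id: str = "", encoder_id: str = "") -> SlideEmbedding:
    """Concatenate [token || 11 stats] into the slide embedding."""
    t = np.asarray(token, dtype=float).ravel()
    s = stats.values if isinstance(stats, StatSummary) else np.asarray(stats, float)
    if s.size != N_STATS:
        raise MiltsInputError(f"statistical summary must have {N_STATS} values")
    return SlideEmbedding(vector=np.concatenate([t, s]), d=t.size,
                          slide_id=slide_id, encoder_id=encoder_id)


class SlideClassifier(BaseEstimator):
    """Attention fusion + MLP slide classifier, trained jointly.

    ``X`` is a list of ``(features, stats)`` pairs — one (n_tiles, d) float
    array and one 11-vector per slide — and ``y`` the binary slide labels.
    The class token, attention block, layer norm and MLP are optimized
    together with softmax cross-entropy and momentum SGD (default learning
    rate 2e-4), deterministically under a fixed seed.
    """

    def __init__(self, lr: float = 2e-4, momentum: float = 0.9,
                 epochs: int = 500, hidden: tuple[int, int] = (256, 64),
                 n_heads: int | None = None, seed: int = 0,
                 tol: float = 1e-4) -> None:
        self.lr = lr
        self.momentum = momentum
        self.epochs = epochs
        self.hidden = hidden
        self.n_heads = n_heads
        self.seed = seed
        self.tol = tol

    def fit(self, X, y) -> "SlideClassifier":
        y = np.asarray(y, dtype=int)
        if len(set(y.tolist())) < 2:
            raise MiltsInputError("need at least one slide per class")
        feats = [np.asarray(f, dtype=np.float32) for f, _ in X]
        stats = [np.asarray(s, dtype=np.float32).ravel() for _, s in X]
        d = feats[0].shape[1]
        if any(f.shape[1] != d for f in feats):
            raise MiltsInputError("inconsistent feature dimensions across slides")
        rng = np.random.default_rng(self.seed)
        heads = self.n_heads or default_n_heads(d)
        net = SlideFusionNet(d, heads, rng, n_stats=stats[0].size,
                             hidden=tuple(self.hidden))
        opt = SGD(net, momentum=self.momentum)
        n = len(X)
        self.history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            total = 0.0
            for i in order:
                logits = net.forward_slide(feats[i], stats[i], train=True)
                p = softmax(logits)
                total += -float(np.log(max(p[y[i]], 1e-12)))
                dlogits = p.copy()
                dlogits[y[i]] -= 1.0
                opt.zero_grad()
                net.backward_slide(dlogits.astype(np.float32))
                opt.step(self.lr)
            self.history_.append(total / n)
            if total / n < self.tol:
                break
        self.net_ = net
        self.d_ = d
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise MiltsInputError("classifier is not fitted")
        out = np.empty((len(X), 2), dtype=float)
        for i, (f, s) in enumerate(X):
            logits = self.net_.forward_slide(
                np.asarray(f, dtype=np.float32),
                np.asarray(s, dtype=np.float32).ravel(), train=False)
            out[i] = softmax(logits)
        return out

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def embed(self, features, stats) -> SlideEmbedding:
        """The slide embedding [fused token || stats] under the trained fuser."""
        token = fuse_token(np.asarray(features, np.float32), fuser=self.net_)
        return build_embedding(token, np.asarray(stats, float))


class EmbeddingMLP(BaseEstimator):
    """MLP over fixed slide-embedding vectors (two hidden layers, softmax CE)."""

    def __init__(self, lr: float = 2e-4, momentum: float = 0.9,
                 epochs: int = 500, hidden: tuple[int, int] = (256, 64),
                 seed: int = 0) -> None:
        self.lr = lr
        self.momentum = momentum
        self.epochs = epochs
        self.hidden = hidden
        self.seed = seed

    def fit(self, X, y) -> "EmbeddingMLP":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        if len(set(y.tolist())) < 2:
            raise MiltsInputError("need at least one example per class")
        rng = np.random.default_rng(self.seed)
        self._layers = [Linear(X.shape[1], self.hidden[0], rng), ReLU(),
                        Linear(self.hidden[0], self.hidden[1], rng), ReLU(),
                        Linear(self.hidden[1], 2, rng)]

        class _Net:
            def param_items(inner) -> list:
                return [(f"l{i}.{k}", l.params[k], l.grads[k])
                        for i, l in enumerate(self._layers) for k in l.params]

        opt = SGD(_Net(), momentum=self.momentum)
        for _ in range(self.epochs):
            order = rng.permutation(len(X))
            for i in order:
                h = X[i : i + 1]
                for l in self._layers:
                    h = l.forward(h, train=True)
                p = softmax(h[0])
                g = p.copy()
                g[y[i]] -= 1.0
                g = g[None, :].astype(np.float32)
                opt.zero_grad()
                for l in reversed(self._layers):
                    g = l.backward(g)
                opt.step(self.lr)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        h = np.asarray(X, dtype=np.float32)
        for l in self._layers:
            h = l.forward(h, train=False)
        return softmax(h, axis=1)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def train_slide_classifier(embeddings, labels, lr: float = 2e-4,
                           epochs: int = 500, seed: int = 0) -> EmbeddingMLP:
    """Train the MLP head on fixed slide-embedding vectors."""
    vecs = [e.vector if isinstance(e, SlideEmbedding) else np.asarray(e, float)
            for e in embeddings]
    mlp = EmbeddingMLP(lr=lr, epochs=epochs, seed=seed)
    return mlp.fit(np.asarray(vecs), labels)


def predict_slide(tiles, mil_model, classifier: SlideClassifier
                  ) -> tuple[float, np.ndarray]:
    """Tile probabilities plus the slide-level probability of class 1."""
    if len(tiles) == 0:
        raise MiltsInputError("empty tile list")
    tile_probs = mil_model.predict_proba(tiles)
    feats = mil_model.features(tiles)
    stats = trimmed_stat_summary(tile_probs)
    prob = classifier.predict_proba([(feats, stats.values)])[0, 1]
    return float(prob), tile_probs
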