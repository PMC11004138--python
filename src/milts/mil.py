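"""Teacher-student multiple-instance learning engine.

The slide label is the only supervision.  Each epoch the teacher scores
every tile; within each bag the top-scoring tiles (positive bags) or the
bottom-scoring tiles (negative bags) are pseudo-labeled with the bag label
(max-min representative selection), while the remaining tiles stay
unlabeled.  The student minimizes a weighted cross-entropy on the
pseudo-labeled tiles plus a consistency cost — the squared gap between
teacher and student probabilities on identically transformed unlabeled
tiles.  After every optimizer step the teacher is updated as an
exponential moving average of the student, so it is always a convex
combination of historical student parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .errors import MiltsError, MiltsInputError
from .nn import SGD, SmallConvNet, sigmoid
from .tiling import AugmentParams, Tile, augment_array

EPS = 1e-7


@dataclass
class Bag:
    """All tiles of one slide plus its binary label."""

    slide_id: str
    instances: list
    label: int | None = None

    def __len__(self) -> int:
        return len(self.instances)


@dataclass
class PseudoLabelSet:
    labeled_indices: np.ndarray
    unlabeled_indices: np.ndarray
    label: int

    @property
    def M(self) -> int:
        return len(self.labeled_indices)


@dataclass
class TeacherStudentState:
    """Paired student/teacher parameter dicts with the EMA decay."""

    student: dict[str, np.ndarray]
    teacher: dict[str, np.ndarray]
    ema_decay: float = 0.99
    global_step: int = 0


@dataclass
class LossConfig:
    class_weights: tuple[float, float] | None = None   # (w_pos, w_neg); None => inverse frequency
    consistency_weight: float = 100.0
    augment: AugmentParams = field(default_factory=AugmentParams)
    shared_transform: bool = True


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 512
    base_lr: float = 1e-2
    min_lr: float = 1e-4
    lr_cycles: int = 2
    momentum: float = 0.9
    ema_decay: float = 0.99
    labeled_proportion: float = 0.35
    encoder_side: int = 32
    encoder_widths: tuple[int, ...] = (16, 32, 32)
    seed: int = 0


def bag_label_oracle(instance_labels) -> int:
    """MIL bag rule: positive iff any instance is positive."""
    arr = np.asarray(instance_labels)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise MiltsInputError("instance labels must be 0/1")
    return int(arr.sum() > 0) if arr.size else 0


def select_representatives(scores, bag_label: int, M: int) -> np.ndarray:
    """Max-min selection: top-M scores for positive bags, bottom-M for negative.

    Ties are broken toward the lowest index; the result is sorted ascending.
    """
    s = np.asarray(scores, dtype=float)
    if np.isnan(s).any():
        raise MiltsInputError("NaN score")
    if not np.isfinite(s).all():
        raise MiltsInputError("scores must be finite")
    if not 1 <= M <= s.size:
        raise MiltsInputError(f"M={M} outside [1, {s.size}]")
    key = -s if bag_label == 1 else s
    order = np.argsort(key, kind="stable")      # stable sort => lowest index on ties
    return np.sort(order[:M])


def assign_pseudo_labels(bag: Bag, teacher_scores, proportion: float) -> PseudoLabelSet:
    """Pseudo-label the representative fraction of a bag with its slide label."""
    n = len(bag)
    if n == 0:
        raise MiltsInputError(f"bag {bag.slide_id!r} is empty")
    scores = np.asarray(teacher_scores, dtype=float)
    if scores.size != n:
        raise MiltsInputError("teacher_scores length mismatch")
    if not 0 < proportion <= 1:
        raise MiltsInputError("proportion must be in (0, 1]")
    M = max(1, int(round(proportion * n)))
    labeled = select_representatives(scores, int(bag.label), M)
    unlabeled = np.setdiff1d(np.arange(n), labeled, assume_unique=True)
    return PseudoLabelSet(labeled, unlabeled, label=int(bag.label))


def ema_update(state: TeacherStudentState) -> TeacherStudentState:
    """Teacher <- alpha * teacher + (1 - alpha) * student, once per step."""
    a = state.ema_decay
    for name, s in state.student.items():
        t = state.teacher.get(name)
        if t is None or t.shape != s.shape:
            raise MiltsInputError(f"parameter shape mismatch for {name!r}")
        t *= a
        t += (1.0 - a) * s
    state.global_step += 1
    return state


def milts_loss(labeled_probs, pseudo_labels, weights,
               student_unlabeled_probs, teacher_unlabeled_probs,
               lam: float) -> float:
    """Weighted cross-entropy on pseudo-labeled tiles plus consistency cost.

    Both terms are sums; the training loop divides by the batch size.
    """
    if lam < 0:
        raise MiltsInputError("consistency weight must be >= 0")
    f = np.clip(np.asarray(labeled_probs, dtype=float), EPS, 1 - EPS)
    y = np.asarray(pseudo_labels, dtype=float)
    if f.shape != y.shape:
        raise MiltsInputError("labeled probs / labels length mismatch")
    s = np.asarray(student_unlabeled_probs, dtype=float)
    t = np.asarray(teacher_unlabeled_probs, dtype=float)
    if s.shape != t.shape:
        raise MiltsInputError("student / teacher unlabeled length mismatch")
    w_pos, w_neg = weights
    wce = -np.sum(w_pos * y * np.log(f) + w_neg * (1 - y) * np.log(1 - f))
    cons = lam * np.sum((t - s) ** 2)
    return float(wce + cons)


def cosine_lr(step: int, base_lr: float = 1e-2, min_lr: float = 1e-4,
              cycle_steps: int = 15) -> float:
    """Cosine-annealed learning rate with warm restarts.

    The phase runs from 0 at the first step of a cycle to 1 at its last
    step, so each cycle starts exactly at ``base_lr`` and bottoms out
    exactly at ``min_lr`` before restarting.
    """
    if step < 0:
        raise MiltsInputError("step must be >= 0")
    if cycle_steps <= 1:
        return base_lr
    t = (step % cycle_steps) / (cycle_steps - 1)
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + math.cos(math.pi * t))


def prep_patch(patch: np.ndarray, side: int = 32) -> np.ndarray:
    """Downsample a tile raster to (3, side, side) float32 in [0, 1]."""
    if patch is None or patch.ndim != 3 or patch.shape[2] != 3:
        raise MiltsInputError("tile patch must be an HxWx3 raster")
    img = patch.astype(np.float32) / 255.0
    h = patch.shape[0]
    if h % side == 0 and patch.shape[1] == h:
        f = h // side
        if f > 1:
            img = img.reshape(side, f, side, f, 3).mean(axis=(1, 3))
    else:
        from skimage.transform import resize

        img = resize(img, (side, side), order=1, anti_aliasing=True,
                     preserve_range=True).astype(np.float32)
    return np.ascontiguousarray(img.transpose(2, 0, 1))


def _prep_tiles(tiles, side: int) -> np.ndarray:
    out = np.empty((len(tiles), 3, side, side), dtype=np.float32)
    for i, t in enumerate(tiles):
        patch = t.patch if isinstance(t, Tile) else np.asarray(t)
        try:
            out[i] = prep_patch(patch, side)
        except MiltsInputError as exc:
            ident = f"{t.slide_id} ({t.x},{t.y})" if isinstance(t, Tile) else f"#{i}"
            raise MiltsInputError(f"malformed tile {ident}: {exc}") from exc
    return out


def score_instances(net: SmallConvNet, tiles, batch_size: int = 256) -> np.ndarray:
    """Typicality in [0, 1] for each tile; deterministic (no augmentation)."""
    if len(tiles) == 0:
        raise MiltsInputError("no tiles to score")
    x = tiles if isinstance(tiles, np.ndarray) else _prep_tiles(tiles, net.in_side)
    probs = np.empty(len(x), dtype=float)
    for i in range(0, len(x), batch_size):
        probs[i : i + batch_size] = net.predict_proba(x[i : i + batch_size])
    return probs


class TeacherStudentMIL(BaseEstimator):
    """Scikit-learn style estimator for teacher-student MIL training.

    ``fit`` consumes a list of :class:`Bag` objects (tiles plus slide
    labels).  After fitting, ``predict_proba`` returns per-tile typicality
    from the teacher (the designated inference model), ``features``
    returns the encoder's pooled feature vectors, and ``history_`` holds
    the per-epoch log (lr, weighted cross-entropy, consistency cost and
    pseudo-label churn).

    Parameters mirror the training recipe: SGD with cosine-annealed
    learning rate (``lr_cycles`` warm restarts over ``epochs``), EMA decay
    ``ema_decay`` applied after every optimizer step, consistency weight
    ``consistency_weight`` on unlabeled tiles, and ``labeled_proportion``
    of each bag pseudo-labeled per epoch.
    """

    def __init__(self, epochs: int = 10, batch_size: int = 64,
                 base_lr: float = 1e-2, min_lr: float = 1e-4,
                 lr_cycles: int = 2, momentum: float = 0.9,
                 ema_decay: float = 0.99, consistency_weight: float = 100.0,
                 consistency_rampup: float = 0.4,
                 warmup_epochs: int = 1,
                 labeled_proportion: float = 0.35,
                 class_weights: tuple[float, float] | None = None,
                 augment: AugmentParams | None = None,
                 shared_transform: bool = True,
                 encoder_side: int = 32,
                 encoder_widths: tuple[int, ...] = (16, 32, 32),
                 seed: int = 0, record_trajectory: bool = False) -> None:
        self.epochs = epochs
        self.batch_size = batch_size
        self.base_lr = base_lr
        self.min_lr = min_lr
        self.lr_cycles = lr_cycles
        self.momentum = momentum
        self.ema_decay = ema_decay
        self.consistency_weight = consistency_weight
        self.consistency_rampup = consistency_rampup
        self.warmup_epochs = warmup_epochs
        self.labeled_proportion = labeled_proportion
        self.class_weights = class_weights
        self.augment = augment
        self.shared_transform = shared_transform
        self.encoder_side = encoder_side
        self.encoder_widths = encoder_widths
        self.seed = seed
        self.record_trajectory = record_trajectory

    # ------------------------------------------------------------------ fit
    def fit(self, bags: list[Bag], y=None) -> "TeacherStudentMIL":
        labels = [b.label for b in bags]
        if any(l is None for l in labels):
            raise MiltsInputError("every bag needs a label before training")
        if len(set(labels)) < 2:
            raise MiltsInputError("need at least one bag per class")
        if any(len(b) == 0 for b in bags):
            raise MiltsInputError("empty bag in training set")
        aug = self.augment if self.augment is not None else AugmentParams()

        rng = np.random.default_rng(self.seed)
        side = self.encoder_side
        xs = [_prep_tiles(b.instances, side) for b in bags]
        bag_labels = np.asarray(labels, dtype=int)
        w_pos, w_neg = (self.class_weights if self.class_weights is not None
                        else _inverse_frequency_weights(bag_labels))
        self.class_weights_ = (float(w_pos), float(w_neg))

        student = SmallConvNet(rng, side, tuple(self.encoder_widths))
        teacher = student.clone()
        self.state_ = TeacherStudentState(
            student=dict(student.param_refs()), teacher=dict(teacher.param_refs()),
            ema_decay=self.ema_decay)
        opt = SGD(student, momentum=self.momentum)

        n_total = sum(len(x) for x in xs)
        steps_per_epoch = max(1, math.ceil(n_total / self.batch_size))
        cycle_steps = max(1, math.ceil(self.epochs / self.lr_cycles)) * steps_per_epoch
        # scale-aware EMA decay: the teacher's averaging horizon is capped at
        # one epoch of optimizer steps, so that at desk scale the teacher
        # tracks the student instead of staying diluted by its random
        # initialization; at full scale (thousands of steps per epoch) this
        # reduces to the configured decay.
        alpha = min(self.ema_decay, 1.0 - 1.0 / steps_per_epoch)

        # flat instance table: (bag index, within-bag index)
        flat = np.array([(bi, ii) for bi, x in enumerate(xs)
                         for ii in range(len(x))], dtype=int)
        prev_labeled: list[set[int]] | None = None
        self.history_ = []
        self.trajectory_ = [] if self.record_trajectory else None
        if self.record_trajectory:
            self.trajectory_.append(("init", student.get_state()))

        for epoch in range(self.epochs):
            lam = self.consistency_weight * _rampup(epoch, self.epochs,
                                                    self.consistency_rampup)
            # 1) teacher scores every instance, per bag
            t_scores = [score_instances(teacher, x) for x in xs]
            # 2) dynamic pseudo-label assignment; during the warm-up epochs
            # every instance is painted with its bag label so the witness
            # features break the selection symmetry in the right direction
            prop = 1.0 if epoch < self.warmup_epochs else self.labeled_proportion
            psets = [assign_pseudo_labels(b, s, prop)
                     for b, s in zip(bags, t_scores)]
            churn = _labeled_churn(psets, prev_labeled)
            prev_labeled = [set(p.labeled_indices.tolist()) for p in psets]
            is_labeled = np.zeros(n_total, dtype=bool)
            pseudo = np.zeros(n_total, dtype=int)
            offset = 0
            for bi, (x, p) in enumerate(zip(xs, psets)):
                is_labeled[offset + p.labeled_indices] = True
                pseudo[offset : offset + len(x)] = p.label
                offset += len(x)

            # 3) SGD over shuffled mini-batches mixing labeled and unlabeled
            perm = rng.permutation(n_total)
            wce_sum = cons_sum = 0.0
            lr = self.base_lr
            for start in range(0, n_total, self.batch_size):
                idx = perm[start : start + self.batch_size]
                xb = np.stack([
                    _augment_prepped(xs[flat[i, 0]][flat[i, 1]], aug, rng)
                    for i in idx
                ])
                lab = is_labeled[idx]
                yb = pseudo[idx]
                if self.shared_transform:
                    xb_t = xb
                else:  # classic mean-teacher noise: independent transforms
                    xb_t = np.stack([
                        _augment_prepped(xs[flat[i, 0]][flat[i, 1]], aug, rng)
                        for i in idx
                    ])
                z = student.forward_logits(xb, train=True)
                p = sigmoid(z)
                tp = sigmoid(teacher.forward_logits(xb_t, train=False))
                B = len(idx)
                dz = np.zeros_like(z)
                pos = lab & (yb == 1)
                neg = lab & (yb == 0)
                dz[pos] = w_pos * (p[pos] - 1.0)
                dz[neg] = w_neg * p[neg]
                unl = ~lab
                dz[unl] = lam * 2.0 * (p[unl] - tp[unl]) * p[unl] * (1.0 - p[unl])
                dz /= B
                opt.zero_grad()
                student.backward_from_logits(dz.astype(np.float32))
                lr = cosine_lr(self.state_.global_step, self.base_lr,
                               self.min_lr, cycle_steps)
                opt.step(lr)
                # EMA warm-up: early teacher tracks the running average of
                # all student states, then settles at the configured decay
                self.state_.ema_decay = min(
                    alpha, 1.0 - 1.0 / (self.state_.global_step + 1))
                ema_update(self.state_)
                if self.record_trajectory:
                    self.trajectory_.append(("step", student.get_state()))

                fl = np.clip(p[lab], EPS, 1 - EPS)
                wce_sum += float(-np.sum(
                    w_pos * yb[lab] * np.log(fl)
                    + w_neg * (1 - yb[lab]) * np.log(1 - fl)))
                cons_sum += float(lam * np.sum((tp[unl] - p[unl]) ** 2))
            loss = (wce_sum + cons_sum) / n_total
            if not np.isfinite(loss):
                raise MiltsError(
                    f"non-finite loss {loss} at epoch {epoch + 1}; aborting")
            self.history_.append({
                "epoch": epoch + 1, "lr": lr,
                "wce": wce_sum / n_total, "cons": cons_sum / n_total,
                "loss": loss, "churn": churn,
            })
        self.student_ = student
        self.teacher_ = teacher
        return self

    # ---------------------------------------------------------- inference
    def _net(self, model: str = "teacher") -> SmallConvNet:
        if not hasattr(self, "teacher_"):
            raise MiltsInputError("estimator is not fitted")
        return self.teacher_ if model == "teacher" else self.student_

    def predict_proba(self, tiles, model: str = "teacher") -> np.ndarray:
        """Per-tile typicality in [0, 1]."""
        return score_instances(self._net(model), tiles)

    def features(self, tiles, model: str = "teacher",
                 batch_size: int = 256) -> np.ndarray:
        """Pooled encoder features, shape (n_tiles, d)."""
        net = self._net(model)
        x = tiles if isinstance(tiles, np.ndarray) else _prep_tiles(tiles, net.in_side)
        out = np.empty((len(x), net.feature_dim), dtype=np.float32)
        for i in range(0, len(x), batch_size):
            out[i : i + batch_size] = net.features(x[i : i + batch_size])
        return out

    @property
    def feature_dim(self) -> int:
        return self._net().feature_dim


def _rampup(epoch: int, epochs: int, rampup_fraction: float) -> float:
    """Sigmoid-shaped ramp of the consistency weight over early epochs.

    With a randomly initialized encoder the consistency cost can dominate
    before the pseudo-labels carry signal and collapse both models onto a
    constant output; ramping lambda in (exp(-5(1-t)^2), the usual
    mean-teacher schedule) lets the classification cost break the symmetry
    first.  ``rampup_fraction = 0`` disables the ramp.
    """
    if rampup_fraction <= 0:
        return 1.0
    span = max(1.0, rampup_fraction * epochs)
    t = min(1.0, epoch / span)
    return math.exp(-5.0 * (1.0 - t) ** 2)


def _inverse_frequency_weights(bag_labels: np.ndarray) -> tuple[float, float]:
    """Inverse slide-label frequency, normalized to mean 1: (w_pos, w_neg)."""
    n = len(bag_labels)
    n_pos = int(bag_labels.sum())
    inv = np.array([n / max(n_pos, 1), n / max(n - n_pos, 1)], dtype=float)
    inv /= inv.mean()
    return float(inv[0]), float(inv[1])


def _labeled_churn(psets, prev: list[set[int]] | None) -> float:
    """Mean fraction of each bag's labeled set replaced since last epoch.

    The first epoch has no predecessor; by convention its churn is 1.0
    (every labeled index is newly assigned).
    """
    if prev is None:
        return 1.0
    fracs = []
    for p, old in zip(psets, prev):
        new = set(p.labeled_indices.tolist())
        fracs.append(1.0 - len(new & old) / max(len(new), 1))
    return float(np.mean(fracs))


def _augment_prepped(x: np.ndarray, params: AugmentParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Apply the stochastic transform T to a prepped (3, s, s) array."""
    img = x.transpose(1, 2, 0)
    out = augment_array(img, params, rng)
    return np.ascontiguousarray(out.transpose(2, 0, 1), dtype=np.float32)


def train_teacher_student(bags: list[Bag], train_cfg: TrainConfig | None = None,
                          loss_cfg: LossConfig | None = None
                          ) -> tuple[TeacherStudentMIL, list[dict]]:
    """Functional wrapper over :class:`TeacherStudentMIL`."""
    tc = train_cfg or TrainConfig()
    lc = loss_cfg or LossConfig()
    est = TeacherStudentMIL(
        epochs=tc.epochs, batch_size=tc.batch_size, base_lr=tc.base_lr,
        min_lr=tc.min_lr, lr_cycles=tc.lr_cycles, momentum=tc.momentum,
        ema_decay=tc.ema_decay, labeled_proportion=tc.labeled_proportion,
        class_weights=lc.class_weights,
        consistency_weight=lc.consistency_weight, augment=lc.augment,
        shared_transform=lc.shared_transform,
        encoder_side=tc.encoder_side, encoder_widths=tc.encoder_widths,
        seed=tc.seed,
    )
    est.fit(bags)
    return est, est.history_
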