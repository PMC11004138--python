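"""Checkpoint serialization for trained models (NumPy .npz + JSON meta)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .aggregation import SlideClassifier
from .errors import MiltsInputError
from .mil import TeacherStudentMIL, TeacherStudentState
from .nn import SlideFusionNet, SmallConvNet


def save_mil(model: TeacherStudentMIL, path: str | Path) -> None:
    if not hasattr(model, "teacher_"):
        raise MiltsInputError("model is not fitted")
    meta = {"encoder_side": model.encoder_side,
            "encoder_widths": list(model.encoder_widths),
            "ema_decay": model.ema_decay,
            "global_step": model.state_.global_step}
    arrays = {f"student::{k}": v for k, v in model.student_.get_state().items()}
    arrays |= {f"teacher::{k}": v for k, v in model.teacher_.get_state().items()}
    arrays["__meta"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_mil(path: str | Path) -> TeacherStudentMIL:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta"]))
        model = TeacherStudentMIL(encoder_side=meta["encoder_side"],
                                  encoder_widths=tuple(meta["encoder_widths"]),
                                  ema_decay=meta["ema_decay"])
        rng = np.random.default_rng(0)
        student = SmallConvNet(rng, meta["encoder_side"],
                               tuple(meta["encoder_widths"]))
        teacher = student.clone()
        student.set_state({k.split("::", 1)[1]: data[k] for k in data.files
                           if k.startswith("student::")})
        teacher.set_state({k.split("::", 1)[1]: data[k] for k in data.files
                           if k.startswith("teacher::")})
    model.student_, model.teacher_ = student, teacher
    model.state_ = TeacherStudentState(
        student=dict(student.param_refs()), teacher=dict(teacher.param_refs()),
        ema_decay=meta["ema_decay"], global_step=meta["global_step"])
    model.history_ = []
    return model


def save_slide_classifier(clf: SlideClassifier, path: str | Path) -> None:
    if not hasattr(clf, "net_"):
        raise MiltsInputError("classifier is not fitted")
    meta = {"d": clf.d_, "n_heads": clf.net_.msa.h,
            "hidden": list(clf.hidden), "n_stats": clf.net_.n_stats}
    arrays = {f"net::{k}": v for k, v in clf.net_.get_state().items()}
    arrays["__meta"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_slide_classifier(path: str | Path) -> SlideClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta"]))
        clf = SlideClassifier(hidden=tuple(meta["hidden"]),
                              n_heads=meta["n_heads"])
        net = SlideFusionNet(meta["d"], meta["n_heads"],
                             np.random.default_rng(0),
                             n_stats=meta["n_stats"], hidden=tuple(meta["hidden"]))
        net.set_state({k.split("::", 1)[1]: data[k] for k in data.files
                       if k.startswith("net::")})
    clf.net_ = net
    clf.d_ = meta["d"]
    clf.classes_ = np.array([0, 1])
    return clf
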