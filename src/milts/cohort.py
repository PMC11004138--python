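"""Expression dichotomization and patient-level cohort splitting.

Slide labels come from a per-cancer-type percentile cutoff on continuous
expression (FPKM-UQ): a slide is expression-high (label 1) iff its value
exceeds the cutoff.  Splits are drawn at patient granularity so that no
patient contributes slides to more than one partition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDistributionError, MiltsInputError

SPLIT_FRACTIONS = (0.60, 0.15, 0.25)
SPLIT_NAMES = ("train", "val", "test")


class ThresholdKind(str, enum.Enum):
    """Percentile cutoff used to dichotomize expression."""

    MEDIAN = "median"
    TERTILE = "tertile"
    QUARTILE = "quartile"

    @property
    def percentile(self) -> float:
        return {"median": 50.0, "tertile": 200.0 / 3.0, "quartile": 75.0}[self.value]


#: per-slide proportion of instances pseudo-labeled during MIL training
_LABELED_PROPORTION = {
    ThresholdKind.QUARTILE: 0.25,
    ThresholdKind.TERTILE: 0.35,
    ThresholdKind.MEDIAN: 0.45,
}


def labeled_proportion(kind: ThresholdKind | str) -> float:
    """Pseudo-labeled instance proportion paired with each cutoff kind."""
    kind = ThresholdKind(kind)
    return _LABELED_PROPORTION[kind]


@dataclass
class ExpressionRecord:
    patient_id: str
    slide_id: str
    cancer_type: str
    fpkm_uq: float


@dataclass
class CohortSplit:
    assignment: dict[str, str]
    fractions: tuple[float, float, float] = SPLIT_FRACTIONS
    seed: int = 0

    def partition(self, name: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == name)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
    required = {"patient_id", "slide_id", "cancer_type", "fpkm_uq"}
    missing = required - set(df.columns)
    if missing:
        raise MiltsInputError(f"manifest missing columns: {sorted(missing)}")
    if df["slide_id"].duplicated().any():
        dupes = df.loc[df["slide_id"].duplicated(), "slide_id"].tolist()
        raise MiltsInputError(f"duplicate slide_ids: {dupes}")
    return df


def dichotomize_expression(records, kind: ThresholdKind | str
                           ) -> tuple[dict[str, float], dict[str, int]]:
    """Binarize expression per cancer type at the kind's percentile.

    Returns ``(cutoffs, labels)`` where ``cutoffs`` maps cancer type to the
    linearly interpolated percentile of its expression values, and
    ``labels`` maps slide id to 1 iff its value strictly exceeds the
    cutoff (ties at the cutoff are negative).
    """
    kind = ThresholdKind(kind)
    df = _as_frame(records)
    bad = df["fpkm_uq"].isna() | (df["fpkm_uq"] < 0)
    if bad.any():
        raise MiltsInputError(
            f"missing/negative expression for slides: {df.loc[bad, 'slide_id'].tolist()}")
    cutoffs: dict[str, float] = {}
    labels: dict[str, int] = {}
    for ctype, grp in df.groupby("cancer_type", sort=True):
        vals = grp["fpkm_uq"].to_numpy(dtype=float)
        if np.unique(vals).size < 2:
            raise DegenerateDistributionError(
                f"cancer type {ctype!r}: expression values are constant")
        cut = float(np.percentile(vals, kind.percentile, method="linear"))
        cutoffs[ctype] = cut
        for sid, v in zip(grp["slide_id"], vals):
            labels[str(sid)] = int(v > cut)
    return cutoffs, labels


def _largest_remainder_counts(n: int, fractions) -> list[int]:
    exact = np.asarray(fractions, dtype=float) * n
    counts = np.floor(exact).astype(int)
    order = np.argsort(-(exact - counts), kind="stable")
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def split_cohort(patient_ids, fractions=SPLIT_FRACTIONS, seed: int = 0,
                 labels: dict[str, int] | None = None) -> CohortSplit:
    """Seeded random train/val/test partition at patient granularity.

    When ``labels`` (patient id -> class) is given, the split is stratified
    so each class is divided by the same fractions.  Partition sizes follow
    largest-remainder rounding.  The assignment is invariant to the input
    ordering of patients.
    """
    patients = sorted(set(map(str, patient_ids)))
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise MiltsInputError("fractions must sum to 1")
    if len(patients) < len(fractions):
        raise MiltsInputError("fewer patients than partitions")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    if labels is None:
        strata = [patients]
    else:
        by_label: dict[int, list[str]] = {}
        for p in patients:
            by_label.setdefault(labels[p], []).append(p)
        strata = [by_label[k] for k in sorted(by_label)]
    for group in strata:
        perm = rng.permutation(len(group))
        counts = _largest_remainder_counts(len(group), fractions)
        start = 0
        for name, cnt in zip(SPLIT_NAMES, counts):
            for idx in perm[start : start + cnt]:
                assignment[group[idx]] = name
            start += cnt
    return CohortSplit(assignment=assignment, fractions=tuple(fractions), seed=seed)


def label_manifest(manifest: pd.DataFrame, kind: ThresholdKind | str,
                   seed: int = 0, stratify: bool = True) -> pd.DataFrame:
    """Attach label, cutoff_kind and patient-level split columns to a manifest."""
    kind = ThresholdKind(kind)
    df = _as_frame(manifest)
    cutoffs, labels = dichotomize_expression(df, kind)
    df["label"] = df["slide_id"].astype(str).map(labels)
    df["cutoff_kind"] = kind.value
    df["cutoff"] = df["cancer_type"].map(cutoffs)
    patient_labels = None
    if stratify:
        # a patient's stratum is the max label over their slides
        patient_labels = df.groupby("patient_id")["label"].max().to_dict()
        patient_labels = {str(k): int(v) for k, v in patient_labels.items()}
    split = split_cohort(df["patient_id"].unique(), seed=seed, labels=patient_labels)
    df["split"] = df["patient_id"].astype(str).map(split.assignment)
    # hard assertion: no patient in two partitions
    per_patient = df.groupby("patient_id")["split"].nunique()
    assert (per_patient == 1).all(), "patient assigned to multiple partitions"
    return df
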