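"""Confusion-matrix metrics and validation protocols.

Metrics follow the standard binary conventions with the positive class
(stress protein) = 1:

    Sn  = TP / (TP + FN)            sensitivity, reported in percent
    Sp  = TN / (FP + TN)            specificity, in percent
    Acc = (TP + TN) / total         in percent
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Any metric whose denominator is zero is defined as 0. Reported percentages
are rounded half-away-from-zero to one decimal, MCC to two, but the
unrounded values are what the report stores.

Four protocol kinds are provided: self-consistency (resubstitution),
jackknife (leave-one-out with per-iteration re-initialization and a pooled
confusion matrix), a stratified 70/30 independent split, and stratified
k-fold cross-validation whose headline numbers average the per-fold
metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, train_test_split

from .classify import ModelSpec, predict, train

PROTOCOL_KINDS = ("self_consistency", "jackknife", "independent_split", "k_fold")


def round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero (5 rounds up in magnitude)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
                 * (1 if value >= 0 else -1))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )


@dataclass
class MetricsReport:
    """Sn/Sp/Acc in percent, MCC, AUC, plus protocol provenance."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None
    cells: ConfusionMatrix | None = None
    protocol: str | None = None
    seed: int | None = None
    k: int | None = None
    per_fold: list[dict] = field(default_factory=list)

    def rounded(self) -> dict:
        out = {
            "Sn": round_half_away(self.sn, 1),
            "Sp": round_half_away(self.sp, 1),
            "Acc": round_half_away(self.acc, 1),
            "MCC": round_half_away(self.mcc, 2),
        }
        if self.auc is not None:
            out["AUC"] = round_half_away(self.auc, 3)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "protocol": self.protocol,
            "seed": self.seed,
            "k": self.k,
            "cells": None if self.cells is None else {
                "TP": self.cells.tp, "FN": self.cells.fn,
                "FP": self.cells.fp, "TN": self.cells.tn,
            },
            "metrics": {"Sn": self.sn, "Sp": self.sp, "Acc": self.acc,
                        "MCC": self.mcc, "AUC": self.auc},
            "metrics_rounded": self.rounded(),
            "per_fold": self.per_fold,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Four-cell confusion counts with positive class = 1."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.shape} vs {p.shape}")
    if not (set(np.unique(t)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sn/Sp/Acc (percent) and MCC from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sn = _safe_div(cm.tp, cm.tp + cm.fn)
    sp = _safe_div(cm.tn, cm.fp + cm.tn)
    acc = (cm.tp + cm.tn) / cm.total
    mcc_num = cm.tp * cm.tn - cm.fp * cm.fn
    mcc_den_sq = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = _safe_div(mcc_num, float(np.sqrt(mcc_den_sq)))
    return MetricsReport(sn=100 * sn, sp=100 * sp, acc=100 * acc, mcc=mcc, cells=cm)


def roc_points(true_labels, scores) -> tuple[np.ndarray, float]:
    """ROC curve points (FPR, TPR) swept over score thresholds, plus AUC.

    Equal scores are grouped (one threshold per unique score); AUC is the
    trapezoid-rule area.
    """
    t = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("ROC requires both classes in the truth labels")
    if s.min() < 0 or s.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    fpr, tpr, _ = roc_curve(t, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(_trapezoid_auc(fpr, tpr))


@dataclass
class ProtocolSpec:
    kind: str = "k_fold"
    k: int = 5
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(
                f"unknown protocol {self.kind!r}; choose from {PROTOCOL_KINDS}"
            )
        if self.kind == "k_fold" and self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified partition into k disjoint test folds covering all rows."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=2)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the minority class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def run_protocol(
    features: np.ndarray,
    labels: np.ndarray,
    model_spec: ModelSpec,
    protocol: ProtocolSpec,
    feature_names: list[str] | None = None,
) -> MetricsReport:
    """Train/test under one validation protocol and report metrics."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("empty dataset")
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")

    def fit_predict(train_idx, test_idx):
        model = train(x[train_idx], y[train_idx], model_spec, feature_names)
        return predict(model, x[test_idx])

    if protocol.kind == "self_consistency":
        idx = np.arange(len(y))
        pred, scores = fit_predict(idx, idx)
        cm = confusion(y, pred)
        report = metrics(cm)
        report.auc = roc_points(y, scores)[1]

    elif protocol.kind == "jackknife":
        pred = np.empty(len(y), dtype=int)
        scores = np.empty(len(y), dtype=float)
        for train_idx, test_idx in LeaveOneOut().split(x):
            # canonicalize training-row order so the pooled result depends
            # only on the set of samples, not on how the rows were listed
            train_idx = train_idx[np.lexsort(x[train_idx].T)]
            p, s = fit_predict(train_idx, test_idx)
            pred[test_idx[0]] = p[0]
            scores[test_idx[0]] = s[0]
        cm = confusion(y, pred)
        report = metrics(cm)
        report.auc = roc_points(y, scores)[1]

    elif protocol.kind == "independent_split":
        n_test = int(round((1 - protocol.train_fraction) * len(y)))
        train_idx, test_idx = train_test_split(
            np.arange(len(y)),
            test_size=n_test,
            stratify=y,
            random_state=protocol.seed,
        )
        pred, scores = fit_predict(train_idx, test_idx)
        cm = confusion(y[test_idx], pred)
        report = metrics(cm)
        report.auc = roc_points(y[test_idx], scores)[1]

    else:  # k_fold: headline numbers average the per-fold metrics
        folds = stratified_folds(y, protocol.k, protocol.seed)
        all_idx = np.arange(len(y))
        per_fold: list[MetricsReport] = []
        pooled: ConfusionMatrix | None = None
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            pred, scores = fit_predict(train_idx, test_idx)
            cm = confusion(y[test_idx], pred)
            rep = metrics(cm)
            rep.auc = roc_points(y[test_idx], scores)[1]
            per_fold.append(rep)
            pooled = cm if pooled is None else pooled + cm
        report = MetricsReport(
            sn=float(np.mean([r.sn for r in per_fold])),
            sp=float(np.mean([r.sp for r in per_fold])),
            acc=float(np.mean([r.acc for r in per_fold])),
            mcc=float(np.mean([r.mcc for r in per_fold])),
            auc=float(np.mean([r.auc for r in per_fold])),
            cells=pooled,
        )
        report.per_fold = [
            {"cells": {"TP": r.cells.tp, "FN": r.cells.fn,
                       "FP": r.cells.fp, "TN": r.cells.tn},
             "Sn": r.sn, "Sp": r.sp, "Acc": r.acc, "MCC": r.mcc, "AUC": r.auc}
            for r in per_fold
        ]

    report.protocol = protocol.kind
    report.seed = protocol.seed
    report.k = protocol.k if protocol.kind == "k_fold" else None
    return report
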