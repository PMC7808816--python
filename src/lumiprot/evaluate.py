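"""Performance metrics and evaluation protocols.

Metrics are the standard confusion-matrix quantities for binary
classification with BLP as the positive class — sensitivity Sn =
TP/(TP+FN), specificity Sp = TN/(TN+FP), overall accuracy Acc, Matthews
correlation coefficient MCC — plus the ROC curve and its area (AUC,
equal to the Mann-Whitney U statistic with ties counted one half).

Protocols: stratified k-fold cross-validation (default k = 10, the
model-selection protocol), a cross-species accuracy matrix (each
species-specific model applied to every species' data), and a paired
comparison of tree-based classifiers on identical folds.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from lumiprot.encoders import DatasetEncoder, EncoderConfig
from lumiprot.seqio import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ROCCurve:
    """ROC curve from (0, 0) to (1, 1) with trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"FPR": self.fpr, "TPR": self.tpr})


@dataclass
class MetricsReport:
    """Sn, Sp, Acc, MCC (and AUC when scores are available)."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None
    counts: ConfusionCounts | None = None
    roc: ROCCurve | None = None

    def to_dict(self) -> dict:
        d = {"Sn": self.sn, "Sp": self.sp, "Acc": self.acc, "MCC": self.mcc}
        if self.auc is not None:
            d["AUC"] = self.auc
        return d

    def __str__(self) -> str:
        parts = [f"{k}={v:.4f}" for k, v in self.to_dict().items()]
        return "MetricsReport(" + ", ".join(parts) + ")"


def _as_binary(y, name: str) -> np.ndarray:
    arr = np.asarray(y)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return arr.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts with BLP (label 1) as the positive class."""
    t = _as_binary(y_true, "y_true")
    p = _as_binary(y_pred, "y_pred")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sn, Sp, Acc and MCC from confusion counts.

    A zero factor in the MCC denominator yields MCC = 0 (the standard
    convention for degenerate margins); Sn/Sp with an empty class are 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=mcc, counts=c)


def roc_auc(y_true, scores) -> tuple[ROCCurve, float]:
    """ROC curve over all score thresholds and its trapezoidal area.

    With tied scores the trapezoid crosses the tie block diagonally, so
    the area equals the Mann-Whitney statistic with ties counted half.
    """
    t = _as_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {s.shape}")
    if t.min() == t.max():
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, _ = _sk_roc_curve(t, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    curve = ROCCurve(fpr=fpr, tpr=tpr, auc=auc)
    return curve, auc


def _mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    aucs = [r.auc for r in reports if r.auc is not None]
    return MetricsReport(
        sn=float(np.mean([r.sn for r in reports])),
        sp=float(np.mean([r.sp for r in reports])),
        acc=float(np.mean([r.acc for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        auc=float(np.mean(aucs)) if aucs else None,
    )


def make_folds(labels: Sequence[int], k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds fixed by seed (shared across paired comparisons)."""
    y = _as_binary(labels, "labels")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= k={k} members for stratified folds, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def fold_hash(folds: Sequence[tuple[np.ndarray, np.ndarray]]) -> str:
    """Stable digest of a fold assignment, for paired-comparison checks."""
    h = hashlib.sha256()
    for _, test_idx in folds:
        h.update(np.asarray(test_idx, dtype=np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()[:16]


def _score_report(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    preds = (scores >= threshold).astype(int)
    rep = metrics(confusion(y_true, preds))
    if y_true.min() != y_true.max():
        rep.roc, rep.auc = roc_auc(y_true, scores)
    return rep


def kfold_cv(
    data: LabeledDataset,
    config: EncoderConfig,
    params=None,
    k: int = 10,
    seed: int = 0,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Stratified k-fold cross-validation of the boosted-tree pipeline.

    Returns the unweighted mean report across held-out folds plus the
    per-fold reports.  Folds are fixed by ``seed``.
    """
    from lumiprot.model import BLPClassifier, default_params

    params = params or default_params()
    X = DatasetEncoder(data.sequences).encode(config)
    y = np.asarray(data.labels)
    reports = []
    for train_idx, test_idx in make_folds(y, k, seed):
        bundle = BLPClassifier(
            X.iloc[train_idx], y[train_idx], params=params, config=config
        ).fit()
        scores = bundle.predict_scores(X.iloc[test_idx])
        reports.append(_score_report(y[test_idx], scores))
    return _mean_report(reports), reports


def cross_species_matrix(
    models: Mapping[str, "ModelBundle"],
    datasets: Mapping[str, LabeledDataset],
) -> pd.DataFrame:
    """Accuracy of every model on every dataset.

    Rows are datasets, columns are models (so ``matrix.loc[d, m]`` is the
    accuracy of model ``m`` applied to the data of species ``d``); each
    dataset is encoded under each model's own encoder config.
    """
    missing = set(models) - set(datasets)
    if missing:
        raise KeyError(f"no dataset for model species {sorted(missing)}")
    out = pd.DataFrame(
        index=pd.Index(list(datasets), name="dataset"),
        columns=pd.Index(list(models), name="model"),
        dtype=float,
    )
    for d_name, data in datasets.items():
        for m_name, bundle in models.items():
            try:
                scores = bundle.predict_scores(data.sequences)
            except Exception as exc:
                raise RuntimeError(
                    f"model {m_name!r} failed on dataset {d_name!r}: {exc}"
                ) from exc
            preds = (scores >= 0.5).astype(int)
            out.loc[d_name, m_name] = metrics(confusion(data.labels, preds)).acc
    return out


_BASELINES = {
    "decision_tree": DecisionTreeClassifier,
    "random_forest": RandomForestClassifier,
    "adaboost": AdaBoostClassifier,
}


def compare_classifiers(
    data: LabeledDataset,
    config: EncoderConfig,
    classifiers: Sequence[str],
    params=None,
    k: int = 10,
    seed: int = 0,
) -> dict[str, dict]:
    """Paired k-fold comparison of tree-based classifiers.

    ``classifiers`` is drawn from {xgboost, decision_tree, random_forest,
    adaboost}; the three baselines run at library defaults.  All
    classifiers see identical folds; each entry of the result carries the
    mean report, the per-fold reports and the shared fold hash.
    """
    from lumiprot.model import BLPClassifier, default_params

    if not classifiers:
        raise ValueError("empty classifier list")
    unknown = set(classifiers) - (set(_BASELINES) | {"xgboost"})
    if unknown:
        raise ValueError(f"unsupported classifiers {sorted(unknown)}")
    params = params or default_params()
    X = DatasetEncoder(data.sequences).encode(config)
    y = np.asarray(data.labels)
    folds = make_folds(y, k, seed)
    fhash = fold_hash(folds)
    results: dict[str, dict] = {}
    for name in classifiers:
        reports = []
        for train_idx, test_idx in folds:
            if name == "xgboost":
                bundle = BLPClassifier(
                    X.iloc[train_idx], y[train_idx], params=params, config=config
                ).fit()
                scores = bundle.predict_scores(X.iloc[test_idx])
            else:
                clf = _BASELINES[name](random_state=seed)
                clf.fit(X.iloc[train_idx].to_numpy(), y[train_idx])
                scores = clf.predict_proba(X.iloc[test_idx].to_numpy())[:, 1]
            reports.append(_score_report(y[test_idx], scores))
        results[name] = {
            "mean": _mean_report(reports),
            "folds": reports,
            "fold_hash": fhash,
        }
    return results
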