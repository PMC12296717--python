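"""Model performance surface: ROC/AUC, OOB, accuracy, precision, f1, recall.

Every fitted strategy is summarized in one :class:`ModelReport` — train
and test accuracy, the positive-class precision/recall/f1 on the test
partition, the trapezoidal AUC of the test-set ROC, and (for random
forests) the out-of-bag accuracy.  ``compare_strategies`` ranks the
reports by (AUC, test accuracy) and names the best model, which the
screening stage consumes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm


@dataclass
class ModelReport:
    """Per-model performance summary (all rates in [0, 1])."""

    model_name: str
    accuracy_train: float
    accuracy_test: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc_points: list[tuple[float, float]]
    oob: float | None = None
    positive_class: str | None = None
    seed: int | None = None
    config_digest: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc_points"] = [[float(a), float(b)] for a, b in self.roc_points]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelReport":
        d = json.loads(text)
        d["roc_points"] = [tuple(p) for p in d["roc_points"]]
        return cls(**d)


def config_digest(obj) -> str:
    """Stable short digest of a configuration object for provenance."""
    from dataclasses import is_dataclass

    payload = asdict(obj) if is_dataclass(obj) else obj
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def roc_curve(
    scores: Sequence[float], labels: Sequence, positive_class
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC, sweeping unique scores descending.

    Tied scores contribute a single step, so the AUC equals the
    Mann–Whitney concordance probability with ties counted half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    y = labels == positive_class
    if y.all() or not y.any():
        raise ValueError("ROC undefined: both classes must be present")
    fpr, tpr, _ = skm.roc_curve(y.astype(int), scores)
    auc = float(skm.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def class_scores(model, X, positive_class) -> np.ndarray:
    """Continuous scores oriented so larger ⇒ more likely positive class.

    Falls back to 0/1 predictions (with a warning) for classifiers that
    expose no continuous output.
    """
    Xv = np.asarray(X, dtype=float)
    classes = list(getattr(model, "classes_", []))
    if hasattr(model, "decision_function"):
        s = np.asarray(model.decision_function(Xv), dtype=float)
        if classes and positive_class == classes[0]:
            s = -s
        return s
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(Xv)
        return proba[:, classes.index(positive_class)]
    warnings.warn(
        "model exposes no continuous scores; AUC computed from hard predictions",
        stacklevel=2,
    )
    return (model.predict(Xv) == positive_class).astype(float)


def score_model(
    model,
    X_train,
    y_train,
    X_test,
    y_test,
    positive_class=None,
    name: str = "model",
    seed: int | None = None,
    digest: str | None = None,
) -> ModelReport:
    """Evaluate a fitted two-class model on the train/test partitions.

    The positive class defaults to the alphabetically first label.
    Precision, recall and f1 refer to the positive class on the test
    set; OOB (out-of-bag accuracy) is reported only when the model is a
    bagged ensemble that tracked it.
    """
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise ValueError("empty test set")
    if positive_class is None:
        positive_class = sorted(np.unique(np.concatenate([y_train, y_test])))[0]

    pred_tr = model.predict(np.asarray(X_train, dtype=float))
    pred_te = model.predict(np.asarray(X_test, dtype=float))
    scores = class_scores(model, X_test, positive_class)
    points, auc = roc_curve(scores, y_test, positive_class)

    return ModelReport(
        model_name=name,
        accuracy_train=float(skm.accuracy_score(y_train, pred_tr)),
        accuracy_test=float(skm.accuracy_score(y_test, pred_te)),
        precision=float(
            skm.precision_score(y_test, pred_te, pos_label=positive_class, zero_division=0)
        ),
        recall=float(skm.recall_score(y_test, pred_te, pos_label=positive_class, zero_division=0)),
        f1=float(skm.f1_score(y_test, pred_te, pos_label=positive_class, zero_division=0)),
        auc=auc,
        roc_points=points,
        oob=float(model.oob_score_) if hasattr(model, "oob_score_") else None,
        positive_class=str(positive_class),
        seed=seed,
        config_digest=digest,
    )


def compare_strategies(reports: Sequence[ModelReport]) -> tuple[pd.DataFrame, str]:
    """Rank strategies by (AUC, test accuracy) descending; return the table
    and the best model's name."""
    if not reports:
        raise ValueError("no reports to compare")
    rows = []
    for r in reports:
        rows.append(
            {
                "model": r.model_name,
                "auc": r.auc,
                "oob": r.oob,
                "accuracy_train": r.accuracy_train,
                "accuracy_test": r.accuracy_test,
                "precision": r.precision,
                "f1": r.f1,
                "recall": r.recall,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["auc", "accuracy_test"], ascending=False, kind="mergesort"
    )
    table.index = range(1, len(table) + 1)
    return table, str(table.iloc[0]["model"])


def plot_roc(reports: Sequence[ModelReport], path) -> None:
    """Overlayed ROC curves (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for r in reports:
        pts = np.asarray(r.roc_points)
        ax.plot(pts[:, 0], pts[:, 1], label=f"{r.model_name} (AUC={r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
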