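"""Feature-set assembly and MLP cross-validation protocol.

Eight named feature sets combine the fluency (SSF), fractal (FD1/FD2),
emotional-speech (EF) and Emotional Temperature (ET) columns.  Each set is
evaluated with a single-hidden-layer perceptron (100 neurons, up to 1,000
training steps) under stratified 10-fold cross-validation; the confusion
matrix is accumulated over held-out folds.  Reported measures: global
accuracy, per-class accuracy, per-class classification error rate
(CER = 100 - per-class accuracy) and the accumulative CER (sum over
classes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import InputError

logger = logging.getLogger(__name__)

LABEL_COLUMN = "label"
BINARY_MAP = {"CR": "CR", "ES": "AD", "IS": "AD", "AS": "AD"}

#: Column-prefix composition of each named feature set, in report row order.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "SSF": ("ssf",),
    "SSF+FD1": ("ssf", "fd1"),
    "SSF+FD2": ("ssf", "fd2"),
    "EF": ("esa",),
    "EF+ET": ("esa", "et"),
    "SSF+EF": ("ssf", "esa"),
    "SSF+FD2+EF": ("ssf", "fd2", "esa"),
    "SSF+FD2+EF+ET": ("ssf", "fd2", "esa", "et"),
}

_FD2_COLUMNS = ("fd.mean", "fd.max", "fd.min", "fd.var", "fd.std")
_FD1_COLUMNS = ("fd.mean",)


def _columns_for(block: str, available: list[str]) -> list[str]:
    if block == "fd1":
        cols = list(_FD1_COLUMNS)
    elif block == "fd2":
        cols = list(_FD2_COLUMNS)
    elif block == "et":
        cols = ["et"]
    else:
        cols = [c for c in available if c.startswith(block + ".")]
    missing = [c for c in cols if c not in available]
    if missing or not cols:
        raise InputError(f"feature block {block!r}: missing columns {missing or '(all)'}")
    return cols


def assemble_features(table: pd.DataFrame, set_name: str) -> pd.DataFrame:
    """Select the columns of one named feature set (plus the label column).

    The input is the full per-segment feature table with ``ssf.*``,
    ``fd.*``, ``esa.*`` and ``et`` columns and a ``label`` column.
    """
    if set_name not in FEATURE_SETS:
        raise InputError(f"unknown feature set {set_name!r}; choose from {list(FEATURE_SETS)}")
    if LABEL_COLUMN not in table.columns:
        raise InputError("feature table has no 'label' column")
    if table[LABEL_COLUMN].isna().any():
        bad = table.index[table[LABEL_COLUMN].isna()].tolist()
        raise InputError(f"segments with missing labels: {bad}")
    cols: list[str] = []
    for block in FEATURE_SETS[set_name]:
        cols.extend(_columns_for(block, list(table.columns)))
    sub = table[cols + [LABEL_COLUMN]].copy()
    bad_rows = sub[cols].isna().any(axis=1)
    if bad_rows.any():
        raise InputError(
            f"missing feature values for segments {sub.index[bad_rows].tolist()} in set {set_name}"
        )
    sub.attrs["feature_set_name"] = set_name
    return sub


@dataclass
class ClassificationReport:
    feature_set_name: str
    classes: list[str]
    confusion: np.ndarray  # rows: true, cols: predicted
    folds: int
    seed: int
    acc_pct: float = field(init=False)
    per_class_acc_pct: dict[str, float] = field(init=False)
    cer_per_class_pct: dict[str, float] = field(init=False)
    cer_accumulative_pct: float = field(init=False)

    def __post_init__(self):
        cm = np.asarray(self.confusion, dtype=float)
        total = cm.sum()
        self.acc_pct = 100.0 * np.trace(cm) / total
        row_sums = cm.sum(axis=1)
        per = 100.0 * np.diag(cm) / np.where(row_sums == 0, 1, row_sums)
        self.per_class_acc_pct = {c: float(p) for c, p in zip(self.classes, per)}
        self.cer_per_class_pct = {c: 100.0 - p for c, p in self.per_class_acc_pct.items()}
        self.cer_accumulative_pct = float(sum(self.cer_per_class_pct.values()))

    def to_row(self) -> dict[str, float]:
        row = {
            "feature_set": self.feature_set_name,
            "acc_pct": self.acc_pct,
            "cer_accumulative_pct": self.cer_accumulative_pct,
            "folds": self.folds,
        }
        for c in self.classes:
            row[f"acc_{c}_pct"] = self.per_class_acc_pct[c]
        return row


def train_eval_cv(
    table: pd.DataFrame,
    k: int = 10,
    hidden: int = 100,
    epochs: int = 1000,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified k-fold MLP evaluation of one feature-set table.

    Standardization is fit on each training fold only.  If the smallest
    class has fewer rows than ``k`` the fold count is reduced to it (with a
    warning).  Rows are ordered by (label, index) before folding so the
    report does not depend on input row order.
    """
    y = table[LABEL_COLUMN].astype(str)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise InputError("need at least two classes for classification")
    counts = y.value_counts()
    if counts.min() < 2:
        raise InputError(f"every class needs >= 2 rows, got {counts.to_dict()}")
    k_eff = int(min(k, counts.min()))
    if k_eff < k:
        warnings.warn(f"reducing folds from {k} to {k_eff}: smallest class has {counts.min()} rows",
                      stacklevel=2)

    ordered = table.sort_index(kind="stable").sort_values(LABEL_COLUMN, kind="stable")
    feat_cols = [c for c in ordered.columns if c != LABEL_COLUMN]
    X = ordered[feat_cols].to_numpy(dtype=float)
    yv = ordered[LABEL_COLUMN].astype(str).to_numpy()

    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    y_true_all, y_pred_all = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for fold, (tr, te) in enumerate(skf.split(X, yv)):
            clf = make_pipeline(
                StandardScaler(),
                MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=epochs, random_state=seed),
            )
            clf.fit(X[tr], yv[tr])
            pred = clf.predict(X[te])
            y_true_all.append(yv[te])
            y_pred_all.append(pred)
            logger.debug("fold %d accuracy %.1f%%", fold, 100.0 * np.mean(pred == yv[te]))
    cm = confusion_matrix(np.concatenate(y_true_all), np.concatenate(y_pred_all), labels=classes)
    return ClassificationReport(
        feature_set_name=table.attrs.get("feature_set_name", ""),
        classes=classes, confusion=cm, folds=k_eff, seed=seed,
    )


def run_experiment_matrix(
    table: pd.DataFrame,
    k: int = 10,
    hidden: int = 100,
    epochs: int = 1000,
    seed: int = 0,
    sets=tuple(FEATURE_SETS),
) -> tuple[pd.DataFrame, dict[str, ClassificationReport]]:
    """Evaluate every named feature set on a common segment population.

    Returns the results table (one row per set, in canonical order) and the
    full per-set reports.
    """
    reports: dict[str, ClassificationReport] = {}
    rows = []
    for name in sets:
        sub = assemble_features(table, name)
        rep = train_eval_cv(sub, k=k, hidden=hidden, epochs=epochs, seed=seed)
        reports[name] = rep
        rows.append(rep.to_row())
    return pd.DataFrame(rows), reports


def to_binary(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the four-class labels to control vs impaired (CR vs AD)."""
    out = table.copy()
    out[LABEL_COLUMN] = out[LABEL_COLUMN].map(lambda l: BINARY_MAP.get(l, l))
    return out
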