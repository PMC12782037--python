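"""Jackknife fold combining and classification / regression metric bundles.

Each cross-validation fold's best checkpoint predicts its own holdout
specimens; concatenating the five holdout sets yields one prediction per
clean frame over the complete dataset, on which all metrics are computed
(jackknife-style combining — it reduces metric variance on small datasets).

Classification: per-class and support-weighted precision / recall / F1 and
a row-normalized confusion matrix whose rows sum to 100 (%). A class that
is never predicted gets precision 0, not an error.

Regression (frames as the primary unit, specimen-median as a secondary
view): R^2 = 1 - SS_res/SS_tot (may be negative), MAE and MdAE in mg, MAPE
and MdAPE as fractions of true mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support


class CoverageError(ValueError):
    """Raised when fold predictions overlap or miss curated specimens."""


@dataclass
class ClassificationReport:
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    per_class: pd.DataFrame  # label, precision, recall, f1, support
    confusion_pct: pd.DataFrame  # rows sum to 100
    n_frames: int
    n_specimens: int


@dataclass
class RegressionReport:
    r2: float
    mae_mg: float
    mdae_mg: float
    mape: float  # fraction, not percent
    mdape: float
    n_frames: int
    n_specimens: int


def combine_folds(fold_predictions: list[pd.DataFrame], expected_specimens: list[str]) -> pd.DataFrame:
    """Concatenate per-fold holdout predictions into one full-dataset set."""
    seen: dict[str, int] = {}
    dupes = []
    for i, df in enumerate(fold_predictions):
        for sid in df["specimen_id"].unique():
            if sid in seen:
                dupes.append(sid)
            seen[sid] = i
    missing = sorted(set(expected_specimens) - set(seen))
    if dupes or missing:
        raise CoverageError(
            f"fold coverage broken: duplicated specimens {sorted(set(dupes))}, missing {missing}"
        )
    return pd.concat(fold_predictions, ignore_index=True)


def classification_metrics(pred: pd.DataFrame) -> ClassificationReport:
    """Metrics over frames; needs columns true_label and pred_label."""
    y_true = pred["true_label"].to_numpy()
    y_pred = pred["pred_label"].to_numpy()
    labels = sorted(set(y_true) | set(y_pred))
    p, r, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    wp, wr, wf1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0
    )
    cm = confusion_matrix(y_true, y_pred, labels=labels).astype(float)
    rowsum = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        cm_pct = np.where(rowsum > 0, 100.0 * cm / rowsum, 0.0)
    return ClassificationReport(
        weighted_precision=float(wp),
        weighted_recall=float(wr),
        weighted_f1=float(wf1),
        per_class=pd.DataFrame(
            {"label": labels, "precision": p, "recall": r, "f1": f1, "support": support}
        ),
        confusion_pct=pd.DataFrame(cm_pct, index=labels, columns=labels),
        n_frames=int(len(pred)),
        n_specimens=int(pred["specimen_id"].nunique()) if "specimen_id" in pred else 0,
    )


def group_confusion(pred: pd.DataFrame, rank_map: dict[str, str]) -> ClassificationReport:
    """Relabel species-level predictions at an ancestor rank, then score.

    Confusions between species of the same order vanish at order level —
    the grouped view shows how reliable the coarser identification is.
    """
    missing = (set(pred["true_label"]) | set(pred["pred_label"])) - set(rank_map)
    if missing:
        raise KeyError(f"species missing from taxonomy map: {sorted(missing)}")
    out = pred.copy()
    out["true_label"] = out["true_label"].map(rank_map)
    out["pred_label"] = out["pred_label"].map(rank_map)
    return classification_metrics(out)


def regression_metrics(pred: pd.DataFrame, per_specimen: bool = False) -> RegressionReport:
    """Metrics over frames, or over per-specimen median predictions."""
    if pred.empty:
        raise ValueError("empty prediction set")
    df = pred
    if per_specimen:
        df = (
            pred.groupby("specimen_id")
            .agg(pred_mass_mg=("pred_mass_mg", "median"), true_mass_mg=("true_mass_mg", "first"))
            .reset_index()
        )
    p = df["pred_mass_mg"].to_numpy(dtype=float)
    y = df["true_mass_mg"].to_numpy(dtype=float)
    err = np.abs(p - y)
    ss_res = float(((p - y) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return RegressionReport(
        r2=1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf),
        mae_mg=float(err.mean()),
        mdae_mg=float(np.median(err)),
        mape=float((err / y).mean()),
        mdape=float(np.median(err / y)),
        n_frames=int(len(df)),
        n_specimens=int(pred["specimen_id"].nunique()) if "specimen_id" in pred else len(df),
    )


def regression_table(reports: dict[str, RegressionReport]) -> pd.DataFrame:
    """Plain comparison table: rows = predictors, columns = the five metrics."""
    return pd.DataFrame(
        {
            "predictor": list(reports),
            "MdAPE": [r.mdape for r in reports.values()],
            "MAPE": [r.mape for r in reports.values()],
            "MdAE": [r.mdae_mg for r in reports.values()],
            "MAE": [r.mae_mg for r in reports.values()],
            "R2": [r.r2 for r in reports.values()],
        }
    )
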