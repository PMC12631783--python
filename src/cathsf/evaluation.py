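"""Metrics, bootstrap confidence intervals, and the hyperparameter grid.

The label space is highly unbalanced (a few superfamilies hold most
domains, many hold fewer than ten), so the headline metric is macro F1 —
the unweighted mean of per-class F1, which weighs a ten-domain
superfamily the same as a ten-thousand-domain one.  Accuracy, balanced
accuracy (mean per-class recall over classes present in the truth) and
the multiclass Matthews correlation coefficient are reported alongside.

Confidence intervals use the test-set bootstrap: the (truth, prediction)
pairs are resampled with replacement at full test-set size ``n_boot``
times (default 1000), each metric is recomputed per replicate, and the
half-width is ``z`` × the standard deviation of the replicate values
(z = 1.96 for a 95% interval).  The model is *not* retrained per
replicate; predictions are fixed and only the test sample varies.

All four metrics are computed from the confusion matrix in vectorized
numpy.  A single code path serves both the point estimates and the
bootstrap replicates, which keeps a 1000-replicate bootstrap on a few
thousand samples well under a second.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    ClassifierConfig,
    build_classifier,
    predict_proba,
    train_classifier,
)
from .dataset import FilterConfig, SplitBundle, apply_filter_cascade
from .embedding import EmbeddingStore, build_input_vector
from .errors import ConfigurationError, IntegrityError

__all__ = [
    "MetricReport", "compute_metrics", "bootstrap_ci",
    "run_grid", "assemble_design",
]

_METRICS = ("f1_macro", "accuracy", "balanced_accuracy", "mcc")


@dataclass(frozen=True)
class MetricReport:
    """Point estimates with optional bootstrap CI half-widths."""

    f1_macro: float
    accuracy: float
    balanced_accuracy: float
    mcc: float
    ci_halfwidth: dict[str, float] = field(default_factory=dict)
    n_boot: int = 0
    z: float = 1.96
    n_test: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in ("f1_macro", "accuracy", "balanced_accuracy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise IntegrityError(f"{name}={v} outside [0, 1]")
        if not -1.0 - 1e-12 <= self.mcc <= 1.0 + 1e-12:
            raise IntegrityError(f"mcc={self.mcc} outside [-1, 1]")
        if any(h < 0 for h in self.ci_halfwidth.values()):
            raise IntegrityError("negative CI half-width")


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               n_classes: int) -> np.ndarray:
    return np.bincount(y_true * n_classes + y_pred,
                       minlength=n_classes * n_classes
                       ).reshape(n_classes, n_classes)


def _metrics_from_confusion(cm: np.ndarray) -> tuple[float, float, float, float]:
    """(f1_macro, accuracy, balanced_accuracy, mcc) from a confusion matrix.

    Macro F1 averages over the classes present in truth or predictions;
    a class that occurs but is never predicted correctly contributes
    F1 = 0.  Classes of the label space absent from both sides (e.g.
    filtered out of this test sample) do not dilute the mean.  Balanced
    accuracy averages recall over classes present in the truth only.
    """
    n = cm.sum()
    tp = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)   # true counts per class
    col = cm.sum(axis=0).astype(float)   # predicted counts per class
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, tp / np.maximum(col, 1), 0.0)
        recall = np.where(row > 0, tp / np.maximum(row, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    occurring = (row > 0) | (col > 0)
    f1_macro = float(f1[occurring].mean())
    accuracy = float(tp.sum() / n)
    present = row > 0
    balanced = float(recall[present].mean())
    # multiclass Matthews correlation from the confusion matrix
    s = float(n)
    c = float(tp.sum())
    pt = float(col @ row)
    denom2 = (s * s - float(col @ col)) * (s * s - float(row @ row))
    mcc = 0.0 if denom2 <= 0 else float((c * s - pt) / np.sqrt(denom2))
    return f1_macro, accuracy, balanced, mcc


def _check_labels(y_true, y_pred, n_classes):
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise IntegrityError(
            f"label arrays must be equal-length 1-D; got {y_true.shape} "
            f"and {y_pred.shape}")
    if len(y_true) == 0:
        raise IntegrityError("empty label arrays")
    for nm, y in (("true", y_true), ("predicted", y_pred)):
        if y.min() < 0 or y.max() >= n_classes:
            raise IntegrityError(
                f"{nm} class indices outside [0, {n_classes})")
    return y_true, y_pred


def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                    n_classes: int) -> MetricReport:
    """Point estimates of macro F1, accuracy, balanced accuracy and MCC."""
    y_true, y_pred = _check_labels(y_true, y_pred, n_classes)
    cm = _confusion(y_true, y_pred, n_classes)
    f1, acc, bacc, mcc = _metrics_from_confusion(cm)
    return MetricReport(f1_macro=f1, accuracy=acc, balanced_accuracy=bacc,
                        mcc=mcc, n_test=len(y_true))


def bootstrap_ci(y_true: Sequence[int], y_pred: Sequence[int],
                 n_classes: int, n_boot: int = 1000, z: float = 1.96,
                 seed: int = 0) -> MetricReport:
    """Test-set bootstrap CIs around the unresampled point estimates.

    Half-width per metric = ``z`` × sd over ``n_boot`` replicates, each
    replicate resampling the (truth, prediction) pairs with replacement
    at full test-set size.  Seeded and reproducible.
    """
    if n_boot < 2:
        raise ConfigurationError("n_boot must be >= 2")
    y_true, y_pred = _check_labels(y_true, y_pred, n_classes)
    n = len(y_true)
    if n < 2:
        raise ConfigurationError(
            "bootstrap is undefined for a single-sample test set")
    point = compute_metrics(y_true, y_pred, n_classes)
    rng = np.random.default_rng(seed)
    values = np.empty((n_boot, len(_METRICS)))
    code = y_true * n_classes + y_pred  # one resamplable code per pair
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cm = np.bincount(code[idx], minlength=n_classes * n_classes
                         ).reshape(n_classes, n_classes)
        values[b] = _metrics_from_confusion(cm)
    sd = values.std(axis=0, ddof=1)
    return dc_replace(
        point,
        ci_halfwidth={m: float(z * s) for m, s in zip(_METRICS, sd)},
        n_boot=n_boot, z=z, n_test=n, seed=seed,
    )


def assemble_design(bundle: SplitBundle, store: EmbeddingStore,
                    input_type: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Build (X, y) design matrices per split for one input type.

    AA and 3Di pooled vectors are fetched from the store by domain id and
    concatenated per ``input_type`` (AA then 3Di).  Class indices follow
    the bundle's label-space order.
    """
    index = bundle.class_index()
    out = {}
    for split in ("train", "val", "test"):
        records = getattr(bundle, split)
        vecs, ys = [], []
        for r in records:
            aa = store.get(r.domain_id, "AA") if "AA" in input_type else None
            tdi = store.get(r.domain_id, "3Di") if "3Di" in input_type else None
            vecs.append(build_input_vector(aa, tdi, input_type).vector)
            ys.append(index[r.sf_label])
        out[split] = (np.stack(vecs) if vecs else np.empty((0, 0)),
                      np.asarray(ys, dtype=np.int64))
    return out


_GRID_KEYS = ("n_layer_blocks", "layer_size", "dropout_rate", "input_type",
              "plddt_threshold", "support_threshold")


def run_grid(bundle: SplitBundle, store: EmbeddingStore,
             grid: dict[str, list], base_config: Optional[ClassifierConfig] = None,
             n_boot: int = 200, seed: int = 0,
             out_csv: Optional[str] = None) -> pd.DataFrame:
    """Evaluate every hyperparameter combination and tabulate the results.

    ``grid`` maps a subset of {n_layer_blocks, layer_size, dropout_rate,
    input_type, plddt_threshold, support_threshold} to value lists; the
    cartesian product is evaluated.  Each row records the combination, the
    post-filter dataset sizes, the test metrics with bootstrap half-widths,
    and a status; a failing combination (e.g. a missing channel) is
    recorded as failed and the run continues.  Rows are appended to
    ``out_csv`` as they finish, so a crash loses at most one row.  The
    best completed row by macro F1 is flagged.
    """
    if not grid:
        raise ConfigurationError("empty grid")
    unknown = set(grid) - set(_GRID_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown grid keys: {sorted(unknown)}")
    base = base_config or ClassifierConfig()
    keys = [k for k in _GRID_KEYS if k in grid]
    rows: list[dict] = []
    header_written = out_csv is not None and os.path.exists(out_csv)
    for combo_values in itertools.product(*(grid[k] for k in keys)):
        combo = dict(zip(keys, combo_values))
        input_type = combo.get("input_type", base.input_type)
        row: dict = {k: combo.get(k) for k in _GRID_KEYS}
        row["input_type"] = input_type
        row.setdefault("plddt_threshold", 0.0)
        row.setdefault("support_threshold", 0)
        try:
            fc = FilterConfig(
                plddt_threshold=combo.get("plddt_threshold", 0.0),
                support_threshold=combo.get("support_threshold", 0),
                require_structure="3Di" in input_type,
            )
            fc.validate_for_input_type(input_type)
            filtered = apply_filter_cascade(bundle, fc)
            design = assemble_design(filtered, store, input_type)
            cfg_fields = {k: v for k, v in combo.items()
                          if k in ("n_layer_blocks", "layer_size",
                                   "dropout_rate")}
            cfg = dc_replace(base, input_type=input_type, **cfg_fields)
            model = build_classifier(cfg, design["train"][0].shape[1],
                                     label_space=filtered.label_space)
            train_classifier(model, *design["train"], *design["val"])
            x_test, y_test = design["test"]
            y_hat = predict_proba(model, x_test).argmax(axis=1)
            report = bootstrap_ci(y_test, y_hat, model.n_classes,
                                  n_boot=n_boot, seed=seed)
            row.update({
                "n_layer_blocks": cfg.n_layer_blocks,
                "layer_size": cfg.layer_size,
                "dropout_rate": cfg.dropout_rate,
                "embedder_id": _store_embedders(store, input_type),
                "n_train": len(filtered.train),
                "n_val": len(filtered.val),
                "n_test": len(filtered.test),
                "n_classes": len(filtered.label_space),
                "f1_macro": report.f1_macro,
                "accuracy": report.accuracy,
                "balanced_accuracy": report.balanced_accuracy,
                "mcc": report.mcc,
                **{f"ci_{m}": report.ci_halfwidth[m] for m in _METRICS},
                "status": "ok", "reason": "",
            })
        except Exception as exc:  # noqa: BLE001 — a grid survives bad points
            row.update({"status": "failed",
                        "reason": f"{type(exc).__name__}: {exc}"})
        rows.append(row)
        if out_csv is not None:
            pd.DataFrame([row]).to_csv(out_csv, mode="a", index=False,
                                       header=not header_written)
            header_written = True
    df = pd.DataFrame(rows)
    ok = df["status"] == "ok"
    df["best"] = False
    if ok.any():
        df.loc[df.loc[ok, "f1_macro"].idxmax(), "best"] = True
    return df


def _store_embedders(store: EmbeddingStore, input_type: str) -> str:
    parts = []
    for ch in ("AA", "3Di"):
        if ch in input_type and ch in store._fh:
            parts.append(str(store._fh[ch].attrs.get("embedder_id", "?")))
    return "+".join(parts)
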