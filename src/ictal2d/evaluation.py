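"""Classifier heads, evaluation metrics, and experiment designs.

Metrics follow the standard confusion-matrix definitions with the seizure
class positive:

    accuracy    = (TP + TN) / (TP + TN + FP + FN) x 100%
    sensitivity = TP / (TP + FN) x 100%
    specificity = TN / (TN + FP) x 100%

Two experiment designs are provided: *intrapatient* (all subjects pooled,
class-balanced 1:1, randomly partitioned into train/validation/test) and
*interpatient* (entire subjects held out of training, the
leave-subject-out protocol). ``run_experiment`` sweeps windows x frequency
bands x network levels and reports repeat-averaged metrics per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .eeg_io import EEGRecord, SEIZURE
from .features import (DEFAULT_TOTAL_SCALE, DEFAULT_WAVELET, WindowConfig,
                       cwt_scalogram, fft_band_features, slice_record)
from .network import (Network, TrainConfig, build_network, predict_logits,
                      extract_depth_features, spec_for_level, tiny_spec, train)
from .representation import (render_matrix_image, render_scalogram_image,
                             to_net_input)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total < 1:
            raise ValueError("confusion counts must cover at least one case")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class EvalResult:
    """Percentage metrics; a metric whose denominator is zero is None
    (undefined), never 0."""

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float | None
    specificity: float | None

    def __str__(self) -> str:
        def fmt(v):
            return "undefined" if v is None else f"{v:.2f}"

        return (f"Acc {fmt(self.accuracy)}% | Sen {fmt(self.sensitivity)}% | "
                f"Spe {fmt(self.specificity)}%")


def compute_metrics(counts: ConfusionCounts) -> EvalResult:
    """Accuracy, sensitivity and specificity (percent) from counts."""
    c = counts
    accuracy = (c.TP + c.TN) / c.total * 100.0
    sensitivity = c.TP / (c.TP + c.FN) * 100.0 if c.TP + c.FN > 0 else None
    specificity = c.TN / (c.TN + c.FP) * 100.0 if c.TN + c.FP > 0 else None
    return EvalResult(counts=c, accuracy=accuracy, sensitivity=sensitivity,
                      specificity=specificity)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray
                               ) -> ConfusionCounts:
    """Counts with label 1 = seizure (positive class)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y_pred == 1) & (y_true == 1))),
        FP=int(np.sum((y_pred == 1) & (y_true == 0))),
        TN=int(np.sum((y_pred == 0) & (y_true == 0))),
        FN=int(np.sum((y_pred == 0) & (y_true == 1))),
    )


# ---------------------------------------------------------------------------
# Classifier heads
# ---------------------------------------------------------------------------

class FeatureClassifier:
    """A classifier head over depth features: softmax (the network's own
    fully-connected head), KNN, or SVM."""

    def __init__(self, head: str = "softmax", head_params: dict | None = None,
                 net: Network | None = None, seed: int = 0):
        if head not in ("softmax", "knn", "svm"):
            raise ValueError(f"unknown head {head!r}")
        if head == "softmax" and net is None:
            raise ValueError("the softmax head requires the trained network")
        self.head = head
        self.head_params = dict(head_params or {})
        self.net = net
        self.seed = seed
        self._model = None
        self._fitted = head == "softmax"  # the network head is already fit

    def fit(self, features: np.ndarray, labels: np.ndarray
            ) -> "FeatureClassifier":
        if self.head == "softmax":
            return self
        if self.head == "knn":
            from sklearn.neighbors import KNeighborsClassifier

            self._model = KNeighborsClassifier(
                n_neighbors=self.head_params.get("k", 5)
            )
        else:
            from sklearn.svm import SVC

            self._model = SVC(
                kernel=self.head_params.get("kernel", "rbf"),
                C=self.head_params.get("C", 1.0),
                random_state=self.seed,
            )
        self._model.fit(np.asarray(features), np.asarray(labels))
        self._fitted = True
        return self

    def predict(self, features: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
        """Predicted labels and per-item scores (probabilities for softmax,
        neighbor fractions for KNN, decision values for SVM)."""
        if not self._fitted or (self.head != "softmax" and self._model is None):
            raise RuntimeError(f"{self.head} head has not been fit")
        features = np.asarray(features, dtype=np.float32)
        if self.head == "softmax":
            logits = features @ self.net.fc.weight.data + self.net.fc.bias.data
            z = logits - logits.max(axis=1, keepdims=True)
            probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            return probs.argmax(axis=1), probs[:, 1]
        if self.head == "knn":
            probs = self._model.predict_proba(features)
            return self._model.predict(features), probs[:, -1]
        scores = self._model.decision_function(features)
        return self._model.predict(features), scores


def classify_features(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    head: str = "svm",
    head_params: dict | None = None,
    net: Network | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a head on training depth features and apply it to test features."""
    clf = FeatureClassifier(head=head, head_params=head_params, net=net,
                            seed=seed)
    clf.fit(train_features, train_labels)
    return clf.predict(test_features)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    mode: str = "intrapatient"  # or "interpatient"
    window_s: tuple[float, ...] = (1.0,)
    overlap_frac: float = 0.5
    bands: tuple = (None,)  # (lo, hi) tuples, or None for the CWT scalogram
    levels: tuple = ("tiny",)  # network levels 0..7 or "tiny"
    repeats: int = 5
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    balance: bool = True
    label_rule: float = 1.0
    wavelet: str = DEFAULT_WAVELET
    total_scale: int = DEFAULT_TOTAL_SCALE
    held_out: tuple[str, ...] | None = None  # interpatient: subjects to hold out
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("intrapatient", "interpatient"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _labels_of(items) -> np.ndarray:
    return np.asarray([it.label == SEIZURE for it in items], dtype=int)


def _balance_classes(items: list, rng: np.random.Generator) -> list:
    """Random down-sample the majority class to a 1:1 ratio."""
    pos = [it for it in items if it.label == SEIZURE]
    neg = [it for it in items if it.label != SEIZURE]
    if not pos or not neg:
        raise ValueError("both classes must be present to balance 1:1")
    k = min(len(pos), len(neg))
    pos = [pos[i] for i in rng.choice(len(pos), size=k, replace=False)]
    neg = [neg[i] for i in rng.choice(len(neg), size=k, replace=False)]
    return pos + neg


def split_intrapatient(
    slices: list,
    cfg: ExperimentConfig,
    seed: int | None = None,
) -> tuple[list, list, list]:
    """Pool all subjects, optionally balance 1:1, and randomly partition.

    The partition is stratified per class so train/validation/test class
    ratios stay 1:1 (within one slice) when balancing is on. Deterministic
    given the seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    items = list(slices)
    if not items:
        raise ValueError("no slices to split")
    if cfg.balance:
        items = _balance_classes(items, rng)
    elif not (any(it.label == SEIZURE for it in items)
              and any(it.label != SEIZURE for it in items)):
        raise ValueError("both classes must be present")
    f_train, f_val, _ = cfg.split
    train_l, val_l, test_l = [], [], []
    by_class = {}
    for it in items:
        by_class.setdefault(it.label, []).append(it)
    for cls_items in by_class.values():
        order = rng.permutation(len(cls_items))
        n = len(cls_items)
        n_train = int(round(f_train * n))
        n_val = int(round(f_val * n))
        idx_train = order[:n_train]
        idx_val = order[n_train:n_train + n_val]
        idx_test = order[n_train + n_val:]
        train_l += [cls_items[i] for i in idx_train]
        val_l += [cls_items[i] for i in idx_val]
        test_l += [cls_items[i] for i in idx_test]
    for part in (train_l, val_l, test_l):
        rng.shuffle(part)
    return train_l, val_l, test_l


def split_interpatient(slices: list, held_out: str | list[str]
                       ) -> tuple[list, list]:
    """Hold entire subjects out: their slices form the test set, everyone
    else's form the train+validation pool. No subject crosses the boundary."""
    held = {held_out} if isinstance(held_out, str) else set(held_out)
    subjects = {it.source[0] for it in slices}
    unknown = held - subjects
    if unknown:
        raise ValueError(
            f"unknown subject id(s) {sorted(unknown)}; "
            f"available: {sorted(subjects)}"
        )
    pool = [it for it in slices if it.source[0] not in held]
    test = [it for it in slices if it.source[0] in held]
    return pool, test


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

@dataclass
class _IndexedSlice:
    """Lightweight stand-in pairing a slice's label/provenance with its row
    in the precomputed input tensor."""

    label: str
    source: tuple[str, str]
    index: int


def slices_to_net_inputs(
    slices: list,
    band: tuple[float, float] | None,
    resolution: int,
    wavelet: str = DEFAULT_WAVELET,
    total_scale: int = DEFAULT_TOTAL_SCALE,
    scalogram_render_res: int | None = None,
) -> np.ndarray:
    """Run feature extraction + 2D representation + resize/normalize for a
    list of slices, returning an (N, 3, R, R) array.

    ``band=None`` selects the CWT scalogram route (single-channel slices);
    a (lo, hi) band selects the per-channel FFT route.
    """
    out = np.empty((len(slices), 3, resolution, resolution), dtype=np.float32)
    render_res = scalogram_render_res or resolution
    for i, slc in enumerate(slices):
        if band is None:
            fm = cwt_scalogram(slc, wavelet, total_scale)
            img = render_scalogram_image(fm, out_res=render_res,
                                         label=slc.label)
        else:
            fm = fft_band_features(slc, band)
            img = render_matrix_image(fm, label=slc.label)
        out[i] = to_net_input(img, resolution).tensor
    return out


def _network_for(level, seed: int) -> Network:
    spec = tiny_spec() if level == "tiny" else spec_for_level(int(level))
    return build_network(spec, seed=seed)


def _evaluate_once(
    x: np.ndarray,
    train_items: list[_IndexedSlice],
    val_items: list[_IndexedSlice],
    test_items: list[_IndexedSlice],
    level,
    train_cfg: TrainConfig,
    seed: int,
) -> EvalResult:
    net = _network_for(level, seed)
    idx = lambda items: np.asarray([it.index for it in items])
    tr, va, te = idx(train_items), idx(val_items), idx(test_items)
    cfg = replace(train_cfg, seed=seed)
    net, _ = train(net, (x[tr], _labels_of(train_items)),
                   (x[va], _labels_of(val_items)), cfg)
    preds = predict_logits(net, x[te]).argmax(axis=1)
    return compute_metrics(
        confusion_from_predictions(_labels_of(test_items), preds)
    )


def run_experiment(cfg: ExperimentConfig, records: list[EEGRecord]
                   ) -> pd.DataFrame:
    """Sweep windows x bands x levels; per cell, run the full pipeline
    ``repeats`` times and report mean metrics.

    A failure in one cell logs the reason and leaves NaN metrics for that
    cell; the sweep continues.
    """
    rows = []
    for window_s in cfg.window_s:
        for band in cfg.bands:
            wc = WindowConfig(window_s=window_s, overlap_frac=cfg.overlap_frac)
            try:
                all_slices = [
                    s for rec in records
                    for s in slice_record(rec, wc, cfg.label_rule)
                ]
            except Exception as exc:
                logger.warning("slicing failed for window %s: %s", window_s, exc)
                all_slices, slice_err = None, str(exc)
            for level in cfg.levels:
                row = {"mode": cfg.mode, "window_s": window_s,
                       "band": None if band is None else f"{band[0]}-{band[1]}",
                       "level": str(level)}
                if all_slices is None:
                    row.update(accuracy=np.nan, sensitivity=np.nan,
                               specificity=np.nan, error=slice_err)
                    rows.append(row)
                    continue
                try:
                    row.update(
                        _run_cell(cfg, all_slices, band, level)
                    )
                except Exception as exc:
                    logger.warning(
                        "cell (window=%s, band=%s, level=%s) failed: %s",
                        window_s, band, level, exc,
                    )
                    row.update(accuracy=np.nan, sensitivity=np.nan,
                               specificity=np.nan, error=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)


def _mean_or_nan(values) -> float:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else float("nan")


def _run_cell(cfg: ExperimentConfig, all_slices: list, band, level) -> dict:
    resolution = (tiny_spec().input_resolution if level == "tiny"
                  else spec_for_level(int(level)).input_resolution)
    x = slices_to_net_inputs(all_slices, band, resolution,
                             cfg.wavelet, cfg.total_scale)
    items = [_IndexedSlice(s.label, s.source, i)
             for i, s in enumerate(all_slices)]
    results: list[EvalResult] = []
    for rep in range(cfg.repeats):
        seed = cfg.seed + rep
        if cfg.mode == "intrapatient":
            tr, va, te = split_intrapatient(items, cfg, seed=seed)
            results.append(
                _evaluate_once(x, tr, va, te, level, cfg.train, seed)
            )
        else:
            held = (cfg.held_out if cfg.held_out
                    else sorted({it.source[0] for it in items}))
            for subject in held:
                pool, test = split_interpatient(items, subject)
                rng = np.random.default_rng(seed)
                if cfg.balance:
                    pool = _balance_classes(pool, rng)
                    test = _balance_classes(test, rng)
                f_train, f_val, _ = cfg.split
                frac = f_train / (f_train + f_val)
                pool_cfg = replace(
                    cfg, split=(frac, 1.0 - frac, 0.0), balance=False
                )
                tr, va, _empty = split_intrapatient(pool, pool_cfg, seed=seed)
                results.append(
                    _evaluate_once(x, tr, va, test, level, cfg.train, seed)
                )
    return {
        "accuracy": _mean_or_nan([r.accuracy for r in results]),
        "sensitivity": _mean_or_nan([r.sensitivity for r in results]),
        "specificity": _mean_or_nan([r.specificity for r in results]),
        "n_runs": len(results),
        "n_test": int(np.mean([r.counts.total for r in results])),
        "error": "",
    }
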