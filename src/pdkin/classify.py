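"""Leakage-aware repeated cross-validation for subtype classification.

Two split schemes mirror the deployment scenarios:

* ``user_independent`` — participants are partitioned 50/20/30 into
  train/validation/test (stratified by subtype), so no participant's
  windows appear in more than one partition;
* ``user_dependent`` — windows are partitioned 50/20/30 *within* each
  participant; any validation/test window that shares frames with, or is
  the immediate window-index neighbor of, a training window from the same
  session is removed, so overlapping-window similarity cannot leak into
  the evaluation.

Because the 50/20/30 fractions do not correspond to a literal k-fold
rotation, each of the ``n_folds x n_repeats`` evaluations re-draws an
independent partition from a per-(repeat, fold) child seed; "5-fold,
50 repeats" then means 250 independently drawn evaluations, which is what
the Wilson interval at N = 250 summarizes.

Hyperparameters are tuned once (randomized search scored on the validation
partition of the first split) and the chosen configuration is reused
across all repeats.  Feature standardization statistics are always
computed on the training partition only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import (
    DegenerateFoldError,
    InfeasibleExperimentError,
    InfeasibleSplitError,
    InvalidArgumentError,
    ValidationError,
)

MODEL_TYPES = ("rf", "rbfsvm", "mlp")
SCHEMES = ("user_independent", "user_dependent")

#: Positive class for the binary F1 (the majority clinical target).
POSITIVE_CLASS = "PIGD"


def child_seed(seed: int, *keys: int) -> int:
    """Deterministic child seed derivation (SeedSequence-based, < 2^31)."""
    ss = np.random.SeedSequence([int(seed), *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SplitSpec:
    """Cross-validation layout: scheme, fractions and repetition counts."""

    scheme: str = "user_independent"
    fractions: tuple[float, float, float] = (0.50, 0.20, 0.30)
    n_folds: int = 5
    n_repeats: int = 50
    seed: int = 0
    window_s: float = 4.0
    step_s: float = 3.0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise InvalidArgumentError(f"unknown scheme {self.scheme!r}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise InvalidArgumentError("fractions must sum to 1")
        if self.n_folds < 1 or self.n_repeats < 1:
            raise InvalidArgumentError("n_folds and n_repeats must be >= 1")


@dataclass
class Dataset:
    """Row-aligned window features, labels and provenance."""

    X: np.ndarray  # (n_windows, n_features)
    y: np.ndarray  # binary subtype labels
    feature_names: list[str]
    participant_ids: np.ndarray
    session_ids: np.ndarray
    window_index: np.ndarray
    fog_scores: dict[str, int] = field(default_factory=dict)
    session_type: str | None = None

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for name in ("y", "participant_ids", "session_ids", "window_index"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} is not row-aligned with X")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains non-finite values")

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame,
                           feature_cols: list[str] | None = None,
                           label_col: str = "label",
                           session_type: str | None = None) -> "Dataset":
        meta = {"participant_id", "session_id", "session_type", "window_index",
                "start_time", "label", "fog_score"}
        if feature_cols is None:
            feature_cols = [c for c in table.columns if c not in meta]
        fog = {}
        if "fog_score" in table.columns:
            fog = (table.dropna(subset=["fog_score"])
                   .groupby("participant_id")["fog_score"].first()
                   .astype(int).to_dict())
        if session_type is None and "session_type" in table.columns:
            uniq = table["session_type"].dropna().unique()
            session_type = uniq[0] if len(uniq) == 1 else None
        return cls(
            X=table[feature_cols].to_numpy(float),
            y=table[label_col].to_numpy(str),
            feature_names=list(feature_cols),
            participant_ids=table["participant_id"].to_numpy(str),
            session_ids=table["session_id"].to_numpy(str),
            window_index=table["window_index"].to_numpy(int),
            fog_scores=fog,
            session_type=session_type,
        )

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def participant_labels(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for pid, lab in zip(self.participant_ids, self.y):
            out.setdefault(pid, lab)
        return out

    def select_features(self, names: list[str]) -> "Dataset":
        """Column subset in the dataset's own order; unknown names raise."""
        unknown = [n for n in names if n not in self.feature_names]
        if unknown:
            raise ValidationError(f"unknown feature name(s): {unknown[:5]}")
        keep = [n for n in self.feature_names if n in set(names)]
        cols = [self.feature_names.index(n) for n in keep]
        return Dataset(X=self.X[:, cols], y=self.y, feature_names=keep,
                       participant_ids=self.participant_ids,
                       session_ids=self.session_ids,
                       window_index=self.window_index,
                       fog_scores=dict(self.fog_scores),
                       session_type=self.session_type)

    def filter_fog(self, fog_included: bool) -> "Dataset":
        """Keep all participants, or only those with FOG score 0."""
        if fog_included:
            return self
        keep_pids = {p for p, s in self.fog_scores.items() if s == 0}
        mask = np.isin(self.participant_ids, sorted(keep_pids))
        return Dataset(X=self.X[mask], y=self.y[mask],
                       feature_names=list(self.feature_names),
                       participant_ids=self.participant_ids[mask],
                       session_ids=self.session_ids[mask],
                       window_index=self.window_index[mask],
                       fog_scores={p: s for p, s in self.fog_scores.items()
                                   if p in keep_pids},
                       session_type=self.session_type)

    def permute_labels(self, seed: int) -> "Dataset":
        """Shuffle subtype labels at the participant level (null model)."""
        rng = np.random.default_rng(seed)
        plabels = self.participant_labels()
        pids = sorted(plabels)
        shuffled = rng.permutation([plabels[p] for p in pids])
        mapping = dict(zip(pids, shuffled))
        y = np.array([mapping[p] for p in self.participant_ids])
        return Dataset(X=self.X, y=y, feature_names=list(self.feature_names),
                       participant_ids=self.participant_ids,
                       session_ids=self.session_ids,
                       window_index=self.window_index,
                       fog_scores=dict(self.fog_scores),
                       session_type=self.session_type)


def _partition_counts(n: int, fractions: tuple[float, float, float]
                      ) -> tuple[int, int, int]:
    n_tr = max(int(round(fractions[0] * n)), 1)
    n_val = max(int(round(fractions[1] * n)), 1)
    if n_tr + n_val >= n:
        n_tr = max(n - 2, 1)
        n_val = 1
    return n_tr, n_val, n - n_tr - n_val


def make_splits(dataset: Dataset, spec: SplitSpec, fold: int, repeat: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one train/val/test partition of window row indices.

    Deterministic per ``(spec.seed, repeat, fold)``.
    """
    rng = np.random.default_rng(child_seed(spec.seed, repeat, fold))
    if dataset.n_windows == 0:
        raise InfeasibleSplitError("empty dataset")
    plabels = dataset.participant_labels()
    classes = sorted(set(plabels.values()))
    if len(classes) < 2:
        raise InfeasibleSplitError("dataset must contain both classes")

    if spec.scheme == "user_independent":
        part: dict[str, str] = {}
        for cls in classes:
            pids = sorted(p for p, lab in plabels.items() if lab == cls)
            if len(pids) < spec.n_folds:
                raise InfeasibleSplitError(
                    f"class {cls} has {len(pids)} participants "
                    f"(< n_folds = {spec.n_folds})")
            pids = list(rng.permutation(pids))
            n_tr, n_val, _ = _partition_counts(len(pids), spec.fractions)
            for i, p in enumerate(pids):
                part[p] = ("train" if i < n_tr
                           else "val" if i < n_tr + n_val else "test")
        assign = np.array([part[p] for p in dataset.participant_ids])
        return (np.flatnonzero(assign == "train"),
                np.flatnonzero(assign == "val"),
                np.flatnonzero(assign == "test"))

    # user_dependent: window-level partition within participants, then
    # adjacency/overlap exclusion of val/test windows.
    train_idx, val_idx, test_idx = [], [], []
    for pid in sorted(set(dataset.participant_ids)):
        rows = np.flatnonzero(dataset.participant_ids == pid)
        rows = rng.permutation(rows)
        n_tr, n_val, _ = _partition_counts(len(rows), spec.fractions)
        train_idx += list(rows[:n_tr])
        val_idx += list(rows[n_tr:n_tr + n_val])
        test_idx += list(rows[n_tr + n_val:])
    train_idx = np.array(sorted(train_idx), dtype=int)

    # overlap in frames: |delta window_index| * step < window length;
    # immediate neighbors (|delta| == 1) are excluded regardless.
    max_gap = max(int(math.ceil(spec.window_s / spec.step_s)) - 1, 1)
    train_keys = {(dataset.session_ids[i], int(dataset.window_index[i]))
                  for i in train_idx}

    def clean(indices: list[int]) -> np.ndarray:
        kept = []
        for i in indices:
            sid = dataset.session_ids[i]
            wi = int(dataset.window_index[i])
            if any((sid, wi + d) in train_keys
                   for d in range(-max_gap, max_gap + 1) if d != 0):
                continue
            kept.append(i)
        return np.array(sorted(kept), dtype=int)

    val_idx = clean(val_idx)
    test_idx = clean(test_idx)
    if len(test_idx) == 0 or len(val_idx) == 0:
        raise InfeasibleSplitError(
            "adjacency exclusion removed all validation/test windows; "
            "need more windows per session")
    return train_idx, val_idx, test_idx


# ---------------------------------------------------------------------------
# Models and metrics
# ---------------------------------------------------------------------------

def _sample_params(model_type: str, rng: np.random.Generator) -> dict[str, Any]:
    if model_type == "rf":
        return {
            "n_estimators": int(rng.integers(100, 501)),
            "max_depth": rng.choice([None, *range(5, 21)]),
            "max_features": str(rng.choice(["sqrt", "log2"])),
        }
    if model_type == "rbfsvm":
        return {
            "C": float(10 ** rng.uniform(-2, 3)),
            "gamma": float(10 ** rng.uniform(-4, 1)),
        }
    if model_type == "mlp":
        n_layers = int(rng.integers(1, 3))
        sizes = tuple(int(rng.choice([32, 64, 128])) for _ in range(n_layers))
        return {"hidden_layer_sizes": sizes,
                "alpha": float(10 ** rng.uniform(-5, -2))}
    raise InvalidArgumentError(f"unknown model_type {model_type!r}")


class _AdaptiveEarlyStoppingMLP(MLPClassifier):
    """MLP with early stopping only when the data can spare a validation split.

    Early stopping restores the best-validation iterate; with fewer than
    ~200 training samples the internal 10% split is too small to rank
    iterates and the restored network can underfit, so plain
    tolerance-based training is used instead.
    """

    def fit(self, X, y):  # noqa: D102 - sklearn signature
        self.early_stopping = len(X) >= 200
        return super().fit(X, y)


def build_model(model_type: str, params: dict[str, Any] | None = None,
                seed: int = 0) -> Pipeline:
    """StandardScaler + classifier pipeline (scaler fit on train folds only)."""
    params = dict(params or {})
    if model_type == "rf":
        md = params.pop("max_depth", None)
        est = RandomForestClassifier(
            random_state=seed, n_jobs=1,
            max_depth=None if md is None or (isinstance(md, float)
                                             and math.isnan(md)) else int(md),
            **params)
    elif model_type == "rbfsvm":
        est = SVC(kernel="rbf", random_state=seed, **params)
    elif model_type == "mlp":
        est = _AdaptiveEarlyStoppingMLP(random_state=seed, max_iter=400,
                                        **params)
    else:
        raise InvalidArgumentError(f"unknown model_type {model_type!r}")
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def binary_f1(predictions: np.ndarray, truth: np.ndarray,
              positive_class: str = POSITIVE_CLASS) -> float:
    """F1 = 2PR/(P+R) for the positive class; 0 when there are no TPs."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise InvalidArgumentError("predictions and truth differ in length")
    tp = int(np.sum((predictions == positive_class) & (truth == positive_class)))
    fp = int(np.sum((predictions == positive_class) & (truth != positive_class)))
    fn = int(np.sum((predictions != positive_class) & (truth == positive_class)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def wilson_interval(p_hat: float, n: int = 250,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a proportion (no continuity correction)."""
    if not 0 <= p_hat <= 1:
        raise InvalidArgumentError("p_hat must be in [0, 1]")
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if not 0 < confidence < 1:
        raise InvalidArgumentError("confidence must be in (0, 1)")
    z = float(stats.norm.ppf(1 - (1 - confidence) / 2))
    denom = 1 + z * z / n
    center = (p_hat + z * z / (2 * n)) / denom
    half = z * math.sqrt(p_hat * (1 - p_hat) / n + z * z / (4 * n * n)) / denom
    lo = max(center - half, 0.0)
    hi = min(center + half, 1.0)
    # snap float residue at the closed-form boundaries (p_hat of 0 or 1)
    if lo < 1e-12:
        lo = 0.0
    if hi > 1 - 1e-12:
        hi = 1.0
    return lo, hi


def tune_and_train(X_train: np.ndarray, y_train: np.ndarray,
                   X_val: np.ndarray, y_val: np.ndarray,
                   model_type: str, n_draws: int = 25, seed: int = 0,
                   positive_class: str = POSITIVE_CLASS
                   ) -> tuple[Pipeline, dict[str, Any], float]:
    """Randomized search scored by validation F1; returns the refit winner."""
    if len(set(y_train)) < 2:
        raise DegenerateFoldError("training fold contains a single class")
    rng = np.random.default_rng(child_seed(seed, 7))
    best: tuple[float, dict[str, Any]] | None = None
    for d in range(n_draws):
        params = _sample_params(model_type, rng)
        model = build_model(model_type, params, seed=child_seed(seed, 11, d))
        model.fit(X_train, y_train)
        f1 = binary_f1(model.predict(X_val), y_val, positive_class)
        if best is None or f1 > best[0]:
            best = (f1, params)
    assert best is not None
    final = build_model(model_type, best[1], seed=child_seed(seed, 13))
    final.fit(X_train, y_train)
    return final, best[1], best[0]


@dataclass
class CVResult:
    """Per-fold F1 values with Wilson interval and full provenance."""

    fold_f1: np.ndarray
    mean_f1: float
    wilson: tuple[float, float]
    model_type: str
    scheme: str
    session_type: str | None
    fog_included: bool
    best_params: dict[str, Any]
    positive_class: str = POSITIVE_CLASS
    n_folds: int = 5
    n_repeats: int = 50

    def to_dict(self) -> dict[str, Any]:
        return {
            "mean_f1": self.mean_f1,
            "wilson_lo": self.wilson[0],
            "wilson_hi": self.wilson[1],
            "model_type": self.model_type,
            "scheme": self.scheme,
            "session_type": self.session_type,
            "fog_included": self.fog_included,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "positive_class": self.positive_class,
            "best_params": {k: (None if v is None else
                                v if not isinstance(v, tuple) else list(v))
                            for k, v in self.best_params.items()},
            "fold_f1": [float(v) for v in self.fold_f1],
        }


def run_experiment(dataset: Dataset, spec: SplitSpec, model_type: str,
                   fog_included: bool = True, n_search: int = 25,
                   positive_class: str = POSITIVE_CLASS,
                   tuned_params: dict[str, Any] | None = None) -> CVResult:
    """Repeated cross-validated evaluation of one configuration.

    FOG filtering (when ``fog_included`` is False, only participants with
    FOG score 0 are kept) is applied before splitting.  Hyperparameters
    are tuned once on the first split's validation partition and reused
    across all ``n_repeats x n_folds`` evaluations.
    """
    if model_type not in MODEL_TYPES:
        raise InvalidArgumentError(f"unknown model_type {model_type!r}")
    ds = dataset.filter_fog(fog_included)
    if len(set(ds.y)) < 2 or ds.n_windows == 0:
        raise InfeasibleExperimentError(
            "fewer than two classes remain after FOG filtering")

    if tuned_params is None:
        tr, va, _ = make_splits(ds, spec, fold=0, repeat=0)
        _, tuned_params, _ = tune_and_train(
            ds.X[tr], ds.y[tr], ds.X[va], ds.y[va], model_type,
            n_draws=n_search, seed=spec.seed, positive_class=positive_class)

    fold_f1 = []
    for repeat in range(spec.n_repeats):
        for fold in range(spec.n_folds):
            tr, _, te = make_splits(ds, spec, fold=fold, repeat=repeat)
            if len(set(ds.y[tr])) < 2:
                raise DegenerateFoldError(
                    f"single-class training fold (repeat {repeat}, fold {fold})")
            model = build_model(model_type, tuned_params,
                                seed=child_seed(spec.seed, repeat, fold, 17))
            model.fit(ds.X[tr], ds.y[tr])
            fold_f1.append(binary_f1(model.predict(ds.X[te]), ds.y[te],
                                     positive_class))
    fold_f1 = np.asarray(fold_f1)
    mean_f1 = float(fold_f1.mean())
    return CVResult(fold_f1=fold_f1, mean_f1=mean_f1,
                    wilson=wilson_interval(mean_f1, n=len(fold_f1)),
                    model_type=model_type, scheme=spec.scheme,
                    session_type=ds.session_type, fog_included=fog_included,
                    best_params=dict(tuned_params),
                    n_folds=spec.n_folds, n_repeats=spec.n_repeats)
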