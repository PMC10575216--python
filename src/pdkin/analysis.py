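"""Feature-importance and feature-correlation analyses.

Random-forest feature relevance is measured by mean decrease in impurity
(MDI): the Gini impurity ``1 - sum_i p_i^2`` reduction introduced by each
feature's splits, accumulated within each tree and averaged over the
ensemble, normalized to sum to one.  Top features can then be correlated
(Pearson) with the tremor- and gait-related MDS-UPDRS component scores to
interpret what the classifier keys on.  Correlations are computed over
analysis windows, which overlap in time — the samples are not independent
and the output carries that caveat in its metadata.

``restricted_set_experiment`` reruns a classification experiment with a
restricted feature or marker set (e.g. only thigh+shank markers), the
ablation used to ask how small an instrumentation set still separates the
subtypes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline

from .classify import POSITIVE_CLASS, CVResult, Dataset, SplitSpec, run_experiment
from .errors import InvalidArgumentError, UnsupportedModelError, ValidationError
from .features import FEATURE_NAMES
from .mocap import AXES


def gini_impurity(class_probs: np.ndarray) -> float:
    """Gini impurity ``1 - sum_i p_i^2`` of a class distribution."""
    p = np.asarray(class_probs, dtype=float)
    if p.size == 0 or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise InvalidArgumentError("class_probs must be a probability vector")
    return float(1.0 - (p ** 2).sum())


def _unwrap_forest(model: Any) -> RandomForestClassifier:
    if isinstance(model, Pipeline):
        model = model.named_steps.get("model", model)
    if not (hasattr(model, "estimators_") and hasattr(model, "feature_importances_")):
        raise UnsupportedModelError(
            "MDI importance requires a fitted tree ensemble "
            f"(got {type(model).__name__})")
    return model


def mdi_importance(model: Any, feature_names: list[str],
                   metadata: dict[str, Any] | None = None) -> pd.DataFrame:
    """Mean-decrease-in-impurity ranking for a fitted random forest.

    Returns a DataFrame ``(feature, mdi)`` sorted by non-increasing score;
    scores are >= 0 and sum to 1.  ``metadata`` (model/session/FOG
    provenance) is attached to ``DataFrame.attrs``.
    """
    forest = _unwrap_forest(model)
    imp = np.asarray(forest.feature_importances_, dtype=float)
    if len(imp) != len(feature_names):
        raise ValidationError(
            f"{len(feature_names)} names for {len(imp)} features")
    total = imp.sum()
    if total > 0:
        imp = imp / total
    df = (pd.DataFrame({"feature": feature_names, "mdi": imp})
          .sort_values("mdi", ascending=False, kind="mergesort")
          .reset_index(drop=True))
    df.attrs["metadata"] = dict(metadata or {})
    return df


def feature_score_correlation(feature_table: pd.DataFrame,
                              component_scores: pd.DataFrame,
                              score_kind: str = "tremor",
                              feature_cols: list[str] | None = None,
                              participant_mean: bool = False) -> pd.DataFrame:
    """Pearson correlation of each feature with a UPDRS component score.

    ``component_scores`` must have columns ``participant_id`` and
    ``tremor_score``/``gait_score``.  By default every window is a sample
    (matching how the features enter the classifier; windows overlap, so
    samples are *not* independent — recorded in ``attrs``).  With
    ``participant_mean`` features are first averaged per participant.
    """
    if score_kind not in ("tremor", "gait"):
        raise InvalidArgumentError("score_kind must be 'tremor' or 'gait'")
    col = f"{score_kind}_score"
    if col not in component_scores.columns:
        raise ValidationError(f"component_scores lacks column {col!r}")
    meta = {"participant_id", "session_id", "session_type", "window_index",
            "start_time", "label", "fog_score"}
    if feature_cols is None:
        feature_cols = [c for c in feature_table.columns if c not in meta]
    df = feature_table.merge(
        component_scores[["participant_id", col]], on="participant_id",
        how="inner")
    if participant_mean:
        df = df.groupby("participant_id")[feature_cols + [col]].mean()
    if len(df) < 3:
        raise InvalidArgumentError("need at least 3 samples for correlation")
    y = df[col].to_numpy(float)
    ysd = y.std()
    rows = []
    for feat in feature_cols:
        x = df[feat].to_numpy(float)
        xsd = x.std()
        if xsd == 0 or ysd == 0:
            rows.append({"feature": feat, "r": 0.0, "zero_variance": True})
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"feature": feat, "r": r, "zero_variance": False})
    out = pd.DataFrame(rows)
    out = out.reindex(out["r"].abs().sort_values(ascending=False).index)
    out = out.reset_index(drop=True)
    out.attrs["metadata"] = {
        "score_kind": score_kind,
        "samples": "participant means" if participant_mean else "windows",
        "caveat": ("window samples overlap in time and are not independent"
                   if not participant_mean else None),
    }
    return out


def marker_feature_names(markers: list[str],
                         available: list[str]) -> list[str]:
    """All features computed from the given markers, in ``available`` order."""
    wanted = set()
    for m in markers:
        for ax in AXES:
            for feat in FEATURE_NAMES:
                wanted.add(f"{feat}-{m}_{ax}")
    names = [n for n in available if n in wanted]
    if not names:
        raise ValidationError(f"no features found for markers {markers}")
    return names


def restricted_set_experiment(dataset: Dataset, spec: SplitSpec,
                              model_type: str,
                              features: list[str] | None = None,
                              markers: list[str] | None = None,
                              fog_included: bool = True,
                              n_search: int = 25,
                              positive_class: str = POSITIVE_CLASS,
                              tuned_params: dict[str, Any] | None = None
                              ) -> CVResult:
    """Rerun a classification experiment on a restricted feature/marker set.

    Exactly one of ``features`` (explicit feature names, e.g. the top-k of
    an MDI ranking) or ``markers`` (keep all 8 features x 3 axes of each
    chosen marker) must be given.  Selecting the full feature set
    reproduces ``run_experiment`` exactly under equal seeds.
    """
    if (features is None) == (markers is None):
        raise InvalidArgumentError("give exactly one of features/markers")
    if markers is not None:
        known_markers = {n.split("-", 1)[1].rsplit("_", 1)[0]
                         for n in dataset.feature_names if "-" in n}
        unknown = [m for m in markers if m not in known_markers]
        if unknown:
            raise ValidationError(f"unknown marker(s): {unknown}")
        selection = marker_feature_names(markers, dataset.feature_names)
    else:
        if not features:
            raise InvalidArgumentError("feature selection is empty")
        selection = features
    sub = dataset.select_features(selection)
    return run_experiment(sub, spec, model_type, fog_included=fog_included,
                          n_search=n_search, positive_class=positive_class,
                          tuned_params=tuned_params)


def plot_top_features(importance: pd.DataFrame, path: str | Path,
                      top_k: int = 10) -> Path:
    """Horizontal bar chart of the top-k MDI features (SVG/PNG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = importance.head(top_k).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(top) + 1))
    ax.barh(top["feature"], top["mdi"], color="#3b6ea5")
    ax.set_xlabel("mean decrease in impurity")
    ax.set_title(f"Top {len(top)} features")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
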