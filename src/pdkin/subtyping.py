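"""MDS-UPDRS motor-subtype scoring: TD vs PIGD by the tremor/gait ratio.

The tremor-related component score is the mean of five MDS-UPDRS items
(2.10 tremor, 3.15 postural tremor, 3.16 kinetic tremor, 3.17 rest tremor
amplitude, 3.18 rest tremor constancy); the gait-related score is the mean
of five items (2.12 walking and balance, 2.13 freezing, 3.10 gait,
3.11 freezing of gait, 3.12 postural stability).  Each item is an integer
0-4.  The ratio tremor/gait classifies a patient as:

* **PIGD** when ratio <= 0.90 (boundary inclusive),
* **TD** when ratio >= 1.15 (boundary inclusive),
* **Indeterminate** otherwise.

A zero gait score with any tremor burden gives ratio +inf, i.e. TD (a
package convention: zero gait burden is maximally tremor-dominant); both
scores zero is Indeterminate with the ratio recorded as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

TREMOR_ITEMS: tuple[str, ...] = ("2.10", "3.15", "3.16", "3.17", "3.18")
GAIT_ITEMS: tuple[str, ...] = ("2.12", "2.13", "3.10", "3.11", "3.12")

PIGD_THRESHOLD = 0.90
TD_THRESHOLD = 1.15

LABELS = ("PIGD", "TD", "Indeterminate")


def _validate_items(items: dict[str, float], expected: tuple[str, ...],
                    kind: str) -> None:
    for item in expected:
        if item not in items:
            raise ValidationError(f"missing {kind} item {item}")
        v = items[item]
        if not (isinstance(v, (int, float)) and 0 <= v <= 4):
            raise ValidationError(
                f"{kind} item {item} score {v!r} outside [0, 4]")


@dataclass
class UpdrsScores:
    """The ten MDS-UPDRS items feeding the subtype ratio for one patient."""

    participant_id: str
    tremor_items: dict[str, float] = field(default_factory=dict)
    gait_items: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate_items(self.tremor_items, TREMOR_ITEMS, "tremor")
        _validate_items(self.gait_items, GAIT_ITEMS, "gait")

    @property
    def tremor_score(self) -> float:
        return sum(self.tremor_items[i] for i in TREMOR_ITEMS) / len(TREMOR_ITEMS)

    @property
    def gait_score(self) -> float:
        return sum(self.gait_items[i] for i in GAIT_ITEMS) / len(GAIT_ITEMS)

    @property
    def fog_score(self) -> int:
        """MDS-UPDRS item 3.11 (freezing of gait)."""
        return int(self.gait_items["3.11"])


@dataclass
class SubtypeResult:
    participant_id: str
    tremor_score: float
    gait_score: float
    ratio: float  # NaN when both component scores are zero
    label: str


def aggregate_subitems(subitems: dict[str, float]) -> float:
    """Collapse body-part sub-scores (e.g. 3.17 left/right/lip-jaw) to one item.

    The subtype rule averages *items*; raters often record per-body-part
    sub-scores, which this helper averages first.
    """
    if not subitems:
        raise ValidationError("no sub-item scores given")
    vals = list(subitems.values())
    for v in vals:
        if not 0 <= v <= 4:
            raise ValidationError(f"sub-item score {v!r} outside [0, 4]")
    return sum(vals) / len(vals)


def label_from_scores(tremor_score: float, gait_score: float) -> tuple[float, str]:
    """Apply the ratio rule to component means; returns (ratio, label)."""
    if gait_score == 0:
        if tremor_score == 0:
            return math.nan, "Indeterminate"
        return math.inf, "TD"
    ratio = tremor_score / gait_score
    if ratio <= PIGD_THRESHOLD:
        return ratio, "PIGD"
    if ratio >= TD_THRESHOLD:
        return ratio, "TD"
    return ratio, "Indeterminate"


def classify_subtype(scores: UpdrsScores) -> SubtypeResult:
    """Classify one patient from their ten MDS-UPDRS item scores."""
    t, g = scores.tremor_score, scores.gait_score
    ratio, label = label_from_scores(t, g)
    return SubtypeResult(participant_id=scores.participant_id,
                         tremor_score=t, gait_score=g, ratio=ratio, label=label)


def cohort_subtype_table(scores: list[UpdrsScores],
                         fog_scores: dict[str, int] | None = None,
                         include_indeterminate: bool = True) -> pd.DataFrame:
    """Subtype x FOG-score contingency table for a cohort.

    Rows are subtype labels, columns FOG scores 0-4, cells participant
    counts.  ``fog_scores`` defaults to each patient's own item 3.11.
    Indeterminate rows are reported by default but can be excluded (they
    are dropped from classification experiments).
    """
    ids = [s.participant_id for s in scores]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate participant id(s): {dup}")
    table = pd.DataFrame(0, index=list(LABELS), columns=list(range(5)))
    for s in scores:
        res = classify_subtype(s)
        fog = (fog_scores or {}).get(s.participant_id, s.fog_score)
        if not 0 <= fog <= 4:
            raise ValidationError(
                f"FOG score {fog} for {s.participant_id} outside 0-4")
        table.loc[res.label, int(fog)] += 1
    if not include_indeterminate:
        table = table.drop(index="Indeterminate")
    table = table.loc[table.sum(axis=1) > 0] if scores else table.iloc[0:0]
    table.index.name = "subtype"
    table.columns.name = "fog_score"
    return table
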