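"""Brief-scale scoring and the two-stage triage rule.

The brief cognitive score (0-9, higher = better performance) sums six
pass/fail items and the 0-3 delayed-recall count.  The brief informant
score (0-6, higher = more reported decline) counts symptom-present
items after dichotomization.  The combined score subtracts the
informant score from the cognitive score (range -6 to 9): impairment
lowers the cognitive score and raises the informant score, so
subtraction pools both signals in one direction.

Triage: cognitive <= 4 is highly suggestive of dementia (screen
positive); >= 7 makes it highly improbable (negative); 5-6 defers to
the informant interview, screening positive iff the combined score is
<= 4, or indeterminate when no informant is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .items import (BRIEF_COGNITIVE_ITEMS, BRIEF_INFORMANT_ITEMS,
                    DEFAULT_INFORMANT_CUTS, CohortTable, ItemDefinition)

__all__ = ["Cutpoint", "DEFAULT_CUTPOINTS", "score_cognitive", "score_informant",
           "score_combined", "triage", "score_cohort",
           "COGNITIVE_MAX", "INFORMANT_MAX"]

COGNITIVE_MAX = 9
INFORMANT_MAX = 6

# triage thresholds (inclusive)
TRIAGE_COGNITIVE_POSITIVE_MAX = 4
TRIAGE_COGNITIVE_NEGATIVE_MIN = 7
TRIAGE_COMBINED_POSITIVE_MAX = 4


@dataclass(frozen=True)
class Cutpoint:
    """Half-open screening threshold with an explicit direction.

    ``lower_is_positive`` screens positive when score < threshold (the
    usual "<6" notation at threshold 5.5 on an integer scale);
    ``higher_is_positive`` when score > threshold (">1" at 1.5).
    Storing half-integer thresholds with a direction flag avoids
    off-by-one drift between "<" and ">" style notations.
    """

    threshold: float
    direction: str = "lower_is_positive"

    def __post_init__(self):
        if self.direction not in ("lower_is_positive", "higher_is_positive"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def is_positive(self, score) -> np.ndarray | bool:
        score = np.asarray(score, dtype=float)
        out = (score < self.threshold if self.direction == "lower_is_positive"
               else score > self.threshold)
        return bool(out) if out.ndim == 0 else out

    @property
    def notation(self) -> str:
        if self.direction == "lower_is_positive":
            return f"<{math.ceil(self.threshold)}"
        return f">{math.floor(self.threshold)}"


#: Published optimal cutpoints.  The cognitive scale carries a
#: specificity-favouring ("<6") and a sensitivity-favouring ("<7")
#: threshold; the informant default is ">1" with a regional override
#: (">2" for the Nigerian sample); combined is "<5".
DEFAULT_CUTPOINTS: dict[str, Cutpoint] = {
    "cognitive": Cutpoint(5.5, "lower_is_positive"),
    "cognitive_sensitive": Cutpoint(6.5, "lower_is_positive"),
    "informant": Cutpoint(1.5, "higher_is_positive"),
    "informant_nigeria": Cutpoint(2.5, "higher_is_positive"),
    "combined": Cutpoint(4.5, "lower_is_positive"),
}


def _get_responses(responses: Mapping[str, float],
                   items: Sequence[ItemDefinition],
                   allow_missing: bool) -> dict[str, float]:
    out = {}
    for it in items:
        v = responses.get(it.item_id)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            if not allow_missing:
                raise ValueError(f"missing response for item {it.item_id!r}")
            out[it.item_id] = np.nan
        else:
            v = float(v)
            if not (0 <= v <= it.n_levels - 1) or v != int(v):
                raise ValueError(
                    f"response {v:g} out of range for item {it.item_id!r}")
            out[it.item_id] = v
    return out


def score_cognitive(responses: Mapping[str, float],
                    items: Sequence[ItemDefinition] = BRIEF_COGNITIVE_ITEMS,
                    allow_missing: bool = False) -> float:
    """Sum of correct binary items plus the delayed-recall count (0-9).

    With ``allow_missing`` the total is NaN when any item is missing
    (complete-case scoring); otherwise a missing item raises.
    """
    vals = _get_responses(responses, items, allow_missing)
    total = sum(vals.values())
    return float("nan") if np.isnan(total) else float(total)


def score_informant(responses: Mapping[str, float],
                    plan: Mapping[str, int] | None = None,
                    items: Sequence[ItemDefinition] = BRIEF_INFORMANT_ITEMS,
                    allow_missing: bool = False) -> float:
    """Count of symptom-present items after dichotomization (0-6)."""
    cuts = dict(getattr(plan, "cuts", plan) or DEFAULT_INFORMANT_CUTS)
    vals = _get_responses(responses, items, allow_missing)
    total = 0.0
    for it in items:
        v = vals[it.item_id]
        if np.isnan(v):
            return float("nan")
        cut = cuts.get(it.item_id, 1) if it.polytomous else 1
        total += float(v >= cut)
    return total


def score_combined(cognitive_total: float, informant_total: float) -> float:
    """Combined score = cognitive - informant, range -6 to 9."""
    if not 0 <= cognitive_total <= COGNITIVE_MAX:
        raise ValueError(f"cognitive total {cognitive_total} outside 0..{COGNITIVE_MAX}")
    if not 0 <= informant_total <= INFORMANT_MAX:
        raise ValueError(f"informant total {informant_total} outside 0..{INFORMANT_MAX}")
    return float(cognitive_total) - float(informant_total)


def triage(cognitive_total: float, informant_total: float | None = None) -> str:
    """Two-stage screening decision: positive / negative / indeterminate.

    Cognitive <= 4 -> positive; >= 7 -> negative.  For the borderline
    5-6 band the informant interview decides (positive iff combined
    score <= 4); with no informant the band is indeterminate.
    """
    if not 0 <= cognitive_total <= COGNITIVE_MAX:
        raise ValueError(f"cognitive total {cognitive_total} outside 0..{COGNITIVE_MAX}")
    if cognitive_total <= TRIAGE_COGNITIVE_POSITIVE_MAX:
        return "positive"
    if cognitive_total >= TRIAGE_COGNITIVE_NEGATIVE_MIN:
        return "negative"
    if informant_total is None or (isinstance(informant_total, float)
                                   and np.isnan(informant_total)):
        return "indeterminate"
    combined = score_combined(cognitive_total, informant_total)
    return "positive" if combined <= TRIAGE_COMBINED_POSITIVE_MAX else "negative"


def score_cohort(cohort: CohortTable,
                 informant_plan: Mapping[str, int] | None = None,
                 allow_missing: bool = True) -> pd.DataFrame:
    """Score every subject of a cohort; one row per subject.

    Columns: ``subject_id``, ``cognitive_total``, ``informant_total``,
    ``combined``, ``triage``, ``informant_missing`` plus any label
    columns carried over from the cohort.  Complete-case per scale:
    a subject missing any cognitive item gets NaN totals and an
    indeterminate triage; a subject missing informant items falls back
    to cognitive-only triage with ``informant_missing`` flagged.
    """
    cog_items = [it for it in cohort.items if it.scale == "cognitive"]
    inf_items = [it for it in cohort.items if it.scale == "informant"]
    rows = []
    for _, rec in cohort.data.iterrows():
        responses = {it.item_id: rec[it.item_id] for it in cohort.items}
        cog = score_cognitive(responses, cog_items, allow_missing=allow_missing) \
            if cog_items else float("nan")
        inf = score_informant(responses, informant_plan, inf_items,
                              allow_missing=allow_missing) if inf_items else float("nan")
        if np.isnan(cog):
            comb, decision = float("nan"), "indeterminate"
        else:
            comb = score_combined(cog, inf) if not np.isnan(inf) else float("nan")
            decision = triage(cog, None if np.isnan(inf) else inf)
        row = {"subject_id": rec["subject_id"], "cognitive_total": cog,
               "informant_total": inf, "combined": comb, "triage": decision,
               "informant_missing": bool(np.isnan(inf))}
        for label in ("diagnosis", "severity", "education", "region"):
            if label in cohort.data.columns:
                row[label] = rec[label]
        rows.append(row)
    return pd.DataFrame(rows)
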