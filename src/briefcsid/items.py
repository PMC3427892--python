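"""Item banks, cohort tables and keyed response matrices.

The screening instrument couples a short cognitive test of the older
person with an informant interview about everyday functioning.  This
module holds the item metadata for both scales, a validated
subject-by-item response table, and the keying step that maps raw codes
onto the canonical internal coding in which 1 always means the keyed
direction: a correct answer on a cognitive item, a reported symptom on
an informant item.  One Mokken engine can then serve both scales
without per-scale branching.

Raw codes are assumed ordered toward the keyed direction: for a
dichotomous cognitive item 1 = correct, 0 = incorrect; for a
three-level informant item 0 = never, 1 = sometimes, 2 = often.
Polytomous items are keyed through a dichotomization cut ``c``:
keyed = 1 iff response >= c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_SCALES = ("cognitive", "informant")
_KEYED_MEANINGS = ("correct_response", "symptom_present")

#: optional per-subject label columns recognised in cohort files
LABEL_COLUMNS = ("diagnosis", "severity", "education", "region")


@dataclass(frozen=True)
class ItemDefinition:
    """Identity and coding of a single screening item.

    Parameters
    ----------
    item_id : str
        Short unique identifier, used as the column name in cohort files.
    label : str
        Human-readable description.
    scale : {"cognitive", "informant"}
        Scale membership.
    n_levels : int
        Number of ordered response levels (codes ``0 .. n_levels-1``).
        Dichotomous items have ``n_levels == 2``.
    keyed_level_meaning : {"correct_response", "symptom_present"}
        What the keyed (high) direction means for this item.
    domain_tag : str
        Cognitive or functional domain, used by item selection to favour
        domain coverage (e.g. ``naming``, ``praxis``, ``orientation``).
    """

    item_id: str
    label: str
    scale: str
    n_levels: int = 2
    keyed_level_meaning: str = "correct_response"
    domain_tag: str = ""

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.keyed_level_meaning not in _KEYED_MEANINGS:
            raise ValueError(
                f"unknown keyed_level_meaning {self.keyed_level_meaning!r}; "
                f"expected one of {_KEYED_MEANINGS}"
            )
        if self.n_levels < 2:
            raise ValueError(f"item {self.item_id!r}: n_levels must be >= 2")

    @property
    def polytomous(self) -> bool:
        return self.n_levels > 2


#: The seven brief cognitive items, in ascending order of published
#: marginal difficulty.  Six are pass/fail; delayed recall counts
#: how many of three words are recalled (0-3).
BRIEF_COGNITIVE_ITEMS: tuple[ItemDefinition, ...] = (
    ItemDefinition("hammer", "Describing the use of a hammer", "cognitive", 2,
                   "correct_response", "language"),
    ItemDefinition("elbow", "Naming elbow", "cognitive", 2,
                   "correct_response", "naming"),
    ItemDefinition("point_window_door", "Pointing to window and then to door",
                   "cognitive", 2, "correct_response", "praxis"),
    ItemDefinition("nearest_store", "Locating nearest store", "cognitive", 2,
                   "correct_response", "spatial"),
    ItemDefinition("season", "Orientation to season", "cognitive", 2,
                   "correct_response", "orientation"),
    ItemDefinition("day_of_week", "Orientation to day of the week", "cognitive", 2,
                   "correct_response", "orientation"),
    ItemDefinition("recall_3words", "Delayed recall of three words (0-3)",
                   "cognitive", 4, "correct_response", "recall"),
)

#: The six brief informant items, ascending published difficulty.  All are
#: asked on a never / sometimes / often scale (0/1/2).
BRIEF_INFORMANT_ITEMS: tuple[ItemDefinition, ...] = (
    ItemDefinition("forgets_where_put", "Forgets where she/he has put things",
                   "informant", 3, "symptom_present", "memory-function"),
    ItemDefinition("mental_decline", "General decline in mental functioning",
                   "informant", 3, "symptom_present", "global-function"),
    ItemDefinition("think_reason", "Change in ability to think and reason",
                   "informant", 3, "symptom_present", "reasoning"),
    ItemDefinition("forgets_day_before", "Forgets what happened the day before",
                   "informant", 3, "symptom_present", "memory-function"),
    ItemDefinition("forgets_where_is", "Forgets where she/he is",
                   "informant", 3, "symptom_present", "orientation-function"),
    ItemDefinition("difficulty_dressing", "Difficulty dressing",
                   "informant", 3, "symptom_present", "adl"),
)

BRIEF_ITEM_BANK: tuple[ItemDefinition, ...] = BRIEF_COGNITIVE_ITEMS + BRIEF_INFORMANT_ITEMS

#: Default dichotomization cuts.  Informant cuts follow the published item
#: wording: "often forgets where ..." is keyed at often (>=2), the
#: "sometimes ..." items and the remaining symptom items at sometimes (>=1).
#: Delayed recall enters the Mokken analysis keyed at >=2 of 3 words.
DEFAULT_INFORMANT_CUTS: dict[str, int] = {
    "forgets_where_put": 2,
    "mental_decline": 1,
    "think_reason": 1,
    "forgets_day_before": 1,
    "forgets_where_is": 1,
    "difficulty_dressing": 1,
}
DEFAULT_COGNITIVE_CUTS: dict[str, int] = {"recall_3words": 2}
DEFAULT_CUTS: dict[str, int] = {**DEFAULT_COGNITIVE_CUTS, **DEFAULT_INFORMANT_CUTS}


def items_for_scale(items: Iterable[ItemDefinition], scale: str) -> tuple[ItemDefinition, ...]:
    """Return the subset of an item bank belonging to one scale."""
    return tuple(it for it in items if it.scale == scale)


# ---------------------------------------------------------------------------
# item bank serialization

_BANK_COLUMNS = ["item_id", "label", "scale", "n_levels", "keyed_level_meaning", "domain_tag"]


def item_bank_to_frame(items: Iterable[ItemDefinition]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(it, c) for c in _BANK_COLUMNS} for it in items])


def save_item_bank(items: Iterable[ItemDefinition], path: str | Path) -> None:
    """Write an item bank to CSV or YAML, chosen by file suffix."""
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        records = item_bank_to_frame(items).to_dict(orient="records")
        path.write_text(yaml.safe_dump(records, sort_keys=False))
    else:
        item_bank_to_frame(items).to_csv(path, index=False)


def load_item_bank(path: str | Path) -> tuple[ItemDefinition, ...]:
    """Read an item bank from CSV or YAML, chosen by file suffix."""
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        records = yaml.safe_load(path.read_text())
    else:
        records = pd.read_csv(path).to_dict(orient="records")
    items = tuple(
        ItemDefinition(
            item_id=str(r["item_id"]),
            label=str(r.get("label", "")),
            scale=str(r["scale"]),
            n_levels=int(r.get("n_levels", 2)),
            keyed_level_meaning=str(r.get("keyed_level_meaning", "correct_response")),
            domain_tag=str(r.get("domain_tag", "")),
        )
        for r in records
    )
    ids = [it.item_id for it in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate item_id in item bank")
    return items


# ---------------------------------------------------------------------------
# cohort table


@dataclass
class CohortTable:
    """Validated subject-by-item response table with optional labels.

    ``data`` holds one row per subject: a ``subject_id`` column, one
    column per item (integer codes in ``0 .. n_levels-1`` or missing),
    and any of the optional label columns ``diagnosis`` (0/1 gold
    standard), ``severity`` ("mild"/"moderate", only for cases),
    ``education`` ("low"/"high") and ``region``.
    """

    data: pd.DataFrame
    items: tuple[ItemDefinition, ...]

    def __post_init__(self) -> None:
        self.items = tuple(self.items)
        self.data = self.data.reset_index(drop=True)
        self._validate()

    # -- properties ---------------------------------------------------------

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def item(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        cols = list(self.data.columns)
        if "subject_id" not in cols:
            raise ValueError("cohort table must have a 'subject_id' column")
        sid = self.data["subject_id"].astype(str)
        if sid.duplicated().any():
            dup = sid[sid.duplicated()].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in item bank")
        for it in self.items:
            if it.item_id not in cols:
                raise ValueError(f"missing item column {it.item_id!r}")
            v = pd.to_numeric(self.data[it.item_id], errors="coerce").to_numpy(float)
            raw_missing = self.data[it.item_id].isna().to_numpy()
            if (np.isnan(v) & ~raw_missing).any():
                bad = sid[np.isnan(v) & ~raw_missing].iloc[0]
                raise ValueError(
                    f"non-numeric response for subject {bad!r}, item {it.item_id!r}")
            with np.errstate(invalid="ignore"):
                bad_mask = ~np.isnan(v) & ((v != np.round(v)) | (v < 0) | (v > it.n_levels - 1))
            if bad_mask.any():
                bad = sid[bad_mask].iloc[0]
                bad_val = v[bad_mask][0]
                raise ValueError(
                    f"response {bad_val:g} out of range 0..{it.n_levels - 1} "
                    f"for subject {bad!r}, item {it.item_id!r}")
            self.data[it.item_id] = v
        if "diagnosis" in cols:
            d = pd.to_numeric(self.data["diagnosis"], errors="coerce")
            if not d.dropna().isin([0, 1]).all():
                raise ValueError("diagnosis must be coded 0/1")
            self.data["diagnosis"] = d
        if "severity" in cols:
            s = self.data["severity"]
            bad = s.dropna()[~s.dropna().isin(["mild", "moderate"])]
            if len(bad):
                raise ValueError(f"unknown severity value {bad.iloc[0]!r}")
            if "diagnosis" not in cols:
                if s.notna().any():
                    raise ValueError("severity present but no diagnosis column")
            else:
                mask = s.notna() & (self.data["diagnosis"] != 1)
                if mask.any():
                    bad_sid = sid[mask].iloc[0]
                    raise ValueError(
                        f"severity given for non-case subject {bad_sid!r}")
        if "education" in cols:
            e = self.data["education"]
            bad = e.dropna()[~e.dropna().isin(["low", "high"])]
            if len(bad):
                raise ValueError(f"unknown education value {bad.iloc[0]!r}")

    # -- io -----------------------------------------------------------------

    def write_csv(self, path: str | Path, delimiter: str = ",",
                  missing_token: str = "NA") -> None:
        out = self.data.copy()
        for it in self.items:
            out[it.item_id] = out[it.item_id].map(
                lambda x: missing_token if pd.isna(x) else str(int(x)))
        out.to_csv(path, sep=delimiter, index=False, na_rep=missing_token)

    def subset_items(self, item_ids: Sequence[str]) -> "CohortTable":
        items = tuple(self.item(i) for i in item_ids)
        keep = ["subject_id", *item_ids] + [c for c in LABEL_COLUMNS if c in self.data.columns]
        return CohortTable(self.data[keep].copy(), items)


def load_cohort(path: str | Path, item_bank: Sequence[ItemDefinition],
                delimiter: str = ",", missing_token: str = "NA") -> CohortTable:
    """Read a delimited cohort file and validate it against an item bank.

    Every non-label column other than ``subject_id`` must be a known
    item; out-of-range codes and duplicate subject ids raise with the
    offending cell named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, na_values=[missing_token, ""],
                     keep_default_na=False)
    known = {"subject_id", *LABEL_COLUMNS, *(it.item_id for it in item_bank)}
    for col in df.columns:
        if col not in known:
            raise ValueError(f"unknown item column {col!r} in {path.name}")
    present = [it for it in item_bank if it.item_id in df.columns]
    missing_items = [it.item_id for it in item_bank if it.item_id not in df.columns]
    if missing_items:
        raise ValueError(f"missing item column(s) {missing_items} in {path.name}")
    cohort = CohortTable(df, tuple(present))
    n_missing = int(cohort.data[list(cohort.item_ids)].isna().to_numpy().sum())
    logger.info("loaded cohort %s: %d subjects, %d items, %d missing cells",
                path.name, cohort.n_subjects, len(cohort.items), n_missing)
    return cohort


# ---------------------------------------------------------------------------
# keyed matrix


@dataclass
class KeyedMatrix:
    """Binary (0/1/NaN) matrix after keying and dichotomization.

    A value of 1 always means the keyed direction: the correct response
    on a cognitive item, symptom present on an informant item.
    """

    values: np.ndarray
    item_ids: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-d (subjects x items)")
        v = self.values[~np.isnan(self.values)]
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("keyed values must be 0, 1 or missing")
        self.item_ids = tuple(self.item_ids)
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        if self.values.shape != (len(self.subject_ids), len(self.item_ids)):
            raise ValueError("shape mismatch between values and ids")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def n_per_item(self) -> np.ndarray:
        """Non-missing sample size per item."""
        return (~np.isnan(self.values)).sum(axis=0)

    def complete_cases(self) -> "KeyedMatrix":
        keep = ~np.isnan(self.values).any(axis=1)
        return KeyedMatrix(self.values[keep],
                           self.item_ids,
                           tuple(s for s, k in zip(self.subject_ids, keep) if k))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.item_ids),
                            index=list(self.subject_ids))


def key_responses(cohort: CohortTable,
                  items: Sequence[ItemDefinition] | None = None,
                  plan: Mapping[str, int] | None = None) -> KeyedMatrix:
    """Map raw responses onto the common 1-means-keyed binary coding.

    Dichotomous items key directly (raw 1 -> keyed 1).  Each polytomous
    item needs a cut ``c`` in ``plan`` (keyed iff response >= c) or must
    be excluded from ``items``.  Missing responses propagate.
    ``plan`` may be a plain mapping or any object with a ``cuts``
    mapping attribute (e.g. a ``DichotomizationPlan``).
    """
    if items is None:
        items = cohort.items
    cuts: Mapping[str, int] = getattr(plan, "cuts", plan) or {}
    cols = []
    for it in items:
        raw = cohort.data[it.item_id].to_numpy(float)
        if it.n_levels == 2:
            keyed = raw
        else:
            cut = cuts.get(it.item_id)
            if cut is None:
                raise ValueError(
                    f"polytomous item {it.item_id!r} has no dichotomization cut "
                    "and was not excluded")
            if not 1 <= int(cut) <= it.n_levels - 1:
                raise ValueError(
                    f"cut {cut} invalid for item {it.item_id!r} "
                    f"(levels 0..{it.n_levels - 1})")
            keyed = np.where(np.isnan(raw), np.nan, (raw >= int(cut)).astype(float))
        cols.append(keyed)
    values = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    return KeyedMatrix(values, tuple(it.item_id for it in items),
                       tuple(cohort.data["subject_id"].astype(str)))
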