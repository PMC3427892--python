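"""Optimal dichotomization of polytomous items and brief-subset selection.

Two steps turn a long candidate pool into a brief hierarchical scale:

1. each polytomous item is recoded into the dichotomy that maximises
   its own Loevinger H_i within the candidate scale (coordinate-wise
   search with one refinement pass), and
2. a small subset of k items with the highest H_i is selected, with
   priority rules favouring coverage of distinct content domains and
   spread item difficulties when strongly scalable alternatives exist.

Both procedures are deterministic given their inputs; every skip,
tie-break and constraint application is recorded in a decision log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .items import CohortTable, ItemDefinition, key_responses
from .mokken import H_STRONG, ScaleScalability, scale_scalability

__all__ = ["DichotomizationPlan", "SelectionResult", "optimal_dichotomy",
           "select_items"]


@dataclass
class DichotomizationPlan:
    """Chosen cut per polytomous item (keyed iff response >= cut).

    ``objective`` stores the item H_i obtained for every candidate cut
    in the final refinement pass; ``log`` records the search decisions.
    """

    cuts: dict[str, int]
    objective: dict[str, dict[int, float]] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None):
        payload = {"cuts": self.cuts,
                   "objective": {k: {str(c): v for c, v in d.items()}
                                 for k, d in self.objective.items()},
                   "log": self.log}
        if path is None:
            return json.dumps(payload, indent=2)
        Path(path).write_text(json.dumps(payload, indent=2))
        return None

    @classmethod
    def from_json(cls, path: str | Path) -> "DichotomizationPlan":
        payload = json.loads(Path(path).read_text())
        return cls(cuts={k: int(v) for k, v in payload["cuts"].items()},
                   objective={k: {int(c): float(v) for c, v in d.items()}
                              for k, d in payload.get("objective", {}).items()},
                   log=list(payload.get("log", [])))


@dataclass
class SelectionResult:
    """Brief-subset selection outcome.

    ``selected`` is ordered by ascending difficulty (the instrument's
    presentation order); ``item_H`` holds each selected item's H_i at
    selection time, ``subset_H`` the whole-scale H recomputed over the
    selected items' pairwise counts.
    """

    selected: list[str]
    item_H: dict[str, float]
    subset_H: float | None
    log: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None):
        payload = {"selected": self.selected, "item_H": self.item_H,
                   "subset_H": self.subset_H, "log": self.log}
        if path is None:
            return json.dumps(payload, indent=2)
        Path(path).write_text(json.dumps(payload, indent=2))
        return None

    def to_markdown(self) -> str:
        lines = ["# Brief scale selection", "",
                 "| item | H_i |", "|---|---|"]
        for item in self.selected:
            lines.append(f"| {item} | {self.item_H[item]:.3f} |")
        if self.subset_H is not None:
            lines += ["", f"Whole-scale H of the selected subset: {self.subset_H:.3f}"]
        lines += ["", "## Decision log", ""] + [f"- {line}" for line in self.log]
        return "\n".join(lines)


def optimal_dichotomy(cohort: CohortTable,
                      items: Sequence[ItemDefinition] | None = None,
                      initial: dict[str, int] | None = None,
                      n_passes: int = 2) -> DichotomizationPlan:
    """Choose, per polytomous item, the cut maximising its H_i in the scale.

    Coordinate-wise search: every polytomous item starts at the middle
    level (``n_levels // 2``), items are optimised in listed order with
    the other items held at their current cuts, and the sweep is
    repeated once.  Ties break toward the lower cut (the more prevalent
    symptom).  Cuts that make an item constant are skipped; an item
    whose every cut is degenerate is dropped from the plan and flagged
    in the log.
    """
    if items is None:
        items = cohort.items
    items = list(items)
    scales = {it.scale for it in items}
    if len(scales) > 1:
        raise ValueError("candidate scale mixes cognitive and informant items")
    poly = [it for it in items if it.polytomous]
    log: list[str] = []
    cuts: dict[str, int] = {}
    for it in poly:
        cuts[it.item_id] = (initial or {}).get(it.item_id, max(1, it.n_levels // 2))
    if not poly:
        log.append("no polytomous items; nothing to dichotomize")
        return DichotomizationPlan(cuts={}, log=log)

    objective: dict[str, dict[int, float]] = {}
    unusable: set[str] = set()
    for sweep in range(n_passes):
        for it in poly:
            if it.item_id in unusable:
                continue
            scores: dict[int, float] = {}
            for cut in range(1, it.n_levels):
                trial = dict(cuts)
                trial[it.item_id] = cut
                km = key_responses(cohort, items, trial)
                col = km.values[:, km.item_ids.index(it.item_id)]
                col = col[~np.isnan(col)]
                if len(col) == 0 or col.min() == col.max():
                    log.append(f"pass {sweep + 1}: {it.item_id} cut {cut} "
                               "produces a constant item; skipped")
                    continue
                stats = scale_scalability(km)
                h = next(s.H for s in stats.items if s.item_id == it.item_id)
                scores[cut] = h
            if not scores:
                unusable.add(it.item_id)
                cuts.pop(it.item_id, None)
                log.append(f"{it.item_id}: every cut degenerate; item flagged unusable")
                continue
            best = max(scores.values())
            best_cut = min(c for c, h in scores.items() if h == best)
            if len([c for c, h in scores.items() if h == best]) > 1:
                log.append(f"pass {sweep + 1}: {it.item_id} tie between cuts "
                           f"{sorted(c for c, h in scores.items() if h == best)}; "
                           f"lower cut {best_cut} chosen")
            else:
                log.append(f"pass {sweep + 1}: {it.item_id} cut {best_cut} "
                           f"(H_i = {best:.3f})")
            cuts[it.item_id] = best_cut
            objective[it.item_id] = scores
    return DichotomizationPlan(cuts=cuts, objective=objective, log=log)


def _subset_H(stats: ScaleScalability, selected: Sequence[str]) -> float | None:
    chosen = set(selected)
    F = E = 0.0
    found = False
    for pw in stats.pairwise:
        if pw.item_i in chosen and pw.item_j in chosen and not pw.degenerate:
            F += pw.F
            E += pw.E
            found = True
    if not found or E <= 0:
        return None
    return 1.0 - F / E


def select_items(stats: ScaleScalability,
                 item_bank: Sequence[ItemDefinition],
                 k: int = 6,
                 h_floor: float = H_STRONG,
                 difficulty_eps: float = 0.02,
                 enforce_domains: bool = True) -> SelectionResult:
    """Greedy selection of the k most scalable items with coverage rules.

    Items are ranked by H_i descending (ties: ascending difficulty, then
    bank order).  Walking the ranking, an item is skipped when

    a. its domain is already represented and some unrepresented domain
       still has an unselected item with H_i >= ``h_floor``, or
    b. its difficulty lies within ``difficulty_eps`` of an already
       selected item and an unselected item with H_i >= ``h_floor`` and
       adequate spacing remains.

    Skipped items are reconsidered, in ranking order, if the walk ends
    short of k.  A warning line is logged when fewer than k items reach
    ``h_floor``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    by_id = {it.item_id: it for it in item_bank}
    cand = [s for s in stats.items if s.item_id in by_id and not np.isnan(s.H)]
    order = {it.item_id: i for i, it in enumerate(item_bank)}
    rank = sorted(cand, key=lambda s: (-s.H, s.difficulty, order[s.item_id]))
    log: list[str] = []
    n_strong = sum(1 for s in cand if s.H >= h_floor)
    if n_strong < k:
        log.append(f"warning: only {n_strong} items reach H_i >= {h_floor:.2f}; "
                   "best-effort selection")

    selected: list[str] = []
    skipped: list[str] = []
    sel_domains: set[str] = set()
    sel_diffs: list[float] = []
    stats_by_id = {s.item_id: s for s in cand}

    def strong_unselected(exclude: set[str]):
        return [s for s in rank
                if s.item_id not in exclude and s.H >= h_floor]

    for s in rank:
        if len(selected) == k:
            break
        item = by_id[s.item_id]
        taken = set(selected) | {s.item_id}
        if enforce_domains and item.domain_tag in sel_domains:
            pool = strong_unselected(taken)
            missing_dom = [t for t in pool
                           if by_id[t.item_id].domain_tag not in sel_domains]
            if missing_dom:
                skipped.append(s.item_id)
                log.append(f"skip {s.item_id}: domain {item.domain_tag!r} already "
                           f"represented; {missing_dom[0].item_id} covers "
                           f"{by_id[missing_dom[0].item_id].domain_tag!r}")
                continue
        if sel_diffs and min(abs(s.difficulty - d) for d in sel_diffs) < difficulty_eps:
            pool = strong_unselected(taken)
            spaced = [t for t in pool
                      if all(abs(t.difficulty - d) >= difficulty_eps for d in sel_diffs)]
            if spaced:
                skipped.append(s.item_id)
                log.append(f"skip {s.item_id}: difficulty {s.difficulty:.3f} within "
                           f"{difficulty_eps} of a selected item; spaced alternative "
                           f"{spaced[0].item_id} available")
                continue
        selected.append(s.item_id)
        sel_domains.add(item.domain_tag)
        sel_diffs.append(s.difficulty)
        log.append(f"select {s.item_id} (H_i = {s.H:.3f}, "
                   f"difficulty = {s.difficulty:.3f}, domain = {item.domain_tag!r})")

    if len(selected) < k:
        for item_id in skipped:
            if len(selected) == k:
                break
            selected.append(item_id)
            log.append(f"fill {item_id} from skipped items to reach k = {k}")

    selected.sort(key=lambda i: (stats_by_id[i].difficulty, order[i]))
    item_H = {i: stats_by_id[i].H for i in selected}
    return SelectionResult(selected=selected, item_H=item_H,
                           subset_H=_subset_H(stats, selected), log=log)
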