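"""Seedable synthetic cohort generator.

The development and validation samples behind the brief screen are not
publicly deposited, so this module generates cohorts with the
statistical structure the analysis assumes and the published marginal
item difficulties as calibration targets:

* one latent cognitive trait theta per subject — standard normal in
  controls, shifted downwards in dementia cases (further for moderate
  than for mild severity);
* monotone logistic response functions for the cognitive items, with a
  common discrimination and per-item locations solved numerically so
  that each item's marginal difficulty matches its published target
  under the population mixture;
* the delayed-recall item as three conditionally independent word
  recalls (count 0-3), calibrated on its keyed dichotomy (>= 2 words);
* graded (never / sometimes / often) informant items driven by the
  negative trait through ordered thresholds, the keyed threshold
  calibrated to the published difficulty of the dichotomized item;
* an additive location shift (differential item functioning) on the
  cognitive items for the low-education stratum;
* two designs: a population survey with a dementia prevalence, and a
  pilot-style case-control design with mild/moderate case groups and
  high-/low-education control groups.

Setting ``discrimination=inf`` degenerates every response function to a
step in theta, producing a perfect Guttman scale — a useful limiting
case for tests.  All randomness flows from a single integer seed
through a Philox-seeded generator with a fixed draw order, so identical
configurations reproduce byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

from .items import (BRIEF_COGNITIVE_ITEMS, BRIEF_INFORMANT_ITEMS,
                    BRIEF_ITEM_BANK, DEFAULT_CUTS, CohortTable, ItemDefinition)

__all__ = ["GeneratorConfig", "SyntheticCohort", "calibrate_item_locations",
           "generate", "generate_population", "generate_case_control",
           "generate_informant_pool", "DEFAULT_DIFFICULTIES"]

#: Published marginal difficulties (proportion not keyed) of the brief
#: items in the development survey; the generator's calibration targets.
DEFAULT_DIFFICULTIES: dict[str, float] = {
    "hammer": 0.024,
    "elbow": 0.032,
    "point_window_door": 0.040,
    "nearest_store": 0.059,
    "season": 0.062,
    "day_of_week": 0.100,
    "recall_3words": 0.283,
    "forgets_where_put": 0.523,
    "mental_decline": 0.868,
    "think_reason": 0.908,
    "forgets_day_before": 0.913,
    "forgets_where_is": 0.968,
    "difficulty_dressing": 0.982,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and measurement-model parameters for cohort generation.

    Trait scale: latent trait in standard deviation units of the
    control distribution (mean 0, sd 1); case offsets are negative
    (impairment), moderate more negative than mild.  ``prevalence`` and
    the group sizes define the two designs.  ``discrimination`` is the
    common logistic slope; ``education_dif`` shifts cognitive item
    locations for the low-education stratum (in trait units).
    """

    n: int = 2000
    design: str = "population"                 # "population" | "case_control"
    prevalence: float = 0.06
    case_offset: float = -2.75                 # population-case trait shift
    moderate_quantile: float = 0.5             # cases below this quantile -> moderate
    mild_offset: float = -2.5                  # case-control design offsets
    moderate_offset: float = -4.0
    n_mild: int = 75
    n_moderate: int = 75
    n_high_education_controls: int = 100
    n_low_education_controls: int = 100
    discrimination: float = 2.0
    education_dif: float = 1.0
    p_low_education: float = 0.4
    level_gap: float = 1.5                     # informant threshold spacing
    target_difficulties: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIFFICULTIES))
    seed: int = 0

    def __post_init__(self):
        if self.design not in ("population", "case_control"):
            raise ValueError(f"unknown design {self.design!r}")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for name, tgt in self.target_difficulties.items():
            if not 0 < tgt < 1:
                raise ValueError(f"target difficulty for {name!r} must lie in (0, 1)")
        if self.moderate_offset > self.mild_offset:
            raise ValueError("moderate cases must be more impaired than mild "
                             "(moderate_offset <= mild_offset)")


@dataclass
class SyntheticCohort:
    """Generated cohort plus the generating truth.

    ``truth`` (per-subject latent trait and group assignment) and
    ``item_params`` never leak into the exported analysis CSV unless
    explicitly written out.
    """

    cohort: CohortTable
    truth: pd.DataFrame
    item_params: dict[str, dict]


# ---------------------------------------------------------------------------
# response functions and calibration

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def _irf(theta: np.ndarray, a: float, b) -> np.ndarray:
    """Monotone logistic item response function P(keyed | theta)."""
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.isinf(a):
        return (theta > b).astype(float)
    return special.expit(a * (theta - b))


def _recall_keyed_prob(theta: np.ndarray, a: float, b) -> np.ndarray:
    """P(at least 2 of 3 conditionally independent words recalled)."""
    q = _irf(theta, a, b)
    return 3 * q ** 2 * (1 - q) + q ** 3


def _marginal(prob_fn, b: float, a: float,
              components: Sequence[tuple[float, float]]) -> float:
    """Marginal keyed probability under a normal-mixture trait."""
    if np.isinf(a):
        # step response functions: keyed iff theta > b, for the recall
        # count too (all three words flip together)
        return float(sum(w * sps.norm.sf(b - mean) for w, mean in components))
    total = 0.0
    for w, mean in components:
        theta = mean + np.sqrt(2.0) * _GH_NODES
        total += w * np.sum(_GH_WEIGHTS * prob_fn(theta, a, b)) / np.sqrt(np.pi)
    return total


def calibrate_item_locations(target_difficulties: Mapping[str, float],
                             discrimination: float,
                             components: Sequence[tuple[float, float]],
                             prob_fn=None) -> dict[str, float]:
    """Solve each item's location so its marginal difficulty hits its target.

    ``components`` is the trait distribution as a list of
    ``(weight, mean)`` unit-variance normal mixture components.  The
    marginal probability of the keyed response must equal
    ``1 - target``; a one-dimensional root find per item achieves a
    residual below 1e-6.  Raises if a target is unattainable under the
    configured mixture.
    """
    weights = [w for w, _ in components]
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    fn = prob_fn or _irf
    out = {}
    lo, hi = -40.0, 40.0
    for item, target in target_difficulties.items():
        if not 0 < target < 1:
            raise ValueError(f"target difficulty for {item!r} must lie in (0, 1)")
        keyed = 1.0 - target

        def g(b, keyed=keyed):
            return _marginal(fn, b, discrimination, components) - keyed

        if not (g(lo) > 0 > g(hi)):
            raise ValueError(f"target {target} unattainable for item {item!r} "
                             "under the configured trait mixture")
        b = optimize.brentq(g, lo, hi, xtol=1e-12)
        if abs(g(b)) > 1e-6:
            raise ValueError(f"calibration failed to converge for item {item!r}")
        out[item] = float(b)
    return out


def _cognitive_components(cfg: GeneratorConfig) -> list[tuple[float, float]]:
    """Trait mixture seen by cognitive items (education DIF folded in)."""
    comps = []
    for w_case, mean in (((1 - cfg.prevalence), 0.0),
                         (cfg.prevalence, cfg.case_offset)):
        comps.append((w_case * (1 - cfg.p_low_education), mean))
        comps.append((w_case * cfg.p_low_education, mean - cfg.education_dif))
    return comps


def _informant_components(cfg: GeneratorConfig) -> list[tuple[float, float]]:
    """Impairment (= -trait) mixture seen by informant items."""
    return [((1 - cfg.prevalence), 0.0), (cfg.prevalence, -cfg.case_offset)]


def _calibrate_all(cfg: GeneratorConfig) -> dict[str, dict]:
    """Item parameters for the full brief bank under the population mixture."""
    a = cfg.discrimination
    cog_targets = {it.item_id: cfg.target_difficulties[it.item_id]
                   for it in BRIEF_COGNITIVE_ITEMS}
    inf_targets = {it.item_id: cfg.target_difficulties[it.item_id]
                   for it in BRIEF_INFORMANT_ITEMS}
    cog_comps = _cognitive_components(cfg)
    inf_comps = _informant_components(cfg)

    params: dict[str, dict] = {}
    binary_targets = {k: v for k, v in cog_targets.items() if k != "recall_3words"}
    for item, b in calibrate_item_locations(binary_targets, a, cog_comps).items():
        params[item] = {"kind": "binary", "a": a, "b": b}
    recall_b = calibrate_item_locations(
        {"recall_3words": cog_targets["recall_3words"]}, a, cog_comps,
        prob_fn=_recall_keyed_prob)["recall_3words"]
    params["recall_3words"] = {"kind": "recall", "a": a, "b": recall_b}

    inf_locs = calibrate_item_locations(inf_targets, a, inf_comps)
    for it in BRIEF_INFORMANT_ITEMS:
        cut = DEFAULT_CUTS[it.item_id]
        c_keyed = inf_locs[it.item_id]
        if cut == 2:
            c1, c2 = c_keyed - cfg.level_gap, c_keyed
        else:
            c1, c2 = c_keyed, c_keyed + cfg.level_gap
        params[it.item_id] = {"kind": "graded", "a": a, "c1": c1, "c2": c2,
                              "keyed_cut": cut}
    return params


# ---------------------------------------------------------------------------
# response generation


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def _draw_responses(rng: np.random.Generator, theta: np.ndarray,
                    low_education: np.ndarray,
                    params: dict[str, dict],
                    education_dif: float) -> dict[str, np.ndarray]:
    """Draw raw item codes for every brief item, in fixed bank order."""
    out = {}
    eta = -theta
    for it in BRIEF_ITEM_BANK:
        p = params[it.item_id]
        if p["kind"] == "binary":
            b_eff = p["b"] + education_dif * low_education
            prob = _irf(theta, p["a"], b_eff)
            out[it.item_id] = (rng.random(len(theta)) < prob).astype(float)
        elif p["kind"] == "recall":
            b_eff = p["b"] + education_dif * low_education
            prob = _irf(theta, p["a"], b_eff)
            words = rng.random((len(theta), 3)) < prob[:, None]
            out[it.item_id] = words.sum(axis=1).astype(float)
        else:   # graded informant item on the impairment scale
            p1 = _irf(eta, p["a"], p["c1"])   # P(level >= 1)
            p2 = _irf(eta, p["a"], p["c2"])   # P(level >= 2)
            u = rng.random(len(theta))
            out[it.item_id] = ((u < p1).astype(float) + (u < p2).astype(float))
    return out


def _assemble(cfg: GeneratorConfig, theta, is_case, severity, low_education,
              region, params) -> SyntheticCohort:
    rng = _rng(cfg.seed + 1)   # responses use a stream separate from the design draw
    responses = _draw_responses(rng, theta, low_education, params,
                                cfg.education_dif)
    n = len(theta)
    sid = [f"S{i:06d}" for i in range(n)]
    sev = np.where(is_case, np.where(severity, "moderate", "mild"), None)
    data = pd.DataFrame({"subject_id": sid})
    for it in BRIEF_ITEM_BANK:
        data[it.item_id] = responses[it.item_id]
    data["diagnosis"] = is_case.astype(float)
    data["severity"] = pd.Series(sev, dtype=object)
    data["education"] = np.where(low_education, "low", "high")
    data["region"] = region
    cohort = CohortTable(data, BRIEF_ITEM_BANK)
    truth = pd.DataFrame({"subject_id": sid, "theta": theta,
                          "group": np.where(is_case, "case", "control"),
                          "severity": pd.Series(sev, dtype=object),
                          "education": data["education"]})
    return SyntheticCohort(cohort, truth, params)


def generate_population(config: GeneratorConfig) -> SyntheticCohort:
    """Population-survey design: prevalence-mixed cases and controls.

    Cases' traits are shifted by ``case_offset``; the more impaired
    fraction (below ``moderate_quantile`` of the case trait
    distribution) is labelled moderate, the remainder mild.
    """
    cfg = config
    if cfg.n < 2:
        raise ValueError("need at least 2 subjects")
    params = _calibrate_all(cfg)
    rng = _rng(cfg.seed)
    is_case = rng.random(cfg.n) < cfg.prevalence
    low_education = rng.random(cfg.n) < cfg.p_low_education
    theta = rng.standard_normal(cfg.n) + cfg.case_offset * is_case
    sev_threshold = cfg.case_offset + sps.norm.ppf(cfg.moderate_quantile)
    severity = is_case & (theta < sev_threshold)
    return _assemble(cfg, theta, is_case, severity, low_education,
                     "synthetic-population", params)


def generate_case_control(config: GeneratorConfig) -> SyntheticCohort:
    """Pilot-style case-control design with four recruitment groups.

    Mild and moderate dementia cases (severity-specific trait offsets)
    and high-/low-education control groups; case education follows
    ``p_low_education``.
    """
    cfg = config
    sizes = (cfg.n_mild, cfg.n_moderate,
             cfg.n_high_education_controls, cfg.n_low_education_controls)
    if any(s < 1 for s in sizes):
        raise ValueError("every case-control group needs at least 1 subject")
    params = _calibrate_all(cfg)
    rng = _rng(cfg.seed)
    n = sum(sizes)
    offsets = np.concatenate([
        np.full(cfg.n_mild, cfg.mild_offset),
        np.full(cfg.n_moderate, cfg.moderate_offset),
        np.zeros(cfg.n_high_education_controls),
        np.zeros(cfg.n_low_education_controls),
    ])
    is_case = np.concatenate([
        np.ones(cfg.n_mild + cfg.n_moderate, dtype=bool),
        np.zeros(cfg.n_high_education_controls + cfg.n_low_education_controls,
                 dtype=bool),
    ])
    severity = np.concatenate([
        np.zeros(cfg.n_mild, dtype=bool),
        np.ones(cfg.n_moderate, dtype=bool),
        np.zeros(n - cfg.n_mild - cfg.n_moderate, dtype=bool),
    ])
    case_low_ed = rng.random(cfg.n_mild + cfg.n_moderate) < cfg.p_low_education
    low_education = np.concatenate([
        case_low_ed,
        np.zeros(cfg.n_high_education_controls, dtype=bool),
        np.ones(cfg.n_low_education_controls, dtype=bool),
    ])
    theta = rng.standard_normal(n) + offsets
    return _assemble(cfg, theta, is_case, severity, low_education,
                     "synthetic-pilot", params)


def generate(config: GeneratorConfig) -> SyntheticCohort:
    """Dispatch on ``config.design``."""
    if config.design == "population":
        return generate_population(config)
    return generate_case_control(config)


# ---------------------------------------------------------------------------
# planted-subset item pool (for selection parameter-recovery studies)


def generate_informant_pool(n: int = 5000, n_items: int = 26, n_strong: int = 6,
                            strong_discrimination: float = 3.0,
                            weak_discrimination: float = 0.5,
                            prevalence: float = 0.06,
                            case_offset: float = -2.75,
                            seed: int = 0) -> tuple[CohortTable, list[str]]:
    """Binary informant-style item pool with a planted high-H subset.

    ``n_strong`` items get a high common discrimination (and the
    published brief-scale difficulty spread); the remaining items are
    weakly discriminating noise items with difficulties spread over
    (0.3, 0.95).  Returns the cohort and the planted item ids — the
    ground truth for selection parameter-recovery tests.
    """
    if not 2 <= n_strong < n_items:
        raise ValueError("need 2 <= n_strong < n_items")
    comps = [(1 - prevalence, 0.0), (prevalence, -case_offset)]
    strong_diff = [0.523, 0.661, 0.770, 0.850, 0.915, 0.975][:n_strong]
    if n_strong > 6:
        strong_diff = list(np.linspace(0.5, 0.98, n_strong))
    weak_diff = np.linspace(0.30, 0.95, n_items - n_strong)

    items, params = [], []
    for k in range(n_strong):
        items.append(ItemDefinition(f"strong_{k:02d}", f"planted item {k}",
                                    "informant", 2, "symptom_present", f"dom_s{k}"))
        params.append((strong_discrimination, strong_diff[k]))
    for k in range(n_items - n_strong):
        items.append(ItemDefinition(f"weak_{k:02d}", f"noise item {k}",
                                    "informant", 2, "symptom_present", f"dom_w{k}"))
        params.append((weak_discrimination, weak_diff[k]))

    locations = []
    for a, d in params:
        locations.append(calibrate_item_locations({"x": d}, a, comps)["x"])

    rng = _rng(seed)
    is_case = rng.random(n) < prevalence
    eta = rng.standard_normal(n) - case_offset * is_case
    data = {"subject_id": [f"S{i:06d}" for i in range(n)]}
    for it, (a, _), b in zip(items, params, locations):
        prob = _irf(eta, a, b)
        data[it.item_id] = (rng.random(n) < prob).astype(float)
    cohort = CohortTable(pd.DataFrame(data), tuple(items))
    return cohort, [it.item_id for it in items[:n_strong]]
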