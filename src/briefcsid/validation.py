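"""ROC validation of brief scores against a gold-standard diagnosis.

Empirical ROC analysis for discrete screening scores: the full operating
curve, the area under it (the probability that a random case is ranked
more impaired than a random control, ties counted half) with a DeLong or
Hanley-McNeil confidence interval, Youden-optimal cutpoints with the
dual specificity-/sensitivity-favouring reporting convention, and
sensitivity/specificity stratified by case severity and control
education.

Scores are integers, so thresholds are evaluated at half-integers
(midpoints between adjacent observed values) and every cutpoint carries
an explicit direction: on the cognitive scale low scores indicate
impairment, on the informant scale high scores do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import Cutpoint

__all__ = ["roc_curve", "auroc", "AurocEstimate", "youden", "optimal_cutpoint",
           "CutpointResult", "stratified_validation", "ScreeningValidation",
           "ValidationResults", "validate_scores"]

_DIRECTIONS = ("lower_is_positive", "higher_is_positive")


def _check_inputs(scores, labels, direction):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    keep = ~(np.isnan(scores) | np.isnan(labels))
    scores, labels = scores[keep], labels[keep]
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("labels must include at least one case and one control")
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    return scores, labels


def _impairment(scores: np.ndarray, direction: str) -> np.ndarray:
    """Orient scores so that higher always means more impaired."""
    return -scores if direction == "lower_is_positive" else scores


def roc_curve(scores, labels, direction: str = "higher_is_positive") -> pd.DataFrame:
    """Empirical ROC curve: one row per threshold plus both endpoints.

    Thresholds are midpoints between adjacent distinct score values, on
    the original score scale; a subject screens positive when the score
    is beyond the threshold in the impaired direction.  Endpoint rows
    (sensitivity 0/specificity 1 and sensitivity 1/specificity 0) carry
    infinite thresholds.
    """
    scores, labels = _check_inputs(scores, labels, direction)
    s = _impairment(scores, direction)
    cases, controls = s[labels == 1], s[labels == 0]
    u = np.unique(s)
    mids = (u[:-1] + u[1:]) / 2.0
    thr_imp = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    sens = [(cases > t).mean() for t in thr_imp]
    spec = [(controls <= t).mean() for t in thr_imp]
    thr = -thr_imp if direction == "lower_is_positive" else thr_imp
    df = pd.DataFrame({"threshold": thr, "sensitivity": sens,
                       "specificity": spec})
    df["fpr"] = 1.0 - df["specificity"]
    df["youden"] = df["sensitivity"] + df["specificity"] - 1.0
    return df


@dataclass(frozen=True)
class AurocEstimate:
    auc: float
    ci_low: float
    ci_high: float
    method: str
    n_cases: int
    n_controls: int

    def __iter__(self):
        return iter((self.auc, self.ci_low, self.ci_high))


def _delong(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """AUROC and its DeLong variance via midrank placements."""
    m, n = len(cases), len(controls)
    all_scores = np.concatenate([cases, controls])
    r_all = sps.rankdata(all_scores)
    r_cases = sps.rankdata(cases)
    r_controls = sps.rankdata(controls)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (r_all[:m] - r_cases) / n          # per-case placements
    v10 = 1.0 - (r_all[m:] - r_controls) / m  # per-control placements
    var = 0.0
    if m > 1:
        var += v01.var(ddof=1) / m
    if n > 1:
        var += v10.var(ddof=1) / n
    return float(auc), float(var)


def auroc(scores, labels, direction: str = "higher_is_positive",
          ci_method: str = "delong", level: float = 0.95) -> AurocEstimate:
    """Area under the ROC curve with a confidence interval.

    The point estimate is the rank statistic (Mann-Whitney with the
    half-tie convention).  The interval is DeLong (default) or
    Hanley-McNeil, truncated to [0, 1].
    """
    scores, labels = _check_inputs(scores, labels, direction)
    s = _impairment(scores, direction)
    cases, controls = s[labels == 1], s[labels == 0]
    auc, var = _delong(cases, controls)
    m, n = len(cases), len(controls)
    if ci_method == "delong":
        se = np.sqrt(var)
    elif ci_method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc ** 2 / (1 + auc)
        se = np.sqrt((auc * (1 - auc) + (m - 1) * (q1 - auc ** 2)
                      + (n - 1) * (q2 - auc ** 2)) / (m * n))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    z = sps.norm.ppf(0.5 + level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return AurocEstimate(auc, lo, hi, ci_method, m, n)


def youden(sensitivity: float, specificity: float) -> float:
    """Youden's index J = sensitivity + specificity - 1."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sensitivity + specificity - 1.0


@dataclass(frozen=True)
class CutpointResult:
    cutpoint: Cutpoint
    sensitivity: float
    specificity: float
    youden: float
    favors: str           # "balanced" | "specificity" | "sensitivity"

    @property
    def notation(self) -> str:
        return self.cutpoint.notation


def optimal_cutpoint(roc: pd.DataFrame, direction: str = "higher_is_positive",
                     preference: str = "max_youden",
                     delta_j: float = 0.05) -> list[CutpointResult]:
    """Youden-optimal cutpoint(s) from an ROC table.

    Returns the threshold maximising J.  When an adjacent threshold
    comes within ``delta_j`` of the maximum, both are reported, ordered
    (specificity-favouring, sensitivity-favouring) — the dual "<6"/"<7"
    reporting style.  ``preference`` picks a single side instead:
    ``favor_specificity`` or ``favor_sensitivity``.
    """
    interior = roc[np.isfinite(roc["threshold"])].reset_index(drop=True)
    if len(interior) == 0:
        raise ValueError("degenerate ROC curve: no interior operating point "
                         "(all scores identical?)")
    j = interior["youden"].to_numpy()
    best = int(np.argmax(j))
    chosen = [best]
    neighbors = [i for i in (best - 1, best + 1) if 0 <= i < len(interior)]
    close = [i for i in neighbors if j[best] - j[i] <= delta_j]
    if close:
        chosen.append(max(close, key=lambda i: (j[i], -abs(i - best))))

    def result(i: int, favors: str) -> CutpointResult:
        row = interior.iloc[i]
        return CutpointResult(Cutpoint(float(row["threshold"]), direction),
                              float(row["sensitivity"]), float(row["specificity"]),
                              float(row["youden"]), favors)

    if len(chosen) == 1:
        return [result(best, "balanced")]
    a, b = chosen
    spec_first, sens_first = ((a, b) if interior.iloc[a]["specificity"]
                              >= interior.iloc[b]["specificity"] else (b, a))
    pair = [result(spec_first, "specificity"), result(sens_first, "sensitivity")]
    if preference == "favor_specificity":
        return [pair[0]]
    if preference == "favor_sensitivity":
        return [pair[1]]
    return pair


def _rate(mask_num: np.ndarray, mask_den: np.ndarray) -> float:
    den = int(mask_den.sum())
    return float(mask_num[mask_den].mean()) if den else float("nan")


def stratified_validation(scores, labels, cutpoint: Cutpoint,
                          severity=None, education=None) -> dict:
    """Sensitivity by case severity and specificity by control education.

    Severity strata apply to cases, education strata to controls, at
    the fixed screening ``cutpoint``.  An empty stratum is reported as
    NaN and listed under ``not_estimable``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    positive = np.asarray(cutpoint.is_positive(scores))
    cases, controls = labels == 1, labels == 0
    out = {
        "cutpoint": cutpoint.notation,
        "sensitivity": _rate(positive, cases),
        "specificity": _rate(~positive, controls),
        "by_severity": {},
        "by_education": {},
        "not_estimable": [],
    }
    if severity is not None:
        severity = np.asarray(severity, dtype=object)
        for level in ("mild", "moderate"):
            mask = cases & (severity == level)
            val = _rate(positive, mask)
            out["by_severity"][level] = val
            if np.isnan(val):
                out["not_estimable"].append(f"severity:{level}")
    if education is not None:
        education = np.asarray(education, dtype=object)
        for level in ("low", "high"):
            mask = controls & (education == level)
            val = _rate(~positive, mask)
            out["by_education"][level] = val
            if np.isnan(val):
                out["not_estimable"].append(f"education:{level}")
    return out


# ---------------------------------------------------------------------------
# model / results objects


class ScreeningValidation:
    """ROC validation model for one brief scale against a gold standard.

    Parameters
    ----------
    scores, labels : array-like
        Screening score and binary diagnosis per subject (NaN rows are
        dropped pairwise).
    direction : {"lower_is_positive", "higher_is_positive"}
        Which end of the score indicates impairment.
    severity, education : array-like, optional
        Per-subject strata for the stratified sensitivity/specificity.
    """

    def __init__(self, scores, labels, direction: str = "higher_is_positive",
                 severity=None, education=None, scale: str = "",
                 region: str = "", ci_method: str = "delong",
                 delta_j: float = 0.05):
        raw_scores = np.asarray(scores, dtype=float)
        raw_labels = np.asarray(labels, dtype=float)
        keep = ~(np.isnan(raw_scores) | np.isnan(raw_labels))
        self.scores = raw_scores[keep]
        self.labels = raw_labels[keep]
        self.severity = (np.asarray(severity, dtype=object)[keep]
                         if severity is not None else None)
        self.education = (np.asarray(education, dtype=object)[keep]
                          if education is not None else None)
        self.direction = direction
        self.scale = scale
        self.region = region
        self.ci_method = ci_method
        self.delta_j = delta_j

    @classmethod
    def from_scored(cls, scored: pd.DataFrame, scale: str = "combined",
                    **kwargs) -> "ScreeningValidation":
        """Build from a ``score_cohort`` frame with a ``diagnosis`` column."""
        col = {"cognitive": "cognitive_total", "informant": "informant_total",
               "combined": "combined"}[scale]
        direction = ("higher_is_positive" if scale == "informant"
                     else "lower_is_positive")
        return cls(scored[col], scored["diagnosis"], direction=direction,
                   severity=scored.get("severity"),
                   education=scored.get("education"), scale=scale, **kwargs)

    def fit(self) -> "ValidationResults":
        roc = roc_curve(self.scores, self.labels, self.direction)
        est = auroc(self.scores, self.labels, self.direction, self.ci_method)
        cut = optimal_cutpoint(roc, self.direction, delta_j=self.delta_j)
        strata = stratified_validation(self.scores, self.labels,
                                       cut[0].cutpoint, self.severity,
                                       self.education)
        return ValidationResults(self, roc, est, cut, strata)


@dataclass
class ValidationResults:
    """Fitted ROC validation: curve, AUROC with CI, cutpoints, strata."""

    model: ScreeningValidation
    roc: pd.DataFrame
    auroc: AurocEstimate
    cutpoints: list[CutpointResult]
    strata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per reported cutpoint, validity-table shaped."""
        rows = []
        for c in self.cutpoints:
            rows.append({
                "region": self.model.region, "scale": self.model.scale,
                "auroc": self.auroc.auc, "ci_low": self.auroc.ci_low,
                "ci_high": self.auroc.ci_high, "cutpoint": c.notation,
                "sensitivity": c.sensitivity, "specificity": c.specificity,
                "youden": c.youden, "favors": c.favors,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        a = self.auroc
        lines = [f"ROC validation — scale: {self.model.scale or '?'}"
                 + (f", region: {self.model.region}" if self.model.region else ""),
                 f"cases: {a.n_cases}, controls: {a.n_controls}",
                 f"AUROC {a.auc:.2f} ({a.ci_low:.2f}-{a.ci_high:.2f}, {a.method})"]
        for c in self.cutpoints:
            lines.append(f"cutpoint {c.notation}: sensitivity {c.sensitivity:.1%}, "
                         f"specificity {c.specificity:.1%}, J = {c.youden:.2f} "
                         f"({c.favors})")
        for name, block in (("severity", self.strata.get("by_severity", {})),
                            ("education", self.strata.get("by_education", {}))):
            for level, val in block.items():
                metric = "sensitivity" if name == "severity" else "specificity"
                shown = "not estimable" if np.isnan(val) else f"{val:.1%}"
                lines.append(f"{metric} ({name} {level}): {shown}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Plot the ROC curve; returns the matplotlib axes."""
        import matplotlib
        if ax is None:
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt
            _, ax = plt.subplots()
        ax.plot(self.roc["fpr"], self.roc["sensitivity"], marker="o", lw=1)
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        label = self.model.scale or "scale"
        ax.set_title(f"{label}: AUROC {self.auroc.auc:.2f}")
        return ax


def validate_scores(scored: pd.DataFrame, region: str = "",
                    ci_method: str = "delong",
                    delta_j: float = 0.05) -> dict[str, ValidationResults]:
    """Run the ROC validation for all three brief scales of a scored cohort."""
    out = {}
    for scale in ("cognitive", "informant", "combined"):
        model = ScreeningValidation.from_scored(scored, scale, region=region,
                                                ci_method=ci_method,
                                                delta_j=delta_j)
        out[scale] = model.fit()
    return out
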