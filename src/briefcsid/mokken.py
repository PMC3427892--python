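"""Nonparametric item response theory (Mokken) scaling engine.

Given a binary keyed matrix, this module computes item difficulties,
observed and expected Guttman error counts, Loevinger scalability
coefficients (pairwise H_ij, per-item H_i, whole-scale H) with normal
approximation z statistics, and the two model-assumption diagnostics of
the monotone homogeneity / double monotonicity framework:

* monotonicity, via rest-score groups (the probability of the keyed
  response must not decrease with the rest score), and
* non-intersection, via the P(++) / P(--) matrix method (joint keyed
  and joint unkeyed probabilities must be ordered consistently with the
  item difficulty ordering).

Definitions.  For an item, difficulty is the proportion of analysed
subjects *not* giving the keyed response, so easy, commonly-passed items
have low values.  For a pair with the harder item h and the easier item
e, a Guttman error is the pattern (keyed on h, not keyed on e); the
observed count is F, the expected count under marginal independence is
E = n * P(h keyed) * P(e not keyed), and H = 1 - F/E.  z statistics use
the conditional (fixed margins, hypergeometric) variance of F, so that
z = (E - F) / sd(F) is positive when fewer errors are observed than
independence predicts; aggregate z's sum pairwise variances.

The model-object interface mirrors statsmodels: build a
:class:`MokkenScale` from a keyed matrix (or a cohort), call
``fit()``, and read coefficient tables and diagnostics off the returned
:class:`MokkenScaleResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .items import CohortTable, ItemDefinition, KeyedMatrix, key_responses

__all__ = [
    "MokkenScale", "MokkenScaleResults", "PairwiseStats", "ItemScalability",
    "ScaleScalability", "AssumptionReport", "item_difficulty",
    "pairwise_guttman", "loevinger_from_counts", "z_statistic",
    "scale_scalability", "check_monotonicity", "check_nonintersection_pmatrix",
    "scalability_band", "crit_band",
]

# Scalability bands for Loevinger coefficients.
H_WEAK, H_MODERATE, H_STRONG = 0.30, 0.40, 0.50
# Crit bands for assumption diagnostics.
CRIT_SATISFACTORY, CRIT_VIOLATION = 40.0, 80.0


def scalability_band(h: float) -> str:
    """Classify a Loevinger coefficient: unscalable / weak / moderate / strong."""
    if np.isnan(h):
        return "undefined"
    if h >= H_STRONG:
        return "strong"
    if h >= H_MODERATE:
        return "moderate"
    if h >= H_WEAK:
        return "weak"
    return "unscalable"


def crit_band(crit: float) -> str:
    """Classify a Crit diagnostic: <=40 satisfactory, 40-79 questionable, >=80 violation."""
    if np.isnan(crit):
        return "not_assessable"
    if crit <= CRIT_SATISFACTORY:
        return "satisfactory"
    if crit < CRIT_VIOLATION:
        return "questionable"
    return "violation"


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class PairwiseStats:
    """Guttman error statistics for one item pair (symmetric in i, j)."""

    item_i: str
    item_j: str
    n: int
    F: float
    E: float
    H: float
    z: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class ItemScalability:
    item_id: str
    n: int
    difficulty: float
    F: float
    E: float
    H: float
    z: float
    p: float
    band: str


@dataclass
class ScaleScalability:
    """Per-item and whole-scale Loevinger statistics.

    Satisfies the aggregation identities F_total = sum(F_i)/2 and
    E_total = sum(E_i)/2 (each pair counted once), H_total = 1 - F/E.
    """

    items: list[ItemScalability]
    pairwise: list[PairwiseStats]
    F_total: float
    E_total: float
    H_total: float
    z_total: float
    p_total: float
    n: int

    @property
    def band(self) -> str:
        return scalability_band(self.H_total)

    def item_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(it) for it in self.items])
        return df.set_index("item_id")

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairwise])

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "F_total": self.F_total, "E_total": self.E_total,
            "H_total": self.H_total, "z_total": self.z_total,
            "p_total": self.p_total, "band": self.band,
            "items": [vars(it) for it in self.items],
        }


@dataclass
class AssumptionReport:
    """Diagnostics for one assumption check over all items of a scale.

    ``table`` has one row per item: active comparison count ``n_ac``,
    violation count ``n_vi`` (decreases of at least ``minvi``), the
    largest and summed violations, the count significant at ``alpha``,
    the composite Crit statistic and its band.  Items that cannot be
    assessed (constant responses, too few groups) carry
    ``assessable = False`` and NaN statistics.
    """

    check: str                     # "monotonicity" | "non_intersection"
    settings: dict
    table: pd.DataFrame

    @property
    def n_violations(self) -> int:
        return int(np.nansum(self.table["n_vi"].to_numpy(float)))

    @property
    def max_crit(self) -> float:
        vals = self.table.loc[self.table["assessable"], "crit"]
        return float(vals.max()) if len(vals) else float("nan")

    def summary(self) -> str:
        lines = [f"Assumption check: {self.check}",
                 f"settings: {self.settings}",
                 self.table.to_string()]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# core computations


def _as_values(matrix) -> np.ndarray:
    if isinstance(matrix, KeyedMatrix):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(float)
    v = np.asarray(matrix, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected a 2-d subjects-by-items matrix")
    ok = np.isnan(v) | (v == 0) | (v == 1)
    if not ok.all():
        raise ValueError("keyed matrix must contain only 0, 1 or missing")
    return v


def _item_ids(matrix, p: int) -> list[str]:
    if isinstance(matrix, KeyedMatrix):
        return list(matrix.item_ids)
    if isinstance(matrix, pd.DataFrame):
        return [str(c) for c in matrix.columns]
    return [f"item_{k}" for k in range(p)]


def _pairwise_arrays(V: np.ndarray) -> dict:
    """Vectorised pairwise Guttman error computation on 0/1/NaN data.

    All statistics are computed on pairwise-complete cases; the
    harder/easier ordering of each pair uses difficulties within the
    pair's complete cases, ties broken by ascending column index (the
    lower-indexed item is treated as easier).
    """
    M = (~np.isnan(V)).astype(float)
    A = np.where(np.nan_to_num(V) == 1.0, M, 0.0)   # keyed indicator
    B = M - A                                        # unkeyed indicator
    N = M.T @ M                                      # pairwise n
    C11 = A.T @ A
    C10 = A.T @ B                                    # count(X_i=1, X_j=0)
    C00 = B.T @ B
    ones_i = C11 + C10                               # count X_i=1 within pair
    zeros_i = C00 + C10.T                            # count X_i=0 within pair
    with np.errstate(divide="ignore", invalid="ignore"):
        d_i = zeros_i / N                            # difficulty of i within pair
    d_j = d_i.T
    idx = np.arange(V.shape[1])
    i_harder = (d_i > d_j) | ((d_i == d_j) & (idx[:, None] > idx[None, :]))
    F = np.where(i_harder, C10, C10.T)
    Rh = np.where(i_harder, ones_i, ones_i.T)        # harder item keyed count
    Ce0 = np.where(i_harder, zeros_i.T, zeros_i)     # easier item unkeyed count
    with np.errstate(divide="ignore", invalid="ignore"):
        E = Rh * Ce0 / N
        Var = Rh * Ce0 * (N - Rh) * (N - Ce0) / (N ** 2 * (N - 1))
    degenerate = ((ones_i == 0) | (zeros_i == 0) | (ones_i.T == 0)
                  | (zeros_i.T == 0) | (N < 2))
    np.fill_diagonal(degenerate, True)
    return {"N": N, "F": F, "E": E, "Var": Var, "degenerate": degenerate}


def item_difficulty(matrix, item: int | str | None = None):
    """Proportion of analysed subjects not giving the keyed response.

    With ``item=None`` returns the vector of difficulties for every
    column.  Raises if an item has no non-missing responses.
    """
    V = _as_values(matrix)
    ids = _item_ids(matrix, V.shape[1])
    n = (~np.isnan(V)).sum(axis=0)
    if (n == 0).any() and item is None:
        bad = ids[int(np.argmax(n == 0))]
        raise ValueError(f"item {bad!r} has no non-missing responses")
    with np.errstate(invalid="ignore"):
        diff = np.nansum(1.0 - V, axis=0) / n
    if item is None:
        return diff
    j = ids.index(item) if isinstance(item, str) else int(item)
    if n[j] == 0:
        raise ValueError(f"item {ids[j]!r} has no non-missing responses")
    return float(diff[j])


def loevinger_from_counts(F: float, E: float) -> float:
    """Loevinger coefficient H = 1 - F/E from observed and expected errors."""
    if E <= 0:
        raise ValueError("expected Guttman error count must be positive")
    return 1.0 - F / E


def z_statistic(F: float, E: float, var: float) -> float:
    """Normal-approximation statistic (E - F) / sd(F); positive when F < E."""
    if var <= 0:
        raise ValueError("variance must be positive (degenerate pair?)")
    return (E - F) / np.sqrt(var)


def pairwise_guttman(matrix, i: int | str, j: int | str) -> PairwiseStats:
    """Guttman error statistics for one item pair on pairwise-complete cases."""
    V = _as_values(matrix)
    ids = _item_ids(matrix, V.shape[1])
    ii = ids.index(i) if isinstance(i, str) else int(i)
    jj = ids.index(j) if isinstance(j, str) else int(j)
    if ii == jj:
        raise ValueError("pairwise statistics need two distinct items")
    sub = V[:, [ii, jj]]
    arr = _pairwise_arrays(sub)
    n = int(arr["N"][0, 1])
    if n < 1:
        raise ValueError("no complete cases for the pair")
    F, E, var = float(arr["F"][0, 1]), float(arr["E"][0, 1]), float(arr["Var"][0, 1])
    degen = bool(arr["degenerate"][0, 1])
    if degen:
        return PairwiseStats(ids[ii], ids[jj], n, F, E,
                             float("nan"), float("nan"), float("nan"), True)
    H = loevinger_from_counts(F, E)
    z = z_statistic(F, E, var)
    p = float(sps.norm.sf(z))
    return PairwiseStats(ids[ii], ids[jj], n, F, E, H, z, p, False)


def scale_scalability(matrix, item_ids: Sequence[str] | None = None) -> ScaleScalability:
    """Aggregate pairwise Guttman statistics into item and scale coefficients.

    Degenerate pairs (an item constant within the pair's complete cases)
    are excluded from all aggregates.  Raises when every pair is
    degenerate.
    """
    V = _as_values(matrix)
    ids = list(item_ids) if item_ids is not None else _item_ids(matrix, V.shape[1])
    p = V.shape[1]
    if p < 2:
        raise ValueError("scalability needs at least 2 items")
    arr = _pairwise_arrays(V)
    valid = ~arr["degenerate"]
    if not valid.any():
        raise ValueError("all item pairs are degenerate")
    Fm, Em, Varm = arr["F"] * valid, arr["E"] * valid, arr["Var"] * valid
    Fi, Ei, Vari = Fm.sum(1), Em.sum(1), Varm.sum(1)
    nz = Ei > 0
    Hi = np.where(nz, 1.0 - Fi / np.where(nz, Ei, 1.0), np.nan)
    zi = np.where(Vari > 0, (Ei - Fi) / np.sqrt(np.where(Vari > 0, Vari, 1.0)), np.nan)
    pi = sps.norm.sf(zi)
    n_item = (~np.isnan(V)).sum(axis=0)
    diff = item_difficulty(V)

    items = [ItemScalability(ids[k], int(n_item[k]), float(diff[k]),
                             float(Fi[k]), float(Ei[k]),
                             float(Hi[k]), float(zi[k]), float(pi[k]),
                             scalability_band(float(Hi[k])) if nz[k] else "undefined")
             for k in range(p)]

    F_tot, E_tot, Var_tot = Fi.sum() / 2, Ei.sum() / 2, Vari.sum() / 2
    if E_tot <= 0:
        raise ValueError("expected error count is zero for the whole scale")
    H_tot = loevinger_from_counts(F_tot, E_tot)
    z_tot = z_statistic(F_tot, E_tot, Var_tot)
    p_tot = float(sps.norm.sf(z_tot))

    pairs = []
    for a in range(p):
        for b in range(a + 1, p):
            degen = bool(arr["degenerate"][a, b])
            if degen:
                pairs.append(PairwiseStats(ids[a], ids[b], int(arr["N"][a, b]),
                                           float(arr["F"][a, b]), float(arr["E"][a, b]),
                                           float("nan"), float("nan"), float("nan"), True))
            else:
                z = float((arr["E"][a, b] - arr["F"][a, b]) / np.sqrt(arr["Var"][a, b]))
                pairs.append(PairwiseStats(
                    ids[a], ids[b], int(arr["N"][a, b]),
                    float(arr["F"][a, b]), float(arr["E"][a, b]),
                    1.0 - float(arr["F"][a, b]) / float(arr["E"][a, b]),
                    z, float(sps.norm.sf(z)), False))

    # analysed sample size: rows contributing at least one pair
    n_rows = int((~np.isnan(V)).sum(axis=1).astype(bool).sum())
    return ScaleScalability(items, pairs, float(F_tot), float(E_tot),
                            float(H_tot), float(z_tot), p_tot, n_rows)


# ---------------------------------------------------------------------------
# assumption checks


def _crit(h_i: float, n_ac: int, n_vi: int, maxvi: float, sumvi: float) -> float:
    """Composite Crit diagnostic combining scalability and violation evidence."""
    if n_ac == 0:
        return float("nan")
    h_term = 50.0 * max(0.0, H_WEAK - h_i) if not np.isnan(h_i) else 0.0
    return (h_term + np.sqrt(n_vi) + 100.0 * n_vi / n_ac + 100.0 * maxvi
            + 10.0 * np.sqrt(sumvi) + 1000.0 * sumvi / n_ac)


def _default_group_size(n: int) -> int:
    return max(50, n // 10)


def _rest_score_groups(rest: np.ndarray, min_size: int) -> list[np.ndarray]:
    """Merge adjacent rest-score values (ascending) into groups of >= min_size."""
    groups: list[np.ndarray] = []
    current: list[np.ndarray] = []
    count = 0
    for r in np.unique(rest):
        mask = rest == r
        current.append(np.flatnonzero(mask))
        count += int(mask.sum())
        if count >= min_size:
            groups.append(np.concatenate(current))
            current, count = [], 0
    if current:
        tail = np.concatenate(current)
        if groups:
            groups[-1] = np.concatenate([groups[-1], tail])
        else:
            groups.append(tail)
    return groups


def check_monotonicity(matrix, minvi: float = 0.03, alpha: float = 0.05,
                       min_group_size: int | None = None) -> AssumptionReport:
    """Rest-score check of the monotonicity assumption.

    For each item, subjects are grouped by their rest score (total over
    the other items, complete cases only); the proportion keyed must not
    decrease across ordered groups.  A decrease of at least ``minvi``
    between any ordered pair of groups counts as a violation and is
    additionally tested at level ``alpha`` with a pooled two-proportion
    z test.
    """
    V = _as_values(matrix)
    ids = _item_ids(matrix, V.shape[1])
    if V.shape[1] < 3:
        raise ValueError("monotonicity check needs at least 3 items")
    V = V[~np.isnan(V).any(axis=1)]
    n = V.shape[0]
    gsize = min_group_size if min_group_size is not None else _default_group_size(n)
    scal = scale_scalability(V, ids) if n else None
    zcrit = sps.norm.ppf(1 - alpha)

    rows = []
    for j, item in enumerate(ids):
        col = V[:, j]
        if n == 0 or col.min() == col.max():
            rows.append({"item_id": item, "assessable": False, "n_groups": 0,
                         "n_ac": 0, "n_vi": 0, "maxvi": np.nan, "sumvi": np.nan,
                         "n_sig": 0, "crit": np.nan, "band": "not_assessable"})
            continue
        rest = np.delete(V, j, axis=1).sum(axis=1)
        groups = _rest_score_groups(rest, gsize)
        if len(groups) < 2:
            rows.append({"item_id": item, "assessable": False, "n_groups": len(groups),
                         "n_ac": 0, "n_vi": 0, "maxvi": np.nan, "sumvi": np.nan,
                         "n_sig": 0, "crit": np.nan, "band": "not_assessable"})
            continue
        props = np.array([col[g].mean() for g in groups])
        sizes = np.array([len(g) for g in groups], dtype=float)
        n_ac = n_vi = n_sig = 0
        maxvi = sumvi = 0.0
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                n_ac += 1
                drop = props[a] - props[b]       # a has the lower rest score
                if drop >= minvi:
                    n_vi += 1
                    maxvi = max(maxvi, drop)
                    sumvi += drop
                    pooled = (props[a] * sizes[a] + props[b] * sizes[b]) / (sizes[a] + sizes[b])
                    se = np.sqrt(pooled * (1 - pooled) * (1 / sizes[a] + 1 / sizes[b]))
                    if se > 0 and drop / se > zcrit:
                        n_sig += 1
        h_i = scal.items[j].H if scal is not None else np.nan
        crit = _crit(h_i, n_ac, n_vi, maxvi, sumvi)
        rows.append({"item_id": item, "assessable": True, "n_groups": len(groups),
                     "n_ac": n_ac, "n_vi": n_vi,
                     "maxvi": maxvi if n_vi else 0.0,
                     "sumvi": sumvi if n_vi else 0.0,
                     "n_sig": n_sig, "crit": crit, "band": crit_band(crit)})
    table = pd.DataFrame(rows).set_index("item_id")
    return AssumptionReport("monotonicity",
                            {"minvi": minvi, "alpha": alpha,
                             "min_group_size": gsize, "n": n}, table)


def check_nonintersection_pmatrix(matrix, minvi: float = 0.03,
                                  alpha: float = 0.05) -> AssumptionReport:
    """P-matrix check of the non-intersection (double monotonicity) assumption.

    With items ordered by difficulty, each row of the joint-keyed matrix
    P(++) must be non-increasing and each row of the joint-unkeyed
    matrix P(--) non-decreasing across columns.  Order reversals of at
    least ``minvi`` count as violations, attributed to the row item, and
    are tested at level ``alpha`` with a paired-difference z test.
    """
    V = _as_values(matrix)
    ids = _item_ids(matrix, V.shape[1])
    p = V.shape[1]
    if p < 3:
        raise ValueError("non-intersection check needs at least 3 items")
    V = V[~np.isnan(V).any(axis=1)]
    n = V.shape[0]
    if n < 2:
        raise ValueError("too few complete cases")
    diff = item_difficulty(V)
    nondegen = (V.min(axis=0) == 0) & (V.max(axis=0) == 1)
    order = sorted(range(p), key=lambda k: (diff[k], k))   # easiest first
    order = [k for k in order if nondegen[k]]
    P11 = (V.T @ V) / n
    W = 1.0 - V
    P00 = (W.T @ W) / n
    zcrit = sps.norm.ppf(1 - alpha)
    scal = scale_scalability(V, ids)

    rows = {item: {"item_id": item, "assessable": bool(nondegen[k]), "n_groups": np.nan,
                   "n_ac": 0, "n_vi": 0, "maxvi": 0.0, "sumvi": 0.0, "n_sig": 0,
                   "crit": np.nan, "band": "not_assessable"}
            for k, item in enumerate(ids)}

    for r in order:
        others = [k for k in order if k != r]
        # joint counts among the three items, for the paired variance
        sub1 = V[V[:, r] == 1.0]
        sub0 = V[V[:, r] == 0.0]
        T11 = (sub1.T @ sub1) / n if len(sub1) else np.zeros((p, p))
        W0 = 1.0 - sub0
        T00 = (W0.T @ W0) / n if len(sub0) else np.zeros((p, p))
        rec = rows[ids[r]]
        for a in range(len(others)):
            for b in range(a + 1, len(others)):
                je, jh = others[a], others[b]    # easier, harder column item
                for P, T in ((P11, T11), (P00, T00)):
                    rec["n_ac"] += 1
                    if P is P11:
                        viol = P[r, jh] - P[r, je]   # should be non-increasing
                        p_hi, p_lo = P[r, jh], P[r, je]
                    else:
                        viol = P[r, je] - P[r, jh]   # should be non-decreasing
                        p_hi, p_lo = P[r, je], P[r, jh]
                    if viol >= minvi:
                        rec["n_vi"] += 1
                        rec["maxvi"] = max(rec["maxvi"], viol)
                        rec["sumvi"] += viol
                        p_both = T[je, jh]
                        var = (p_hi * (1 - p_hi) + p_lo * (1 - p_lo)
                               - 2 * (p_both - p_hi * p_lo)) / n
                        if var > 0 and viol / np.sqrt(var) > zcrit:
                            rec["n_sig"] += 1

    out = []
    for k, item in enumerate(ids):
        rec = rows[item]
        if rec["assessable"]:
            h_i = scal.items[k].H
            rec["crit"] = _crit(h_i, rec["n_ac"], rec["n_vi"],
                                rec["maxvi"], rec["sumvi"])
            rec["band"] = crit_band(rec["crit"])
        else:
            rec["maxvi"] = rec["sumvi"] = np.nan
        out.append(rec)
    table = pd.DataFrame(out).set_index("item_id")
    return AssumptionReport("non_intersection",
                            {"minvi": minvi, "alpha": alpha, "n": n}, table)


# ---------------------------------------------------------------------------
# model / results objects


class MokkenScale:
    """Mokken scaling model for one scale of keyed binary items.

    Parameters
    ----------
    matrix : KeyedMatrix, DataFrame or ndarray
        Subject-by-item keyed responses (0/1/NaN).
    item_ids : sequence of str, optional
        Names for plain arrays.
    use : {"complete", "pairwise"}
        Missing-data policy: listwise deletion over the scale's items
        (default, so reported n matches the analysed sample), or
        pairwise-complete cases per item pair.
    """

    def __init__(self, matrix, item_ids: Sequence[str] | None = None,
                 use: str = "complete"):
        if use not in ("complete", "pairwise"):
            raise ValueError("use must be 'complete' or 'pairwise'")
        V = _as_values(matrix)
        ids = list(item_ids) if item_ids is not None else _item_ids(matrix, V.shape[1])
        if use == "complete":
            V = V[~np.isnan(V).any(axis=1)]
        self.values = V
        self.item_ids = ids
        self.use = use

    @classmethod
    def from_cohort(cls, cohort: CohortTable,
                    items: Sequence[ItemDefinition] | None = None,
                    plan=None, use: str = "complete") -> "MokkenScale":
        """Key a cohort's raw responses and build the model."""
        km = key_responses(cohort, items, plan)
        return cls(km, use=use)

    def fit(self) -> "MokkenScaleResults":
        return MokkenScaleResults(self, scale_scalability(self.values, self.item_ids))


class MokkenScaleResults:
    """Fitted Mokken scaling results with diagnostics and export helpers."""

    def __init__(self, model: MokkenScale, scalability: ScaleScalability):
        self.model = model
        self.scalability = scalability

    # -- convenience accessors ---------------------------------------------

    @property
    def item_stats(self) -> pd.DataFrame:
        return self.scalability.item_frame()

    @property
    def pairwise(self) -> pd.DataFrame:
        return self.scalability.pairwise_frame()

    @property
    def scale_H(self) -> float:
        return self.scalability.H_total

    @property
    def scale_z(self) -> float:
        return self.scalability.z_total

    @property
    def n(self) -> int:
        return self.scalability.n

    # -- diagnostics --------------------------------------------------------

    def check_monotonicity(self, minvi: float = 0.03, alpha: float = 0.05,
                           min_group_size: int | None = None) -> AssumptionReport:
        return check_monotonicity(
            pd.DataFrame(self.model.values, columns=self.model.item_ids),
            minvi=minvi, alpha=alpha, min_group_size=min_group_size)

    def check_nonintersection(self, minvi: float = 0.03,
                              alpha: float = 0.05) -> AssumptionReport:
        return check_nonintersection_pmatrix(
            pd.DataFrame(self.model.values, columns=self.model.item_ids),
            minvi=minvi, alpha=alpha)

    # -- reporting ----------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """Item rows plus a whole-scale row, mirroring the usual report layout."""
        s = self.scalability
        df = s.item_frame().reset_index()
        whole = pd.DataFrame([{
            "item_id": "whole_scale", "n": s.n, "difficulty": np.nan,
            "F": s.F_total, "E": s.E_total, "H": s.H_total,
            "z": s.z_total, "p": s.p_total, "band": s.band,
        }])
        return pd.concat([df, whole], ignore_index=True)

    def summary(self) -> str:
        df = self.summary_frame().copy()
        for c, fmt in (("difficulty", "{:.3f}"), ("E", "{:.1f}"), ("H", "{:.2f}"),
                       ("z", "{:.1f}")):
            df[c] = df[c].map(lambda x: "-" if pd.isna(x) else fmt.format(x))
        df["p"] = df["p"].map(lambda x: "<0.00001" if x < 1e-5 else f"{x:.3g}")
        df["F"] = df["F"].map(lambda x: f"{x:.0f}")
        header = (f"Mokken scale analysis (n = {self.n}, "
                  f"H = {self.scale_H:.2f}, {self.scalability.band})")
        return header + "\n" + df.to_string(index=False)

    def to_csv(self, path) -> None:
        self.summary_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        import json
        payload = self.scalability.to_dict()
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return None
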