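"""Mokken engine: difficulties, Guttman errors, H, z, assumption checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from briefcsid import (MokkenScale, check_monotonicity,
                       check_nonintersection_pmatrix, item_difficulty,
                       loevinger_from_counts, pairwise_guttman,
                       scale_scalability, z_statistic)
from briefcsid.mokken import crit_band, scalability_band

from conftest import brute_force_pair_counts, random_keyed_matrix


def perfect_guttman(n_per_step: int = 4, p: int = 4) -> np.ndarray:
    """Deterministic hierarchical matrix: subject i passes the first k_i items."""
    rows = []
    for k in range(p + 1):
        rows += [[1.0] * k + [0.0] * (p - k)] * n_per_step
    return np.array(rows)


# -- difficulties -----------------------------------------------------------


def test_item_difficulty_definition():
    m = np.array([[1, 1], [1, 1], [1, 0], [1, 0]], float)
    assert item_difficulty(m, 0) == 0.0          # everyone keyed
    assert item_difficulty(m, 1) == 0.5
    np.testing.assert_allclose(item_difficulty(m), [0.0, 0.5])


def test_item_difficulty_all_missing_errors():
    m = np.array([[np.nan, 1.0], [np.nan, 0.0]])
    with pytest.raises(ValueError, match="no non-missing"):
        item_difficulty(m, 0)


# -- pairwise Guttman counts ------------------------------------------------


def test_pairwise_guttman_hand_example():
    # harder item (difficulty 0.5) vs easier (0.25): one error pattern
    m = np.column_stack([[1, 1, 0, 0], [1, 0, 1, 1]]).astype(float)
    ps = pairwise_guttman(m, 0, 1)
    assert ps.F == 1.0
    assert ps.E == pytest.approx(4 * 0.5 * 0.25)
    assert ps.H == pytest.approx(-1.0)


def test_pairwise_perfect_guttman_has_no_errors():
    m = np.column_stack([[1, 0, 0, 0], [1, 1, 1, 0]]).astype(float)
    ps = pairwise_guttman(m, 0, 1)
    assert ps.F == 0.0
    assert ps.H == 1.0


def test_pairwise_degenerate_item_flagged():
    m = np.column_stack([[1, 1, 1, 1], [1, 0, 1, 0]]).astype(float)
    ps = pairwise_guttman(m, 0, 1)
    assert ps.degenerate
    assert np.isnan(ps.H)


def test_pairwise_independent_items_h_near_zero(rng):
    n = 20000
    m = np.column_stack([rng.random(n) < 0.5, rng.random(n) < 0.5]).astype(float)
    ps = pairwise_guttman(m, 0, 1)
    assert abs(ps.z) < 3.0
    assert abs(ps.H) < 0.05


def test_pairwise_matches_brute_force_oracle(rng):
    for _ in range(200):
        m = random_keyed_matrix(rng)
        for i in range(m.shape[1]):
            for j in range(i + 1, m.shape[1]):
                n, F, E = brute_force_pair_counts(m[:, i], m[:, j])
                if n == 0:
                    continue
                ps = pairwise_guttman(m, i, j)
                assert ps.n == n
                assert ps.F == F
                assert ps.E == pytest.approx(E)


# -- Loevinger coefficients -------------------------------------------------


def test_loevinger_from_counts():
    assert loevinger_from_counts(0, 100) == 1.0
    assert loevinger_from_counts(50, 100) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        loevinger_from_counts(1, 0)


def test_scalability_bands():
    assert scalability_band(0.25) == "unscalable"
    assert scalability_band(0.35) == "weak"
    assert scalability_band(0.45) == "moderate"
    assert scalability_band(0.55) == "strong"


def test_scale_scalability_perfect_guttman():
    s = scale_scalability(perfect_guttman())
    assert s.H_total == 1.0
    assert all(it.H == 1.0 for it in s.items)


def test_scale_scalability_independent_items(rng):
    n = 10000
    m = (rng.random((n, 5)) < rng.uniform(0.3, 0.7, 5)).astype(float)
    s = scale_scalability(m)
    assert abs(s.z_total) < 3.0


def test_sum_identities_hold_exactly(rng):
    for _ in range(30):
        m = random_keyed_matrix(rng, n_max=30, p_max=6)
        try:
            s = scale_scalability(m)
        except ValueError:
            continue    # all pairs degenerate on a tiny draw
        assert s.F_total == pytest.approx(sum(it.F for it in s.items) / 2, abs=1e-12)
        assert s.E_total == pytest.approx(sum(it.E for it in s.items) / 2, abs=1e-9)
        assert s.H_total == pytest.approx(1 - s.F_total / s.E_total)


def test_h_invariant_under_permutations(rng):
    m = random_keyed_matrix(rng, n_max=40, p_max=5, missing_prob=0.05)
    s0 = scale_scalability(m)
    rows = rng.permutation(m.shape[0])
    cols = rng.permutation(m.shape[1])
    s1 = scale_scalability(m[rows][:, cols])
    assert s1.H_total == pytest.approx(s0.H_total, abs=1e-12)
    h0 = sorted(it.H for it in s0.items)
    h1 = sorted(it.H for it in s1.items)
    np.testing.assert_allclose(h0, h1, atol=1e-12)


# -- z statistic ------------------------------------------------------------


def test_z_sign_contract():
    assert z_statistic(10, 10, 4.0) == 0.0
    assert z_statistic(5, 10, 4.0) > 0
    with pytest.raises(ValueError):
        z_statistic(5, 10, 0.0)


def test_z_type_one_error_calibrated_under_independence(rng):
    """One-sided alpha=0.05 test rejects ~5% of independent-item pairs."""
    n, reps = 400, 1000
    rejections = 0
    for _ in range(reps):
        m = np.column_stack([rng.random(n) < 0.6, rng.random(n) < 0.4]).astype(float)
        ps = pairwise_guttman(m, 0, 1)
        if not ps.degenerate and ps.z > 1.6449:
            rejections += 1
    rate = rejections / reps
    half_width = 2.576 * np.sqrt(0.05 * 0.95 / reps)   # binomial 99% bounds
    assert abs(rate - 0.05) < half_width + 1e-12


# -- monotonicity check -----------------------------------------------------


def _mhm_matrix(rng, n=5000, p=5, a=2.0):
    theta = rng.standard_normal(n)
    b = np.linspace(-1.5, 1.5, p)
    return (rng.random((n, p)) < expit(a * (theta[:, None] - b))).astype(float)


def test_monotonicity_clean_on_mhm_data(rng):
    rep = check_monotonicity(_mhm_matrix(rng))
    assert rep.n_violations == 0
    assert (rep.table.loc[rep.table["assessable"], "band"] == "satisfactory").all()


def _with_dip_item(rng, pfun, n=5000, n_anchor=8):
    """Deterministic anchor items plus one item with an engineered IRF."""
    theta = rng.standard_normal(n)
    b = np.linspace(-1.5, 1.5, n_anchor)
    anchors = (theta[:, None] > b).astype(float)
    dip = (rng.random(n) < np.clip(pfun(theta), 0.02, 0.98)).astype(float)
    return np.column_stack([anchors, dip])


def test_monotonicity_detects_engineered_dip(rng):
    """An IRF that drops by 0.2 over the middle trait range is flagged."""
    def dipped(t):
        p = expit(2.0 * (t + 0.6))
        return np.where((t >= 0.0) & (t <= 1.1),
                        np.minimum(p, expit(1.2)) - 0.2, p)
    rep = check_monotonicity(_with_dip_item(rng, dipped))
    row = rep.table.iloc[-1]
    assert row["n_vi"] >= 1
    assert row["maxvi"] >= 0.03


def test_monotonicity_gross_violation_reaches_violation_band(rng):
    """A grossly non-monotone IRF drives Crit past the violation threshold."""
    def gross(t):
        return np.where((t >= -0.1) & (t <= 1.4), 0.2, expit(3.0 * (t + 0.7)))
    rep = check_monotonicity(_with_dip_item(rng, gross))
    row = rep.table.iloc[-1]
    assert row["crit"] >= 80
    assert row["band"] == "violation"


def test_monotonicity_constant_item_not_assessable(rng):
    m = _mhm_matrix(rng, n=500)
    m[:, 0] = 1.0
    rep = check_monotonicity(m)
    assert not rep.table.loc["item_0", "assessable"]
    assert rep.table.loc["item_0", "band"] == "not_assessable"


def test_monotonicity_report_internal_consistency(rng):
    rep = check_monotonicity(_mhm_matrix(rng, n=2000))
    t = rep.table[rep.table["assessable"]]
    assert (t["n_vi"] <= t["n_ac"]).all()
    with_vi = t[t["n_vi"] >= 1]
    assert (with_vi["maxvi"] <= with_vi["sumvi"] + 1e-12).all()


# -- non-intersection check -------------------------------------------------


def test_nonintersection_clean_on_perfect_guttman():
    rep = check_nonintersection_pmatrix(perfect_guttman(n_per_step=5, p=3))
    assert rep.n_violations == 0


def test_nonintersection_clean_on_parallel_irfs(rng):
    rep = check_nonintersection_pmatrix(_mhm_matrix(rng, n=8000))
    assert rep.n_violations == 0


def test_nonintersection_detects_crossing_irfs(rng):
    n = 20000
    theta = rng.standard_normal(n)
    cols = [
        expit(2.0 * (theta + 1.0)),     # easy anchor
        expit(6.0 * (theta - 0.3)),     # steep item ...
        expit(0.6 * theta),             # ... crossing this flat item
        expit(3.0 * (theta - 0.8)),     # hard anchor resolving the upper range
    ]
    m = np.column_stack([(rng.random(n) < p).astype(float) for p in cols])
    rep = check_nonintersection_pmatrix(m)
    assert rep.n_violations >= 1
    assert rep.table["n_vi"].max() >= 1


def test_crit_bands():
    assert crit_band(10) == "satisfactory"
    assert crit_band(60) == "questionable"
    assert crit_band(120) == "violation"


# -- model object -----------------------------------------------------------


def test_mokken_model_listwise_deletion_and_summary(rng):
    m = _mhm_matrix(rng, n=800).astype(float)
    m[rng.random(m.shape) < 0.05] = np.nan
    res = MokkenScale(m).fit()
    n_complete = int((~np.isnan(m).any(axis=1)).sum())
    assert res.n == n_complete
    text = res.summary()
    assert "whole_scale" in text
    assert f"n = {n_complete}" in text
    # summary frame carries the aggregation identity
    df = res.summary_frame().set_index("item_id")
    whole = df.loc["whole_scale"]
    assert whole["F"] == pytest.approx(df.drop("whole_scale")["F"].sum() / 2)
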