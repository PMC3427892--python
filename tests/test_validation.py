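"""ROC curves, AUROC with confidence intervals, cutpoints and strata."""

import numpy as np
import pandas as pd
import pytest

from briefcsid import (Cutpoint, ScreeningValidation, auroc, optimal_cutpoint,
                       roc_curve, stratified_validation, validate_scores,
                       youden)


def test_roc_hand_enumerated_example():
    scores = np.array([1, 3, 0, 2])
    labels = np.array([1, 1, 0, 0])
    roc = roc_curve(scores, labels, "higher_is_positive")
    assert len(roc) == 5
    pts = set(zip(roc["sensitivity"], roc["fpr"]))
    assert (0.5, 0.0) in pts and (1.0, 0.5) in pts
    assert {(0.0, 0.0), (1.0, 1.0)} <= pts


def test_roc_perfect_separation_passes_through_corner():
    roc = roc_curve([0, 1, 8, 9], [1, 1, 0, 0], "lower_is_positive")
    assert ((roc["sensitivity"] == 1.0) & (roc["fpr"] == 0.0)).any()


def test_roc_direction_flip_equals_negation(rng):
    scores = rng.integers(0, 10, 80).astype(float)
    labels = (rng.random(80) < 0.4).astype(float)
    a = roc_curve(scores, labels, "lower_is_positive")
    b = roc_curve(-scores, labels, "higher_is_positive")
    np.testing.assert_allclose(a["sensitivity"], b["sensitivity"])
    np.testing.assert_allclose(a["specificity"], b["specificity"])


def test_roc_rejects_single_class():
    with pytest.raises(ValueError, match="one case and one control"):
        roc_curve([1, 2], [1, 1], "higher_is_positive")


def test_auroc_hand_example():
    est = auroc([1, 3, 0, 2], [1, 1, 0, 0], "higher_is_positive")
    assert est.auc == pytest.approx(0.75)


def test_auroc_perfect_separation():
    est = auroc([0, 1, 8, 9], [1, 1, 0, 0], "lower_is_positive")
    assert est.auc == 1.0
    assert est.ci_high <= 1.0


def test_auroc_trapezoid_equals_rank_statistic(rng):
    for _ in range(50):
        scores = rng.standard_normal(60)          # continuous: tie-free
        labels = (rng.random(60) < 0.5).astype(float)
        if labels.sum() in (0, 60):
            continue
        roc = roc_curve(scores, labels, "higher_is_positive")
        trap = np.trapezoid(roc["sensitivity"], roc["fpr"])
        est = auroc(scores, labels, "higher_is_positive")
        assert abs(trap - est.auc) < 1e-12


def test_auroc_invariant_under_monotone_transform(rng):
    scores = rng.integers(0, 12, 100).astype(float)
    labels = (rng.random(100) < 0.3).astype(float)
    base = auroc(scores, labels, "higher_is_positive").auc
    for f in (lambda s: 3 * s + 2, lambda s: np.exp(s / 4), lambda s: s ** 3):
        assert auroc(f(scores), labels, "higher_is_positive").auc == pytest.approx(base)


def test_auroc_matches_sklearn_oracle(rng):
    from sklearn.metrics import roc_auc_score
    for _ in range(25):
        scores = rng.integers(0, 8, 120).astype(float)   # heavy ties
        labels = (rng.random(120) < 0.4).astype(float)
        if labels.sum() in (0, 120):
            continue
        est = auroc(scores, labels, "higher_is_positive")
        assert est.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_delong_ci_contains_estimate_and_narrows(rng):
    scores = np.concatenate([rng.normal(1, 1, 150), rng.normal(0, 1, 150)])
    labels = np.concatenate([np.ones(150), np.zeros(150)])
    d = auroc(scores, labels, "higher_is_positive", ci_method="delong")
    h = auroc(scores, labels, "higher_is_positive", ci_method="hanley-mcneil")
    for est in (d, h):
        assert est.ci_low <= est.auc <= est.ci_high
        assert 0.0 <= est.ci_low and est.ci_high <= 1.0
    assert d.auc == h.auc


@pytest.mark.parametrize("sens,spec,expected", [
    (0.879, 0.997, 0.876),
    (1.0, 1.0, 1.0),
    (0.5, 0.5, 0.0),
])
def test_youden_index(sens, spec, expected):
    assert youden(sens, spec) == pytest.approx(expected)


def test_youden_rejects_out_of_range():
    with pytest.raises(ValueError):
        youden(1.2, 0.5)


def test_optimal_cutpoint_unique_maximum():
    scores = [0, 1, 2, 3, 7, 8, 9, 9]
    labels = [1, 1, 1, 1, 0, 0, 0, 0]
    roc = roc_curve(scores, labels, "lower_is_positive")
    cuts = optimal_cutpoint(roc, "lower_is_positive")
    assert len(cuts) == 1
    assert cuts[0].youden == 1.0
    assert cuts[0].favors == "balanced"


def test_optimal_cutpoint_dual_reporting():
    # two adjacent thresholds with nearly equal J are both reported,
    # specificity-favouring first
    scores = [0, 1, 2, 5, 6, 5, 6, 7, 8, 9, 9, 9]
    labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
    roc = roc_curve(scores, labels, "lower_is_positive")
    cuts = optimal_cutpoint(roc, "lower_is_positive", delta_j=0.25)
    assert len(cuts) == 2
    assert cuts[0].favors == "specificity" and cuts[1].favors == "sensitivity"
    assert cuts[0].specificity >= cuts[1].specificity
    assert cuts[0].sensitivity <= cuts[1].sensitivity
    single = optimal_cutpoint(roc, "lower_is_positive", delta_j=0.25,
                              preference="favor_sensitivity")
    assert single[0].favors == "sensitivity"


def test_optimal_cutpoint_degenerate_curve_errors():
    roc = roc_curve([5, 5, 5, 5], [1, 1, 0, 0], "lower_is_positive")
    with pytest.raises(ValueError, match="degenerate"):
        optimal_cutpoint(roc, "lower_is_positive")


def test_stratified_validation_and_empty_stratum():
    scores = np.array([2, 3, 4, 8, 9, 7, 8])
    labels = np.array([1, 1, 1, 0, 0, 0, 0])
    severity = np.array(["mild", "mild", "moderate", None, None, None, None],
                        dtype=object)
    education = np.array([None, None, None, "high", "high", "high", "high"],
                         dtype=object)
    out = stratified_validation(scores, labels, Cutpoint(5.5, "lower_is_positive"),
                                severity=severity, education=education)
    assert out["sensitivity"] == 1.0
    assert out["by_severity"]["mild"] == 1.0
    assert np.isnan(out["by_education"]["low"])
    assert "education:low" in out["not_estimable"]


def test_validation_model_end_to_end(rng):
    n = 200
    labels = (rng.random(n) < 0.3).astype(float)
    scores = np.where(labels == 1, rng.integers(0, 6, n), rng.integers(4, 10, n))
    severity = np.where(labels == 1,
                        np.where(rng.random(n) < 0.5, "mild", "moderate"),
                        None).astype(object)
    res = ScreeningValidation(scores, labels, "lower_is_positive",
                              severity=severity, scale="cognitive",
                              region="test").fit()
    assert 0.5 < res.auroc.auc <= 1.0
    # J at the reported optimum is the maximum over all thresholds
    interior = res.roc[np.isfinite(res.roc["threshold"])]
    assert res.cutpoints[0].youden == pytest.approx(interior["youden"].max())
    frame = res.to_frame()
    assert {"auroc", "cutpoint", "sensitivity", "specificity", "youden"} <= set(frame.columns)
    assert "AUROC" in res.summary()


def test_validate_scores_three_scales(rng):
    scored = pd.DataFrame({
        "cognitive_total": rng.integers(0, 10, 120).astype(float),
        "informant_total": rng.integers(0, 7, 120).astype(float),
        "diagnosis": (rng.random(120) < 0.4).astype(float),
    })
    scored["combined"] = scored["cognitive_total"] - scored["informant_total"]
    out = validate_scores(scored, region="x")
    assert set(out) == {"cognitive", "informant", "combined"}
    assert out["informant"].model.direction == "higher_is_positive"
    assert out["combined"].model.direction == "lower_is_positive"


def test_plot_roc_smoke(rng):
    import matplotlib
    matplotlib.use("Agg")
    res = ScreeningValidation([1, 2, 8, 9], [1, 1, 0, 0],
                              "lower_is_positive").fit()
    ax = res.plot_roc()
    assert ax.get_xlabel() == "1 - specificity"
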