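"""Meta-regression of ln(OR), threshold inversion, subgroup comparisons."""

import math

import numpy as np
import pytest

from frimeta import (
    EQ2_COEFFS,
    TABLE3_CAPTION_COEFFS,
    TABLE3_TARGETS,
    MetaRegression,
    Study2x2,
    SyntheticConfig,
    fit_metareg,
    predict_lnor,
    required_fri,
    required_fri_table,
    simulate_fri_cohort,
    subgroup_analysis,
)
from frimeta.exceptions import (
    InsufficientDataError,
    InversionError,
    NumericalError,
    ValidationError,
)
from frimeta.metareg import round2, threshold_splitter
from frimeta.simulate import FriLink


# ---------------------------------------------------------------------------
# MetaRegression estimator


def test_intercept_only_equal_variances_is_arithmetic_mean():
    y = np.array([1.0, 2.0, 4.0, 5.0, 3.0])
    v = np.full(5, 0.3)
    m = MetaRegression().fit(None, y, v)
    assert m.intercept_ == pytest.approx(y.mean(), abs=1e-9)
    # balanced case: REML tau2 has the closed form max(0, s^2 - v)
    assert m.tau2_ == pytest.approx(max(0.0, y.var(ddof=1) - 0.3), abs=1e-6)


def test_two_point_saturated_fit_is_exact_line():
    studies = []
    for i, (x, tp) in enumerate([(1.0, 30), (3.0, 70)]):
        studies.append(
            Study2x2(study_id=f"s{i}", disease="d", tp=tp, fp=10, fn=100 - tp,
                     tn=90, covariates={"fri": x})
        )
    fit = fit_metareg(studies, ["fri"])
    from frimeta.io import summarize_study

    y = [summarize_study(s).ln_or for s in studies]
    slope = (y[1] - y[0]) / 2.0
    assert fit.coef["fri"].beta == pytest.approx(slope, abs=1e-9)
    assert fit.intercept.beta == pytest.approx(y[0] - slope, abs=1e-9)
    assert fit.tau2 == 0.0


def test_fixed_zero_tau2_equals_wls(rng):
    """With tau2 pinned at 0 the fit is exactly weighted least squares."""
    import statsmodels.api as sm

    n = 25
    x = rng.uniform(0, 5, n)
    v = rng.uniform(0.1, 0.5, n)
    y = 1.0 + 0.5 * x + rng.normal(0, np.sqrt(v))
    m = MetaRegression(fix_tau2=0.0).fit(x[:, None], y, v)
    ref = sm.WLS(y, sm.add_constant(x), weights=1.0 / v).fit()
    assert m.intercept_ == pytest.approx(ref.params[0], abs=1e-8)
    assert m.coef_[0] == pytest.approx(ref.params[1], abs=1e-8)
    # same point estimates as GLS; frimeta's vcov uses known variances
    assert m.se_[1] == pytest.approx(
        np.sqrt(np.linalg.inv(sm.add_constant(x).T @ np.diag(1 / v) @ sm.add_constant(x))[1, 1]),
        abs=1e-10,
    )


def test_reml_tau2_shift_invariance(rng):
    n = 30
    x = rng.uniform(0, 5, n)
    v = rng.uniform(0.1, 0.4, n)
    y = 0.3 * x + rng.normal(0, 0.6, n)
    a = MetaRegression().fit(x[:, None], y, v)
    b = MetaRegression().fit(x[:, None], y + 17.0, v)
    assert b.tau2_ == pytest.approx(a.tau2_, abs=1e-6)
    assert b.coef_[0] == pytest.approx(a.coef_[0], abs=1e-8)
    assert b.intercept_ == pytest.approx(a.intercept_ + 17.0, abs=1e-6)


def test_dl_estimator_matches_standard_q_formula(rng):
    # intercept-only DL: tau2 = (Q - (n-1)) / (S1 - S2/S1)
    n = 20
    v = rng.uniform(0.1, 0.5, n)
    y = rng.normal(1.0, 0.8, n)
    w = 1.0 / v
    yw = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - yw) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    expected = max(0.0, (q - (n - 1)) / c)
    m = MetaRegression(method="dl").fit(None, y, v)
    assert m.tau2_ == pytest.approx(expected, rel=1e-10)


def test_collinear_design_rejected():
    y = np.arange(5.0)
    v = np.full(5, 0.2)
    X = np.column_stack([np.ones(5), np.ones(5)])
    with pytest.raises(NumericalError, match="rank"):
        MetaRegression().fit(X, y, v)


def test_missing_covariate_lists_study_ids():
    studies = [
        Study2x2(study_id="with", disease="d", tp=10, fp=2, fn=3, tn=15,
                 covariates={"fri": 4.0}),
        Study2x2(study_id="without", disease="d", tp=12, fp=3, fn=2, tn=16),
        Study2x2(study_id="also", disease="d", tp=9, fp=1, fn=4, tn=11,
                 covariates={"fri": 6.0}),
    ]
    with pytest.raises(ValidationError, match="without"):
        fit_metareg(studies, ["fri"])


def test_too_few_studies():
    y, v = np.array([1.0]), np.array([0.1])
    with pytest.raises(InsufficientDataError):
        MetaRegression().fit(np.array([[1.0]]), y, v)


def test_slope_recovery_single_cohort():
    link = FriLink(slope=0.4960, intercept=1.459, tau=0.3)
    studies, _ = simulate_fri_cohort(
        SyntheticConfig(n_studies=200, fri_link=link, seed=99)
    )
    fit = fit_metareg(studies, ["fri"])
    c = fit.coef["fri"]
    assert abs(c.beta - 0.4960) < 3 * c.se
    assert c.p < 0.05


# ---------------------------------------------------------------------------
# prediction and inversion


def test_predict_lnor_examples():
    fake = fit_metareg_like(slope=0.4960, intercept=1.459)
    assert predict_lnor(fake, 0.0) == pytest.approx(1.459)
    assert predict_lnor(fake, 4.05) == pytest.approx(0.4960 * 4.05 + 1.459)
    # ln(OR) at the 85/85 threshold is ~3.47
    assert predict_lnor(fake, 4.05) == pytest.approx(3.468, abs=5e-3)
    # affine identity
    a, b = 2.2, 3.3
    assert predict_lnor(fake, a) + predict_lnor(fake, b) - 1.459 == pytest.approx(
        predict_lnor(fake, a + b), abs=1e-12
    )


def fit_metareg_like(slope, intercept):
    from frimeta.metareg import CoefEstimate, MetaRegFit

    est = lambda b: CoefEstimate(beta=b, se=0.1, ci=(b - 0.2, b + 0.2), p=0.01)
    return MetaRegFit(coef={"fri": est(slope)}, intercept=est(intercept),
                      tau2=0.5, n_studies=16, method="reml")


def test_required_fri_round_trips_predict_lnor():
    fake = fit_metareg_like(slope=0.4960, intercept=1.459)
    for fri0 in (0.5, 3.36, 6.0, 9.0):
        ln_or = predict_lnor(fake, fri0)
        # symmetric split: se = sp with logit = ln_or / 2
        p = 1.0 / (1.0 + math.exp(-ln_or / 2.0))
        t = required_fri(p, p, 0.4960, 1.459)
        assert t.fri_required == pytest.approx(fri0, abs=1e-9)


@pytest.mark.parametrize("x,or_expected", [(0.85, 32.11), (0.90, 81.00), (0.95, 361.00)])
def test_symmetric_dor_identity(x, or_expected):
    t = required_fri(x, x)
    assert t.or_implied == pytest.approx((x / (1 - x)) ** 2, rel=1e-12)
    assert round2(t.or_implied) == or_expected


def test_required_fri_published_anchor_points():
    assert round2(required_fri(0.85, 0.85, *EQ2_COEFFS).fri_required) == 4.05
    assert round2(required_fri(0.90, 0.90, *EQ2_COEFFS).fri_required) == 5.92
    assert round2(required_fri(0.95, 0.95, *EQ2_COEFFS).fri_required) == 8.93


def test_required_fri_domain_errors():
    with pytest.raises(ValidationError):
        required_fri(1.0, 0.9)
    with pytest.raises(ValidationError):
        required_fri(0.9, 0.0)
    with pytest.raises(InversionError):
        required_fri(0.9, 0.9, slope=0.0, intercept=1.0)


def test_required_fri_table_shape_and_empty():
    table = required_fri_table()
    assert [t.se_target for t in table] == [p[0] for p in TABLE3_TARGETS]
    assert required_fri_table([]) == []
    # caption coefficient set is exposed and distinct
    assert TABLE3_CAPTION_COEFFS != EQ2_COEFFS


# ---------------------------------------------------------------------------
# subgroups


def _balanced_studies(n_per_group=4):
    studies = []
    for g, label in enumerate(["a", "b"]):
        for i in range(n_per_group):
            studies.append(
                Study2x2(
                    study_id=f"{label}{i}", disease="d",
                    tp=85 + i, fp=10, fn=15 - i, tn=90,
                    covariates={"training_n": 100 if label == "a" else 5000},
                )
            )
    return studies


def test_identical_groups_have_null_interaction():
    studies = _balanced_studies()
    result = subgroup_analysis(
        studies, "training_n", threshold_splitter("training_n", 1000),
        restarts=1, quad_points=7, seed=0,
    )
    assert len(result.groups) == 2
    g1, g2 = result.groups
    assert g1.se == pytest.approx(g2.se, abs=1e-4)
    assert result.p_interaction > 0.95


def test_singleton_group_reported_degenerate():
    studies = _balanced_studies()[:5]  # 4 in group a, 1 in group b
    result = subgroup_analysis(
        studies, "training_n", threshold_splitter("training_n", 1000),
        restarts=1, quad_points=7, seed=0,
    )
    by_label = {g.label: g for g in result.groups}
    assert by_label[">=1000"].degenerate
    assert by_label[">=1000"].n_studies == 1
    assert math.isnan(result.p_interaction)


def test_fixture_training_size_split_counts(fixture_studies):
    result = subgroup_analysis(
        fixture_studies, "training_n", threshold_splitter("training_n", 1000),
        restarts=1, quad_points=7, seed=0,
    )
    counts = {g.label: g.n_studies for g in result.groups}
    assert counts == {"<1000": 14, ">=1000": 6}
    assert sum(counts.values()) == len(fixture_studies)


def test_fri_split_direction_forced_by_generator():
    """Cohorts generated with a positive FRI->DOR slope must show lower
    pooled sensitivity in the low-FRI group nearly always."""
    link = FriLink(slope=0.4960, intercept=1.459, tau=0.3)
    wins = 0
    reps = 10
    for r in range(reps):
        studies, _ = simulate_fri_cohort(
            SyntheticConfig(n_studies=30, fri_link=link, seed=5000 + r)
        )
        result = subgroup_analysis(
            studies, "fri", threshold_splitter("fri", 6.0),
            restarts=1, quad_points=7, seed=r,
        )
        by_label = {g.label: g for g in result.groups}
        wins += by_label["<6"].se < by_label[">=6"].se
    assert wins >= reps - 1


def test_single_group_split_rejected(fixture_studies):
    with pytest.raises(ValidationError):
        subgroup_analysis(
            fixture_studies, "training_n", threshold_splitter("training_n", 1),
        )
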