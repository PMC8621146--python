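"""Bivariate binomial-normal pooling: likelihood, fit, summaries, SROC."""

import numpy as np
import pytest
from scipy import special
from scipy.special import gammaln

from frimeta import (
    BivariateDiagnosticModel,
    Study2x2,
    SyntheticConfig,
    fit_bivariate,
    marginal_loglik,
    pooled_summary,
    refit_excluding,
    simulate_studies,
    sroc,
)
from frimeta.bivariate import BivariateFit
from frimeta.exceptions import (
    DegenerateCurveError,
    InsufficientDataError,
    NumericalError,
    ValidationError,
)

from bivariate_oracles import TOY, brute_force_loglik  # noqa: E402


@pytest.mark.parametrize(
    "mu,sigma",
    [
        ((0.0, 0.0), np.eye(2)),
        ((1.2, 2.0), np.array([[0.6, 0.2], [0.2, 0.9]])),
    ],
)
def test_quadrature_matches_brute_force(mu, sigma):
    gh = marginal_loglik(TOY, mu, sigma, quad_points=15)
    bf = brute_force_loglik(TOY, np.asarray(mu), np.asarray(sigma))
    assert gh == pytest.approx(bf, abs=1e-6)


def test_quadrature_stable_in_node_count():
    sigma = np.array([[0.5, 0.1], [0.1, 0.5]])
    values = [marginal_loglik(TOY, (1.0, 1.5), sigma, q) for q in (15, 21, 31)]
    assert max(values) - min(values) < 1e-7


def test_zero_sigma_is_plain_binomial():
    mu = (0.3, -0.2)
    ll = marginal_loglik(TOY, mu, np.zeros((2, 2)))
    direct = 0.0
    for tp, fp, fn, tn in TOY:
        y, n = np.array([tp, tn]), np.array([tp + fn, fp + tn])
        logc = (gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)).sum()
        direct += logc + (y * np.array(mu) - n * np.logaddexp(0, np.array(mu))).sum()
    assert ll == pytest.approx(direct, abs=1e-10)


def test_non_psd_sigma_rejected():
    with pytest.raises(ValidationError):
        marginal_loglik(TOY, (0, 0), np.array([[1.0, 2.0], [2.0, 1.0]]))


def test_single_balanced_study_with_fixed_zero_sigma():
    model = BivariateDiagnosticModel(fix_sigma=np.zeros((2, 2)))
    model.fit([[50, 50, 50, 50]])
    assert model.mu_ == pytest.approx([0.0, 0.0], abs=1e-12)
    assert model.converged_


def test_too_few_studies_for_free_sigma():
    with pytest.raises(InsufficientDataError):
        fit_bivariate([[50, 50, 50, 50]])


def test_relabeling_studies_leaves_fit_identical():
    studies, _ = simulate_studies(SyntheticConfig(n_studies=12, seed=7))
    fit_a = fit_bivariate(studies, restarts=1, quad_points=7, seed=0)
    fit_b = fit_bivariate(studies[::-1], restarts=1, quad_points=7, seed=0)
    assert fit_a.loglik == pytest.approx(fit_b.loglik, abs=1e-8)
    assert fit_a.mu == pytest.approx(fit_b.mu, abs=1e-6)


def test_arm_swap_swaps_mu_components():
    studies, _ = simulate_studies(SyntheticConfig(n_studies=12, seed=3))
    swapped = [
        Study2x2(study_id=s.study_id, disease=s.disease, tp=s.tn, fp=s.fn, fn=s.fp, tn=s.tp)
        for s in studies
    ]
    fit_a = fit_bivariate(studies, restarts=2, quad_points=9, seed=0)
    fit_b = fit_bivariate(swapped, restarts=2, quad_points=9, seed=0)
    assert fit_b.mu[0] == pytest.approx(fit_a.mu[1], abs=5e-3)
    assert fit_b.mu[1] == pytest.approx(fit_a.mu[0], abs=5e-3)
    assert fit_b.sigma[0, 0] == pytest.approx(fit_a.sigma[1, 1], abs=5e-2)
    assert fit_b.loglik == pytest.approx(fit_a.loglik, abs=1e-5)


def test_mu_recovered_within_monte_carlo_error():
    truth_mu = np.array([special.logit(0.89), special.logit(0.92)])
    studies, _ = simulate_studies(
        SyntheticConfig(
            n_studies=40, sigma=((0.5, 0.0), (0.0, 0.5)),
            arm_size_range=(100, 100), seed=11,
        )
    )
    fit = fit_bivariate(studies, restarts=2, quad_points=9, seed=1)
    se_mu = np.sqrt(np.diag(fit.vcov_mu))
    assert np.all(np.abs(fit.mu - truth_mu) < 3 * se_mu)
    assert fit.converged


def make_fit(mu, sigma=None, vcov=None):
    return BivariateFit(
        mu=np.asarray(mu, float),
        sigma=np.eye(2) * 0.4 if sigma is None else np.asarray(sigma, float),
        vcov_mu=np.eye(2) * 0.01 if vcov is None else np.asarray(vcov, float),
        loglik=0.0,
        n_studies=10,
        converged=True,
        quad_points=15,
    )


def test_pooled_summary_closed_form_dor():
    fit = make_fit([special.logit(0.89), special.logit(0.92)])
    s = pooled_summary(fit)
    assert s.dor == pytest.approx((0.89 * 0.92) / (0.11 * 0.08), rel=1e-9)
    assert s.dor == pytest.approx(93.045, abs=0.01)


def test_pooled_summary_null_case():
    s = pooled_summary(make_fit([0.0, 0.0]))
    assert s.se == s.sp == 0.5
    assert s.plr == pytest.approx(1.0) and s.nlr == pytest.approx(1.0)
    assert s.dor == pytest.approx(1.0)


def test_pooled_summary_zero_vcov_degenerates_cis():
    s = pooled_summary(make_fit([1.0, 2.0], vcov=np.zeros((2, 2))))
    assert s.se_ci == (pytest.approx(s.se), pytest.approx(s.se))
    assert s.dor_ci == (pytest.approx(s.dor), pytest.approx(s.dor))


def test_dor_equals_plr_over_nlr_identity():
    for seed in range(5):
        studies, _ = simulate_studies(SyntheticConfig(n_studies=10, seed=seed))
        s = pooled_summary(fit_bivariate(studies, restarts=1, quad_points=7, seed=0))
        assert s.dor == pytest.approx(s.plr / s.nlr, rel=1e-12)


def test_nonfinite_level_rejected():
    with pytest.raises(ValidationError):
        pooled_summary(make_fit([0, 0]), level=1.0)


def test_sroc_zero_covariance_gives_horizontal_curve():
    fit = make_fit([1.5, 1.0], sigma=np.diag([0.4, 0.3]))
    res = sroc(fit)
    assert np.allclose(res.curve[:, 1], special.expit(1.5), atol=1e-12)


def test_sroc_summary_point_on_curve():
    fit = make_fit([1.2, 1.8], sigma=np.array([[0.5, 0.2], [0.2, 0.4]]))
    res = sroc(fit)
    fpr0, se0 = res.summary_point
    idx = np.argmin(np.abs(res.curve[:, 0] - fpr0))
    assert res.curve[idx, 0] == pytest.approx(fpr0, abs=1e-9)
    assert res.curve[idx, 1] == pytest.approx(se0, abs=1e-9)


def test_sroc_regions_collapse_as_level_vanishes():
    fit = make_fit([1.2, 1.8], sigma=np.array([[0.5, 0.2], [0.2, 0.4]]))
    res = sroc(fit, level=1e-12)
    for region in (res.conf_region, res.pred_region):
        assert np.allclose(region.polygon, res.summary_point, atol=1e-4)


def test_sroc_prediction_region_contains_confidence_region():
    fit = make_fit(
        [1.2, 1.8], sigma=np.array([[0.5, 0.2], [0.2, 0.4]]),
        vcov=np.array([[0.02, 0.005], [0.005, 0.03]]),
    )
    res = sroc(fit)
    pred_cov = fit.vcov_mu + fit.sigma
    r2 = 5.991464547107979  # chi2(2) 95% quantile
    poly = res.conf_region.polygon
    logit_pts = np.column_stack(
        [special.logit(poly[:, 1]), special.logit(1.0 - poly[:, 0])]
    )
    d = logit_pts - fit.mu
    maha = np.einsum("ni,ij,nj->n", d, np.linalg.inv(pred_cov), d)
    assert np.all(maha <= r2 + 1e-9)


def test_sroc_curve_geometry_in_logit_space():
    """The traced curve is the logit-space line through (mu1, mu2) with
    slope sigma12/sigma22 (checked numerically from the sampled points)."""
    sigma = np.array([[0.5, 0.2], [0.2, 0.4]])
    fit = make_fit([1.2, 1.8], sigma=sigma)
    res = sroc(fit, n_points=101)
    w = special.logit(res.curve[:, 1])  # logit se
    u = special.logit(1.0 - res.curve[:, 0])  # logit sp
    slope = sigma[0, 1] / sigma[1, 1]
    assert np.allclose(w, 1.2 + slope * (u - 1.8), atol=1e-9)


def test_sroc_symmetric_fit_summary_point_on_diagonal():
    fit = make_fit([1.4, 1.4], sigma=np.array([[0.5, 0.2], [0.2, 0.5]]))
    res = sroc(fit)
    fpr0, se0 = res.summary_point
    assert se0 == pytest.approx(1.0 - fpr0, abs=1e-12)  # se equals sp


def test_sroc_degenerate_sigma_rejected():
    fit = make_fit([1.0, 1.0], sigma=np.diag([0.4, 0.0]))
    with pytest.raises(DegenerateCurveError):
        sroc(fit)


def test_refit_excluding_noop_and_flagged(fixture_studies):
    full = fit_bivariate(fixture_studies, restarts=1, quad_points=7, seed=0)
    res = refit_excluding(fixture_studies, set(), restarts=1, quad_points=7, seed=0)
    assert res.dropped_study_ids == ()
    assert res.fit.loglik == pytest.approx(full.loglik, abs=1e-9)

    res = refit_excluding(
        fixture_studies, {"unclear_model"}, restarts=1, quad_points=7, seed=0
    )
    assert len(res.dropped_study_ids) == 5
    assert res.fit.n_studies == 15


def test_refit_excluding_everything_errors(fixture_studies):
    all_flags = {"unclear_model", "unclear_reference", "external_validation",
                 "unclear_sampling"}
    keep = [s for s in fixture_studies if s.excl_flags & all_flags]
    # drop every flagged study from a set where <2 clean ones remain
    with pytest.raises(InsufficientDataError):
        refit_excluding(keep[:3], all_flags, restarts=1)


def test_fit_rejects_non_psd_outputs():
    with pytest.raises(NumericalError):
        BivariateFit(
            mu=np.zeros(2), sigma=np.array([[1.0, 2.0], [2.0, 1.0]]),
            vcov_mu=np.eye(2), loglik=0.0, n_studies=3, converged=True,
            quad_points=15,
        )
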