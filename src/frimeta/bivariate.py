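"""Bivariate binomial-normal random-effects pooling of sensitivity/specificity.

The model: study k observes ``tp_k ~ Binomial(tp_k + fn_k, se_k)`` and
``tn_k ~ Binomial(fp_k + tn_k, sp_k)`` where the latent pair
``(logit se_k, logit sp_k)`` is bivariate normal with mean ``mu`` and
between-study covariance ``sigma``.  The marginal likelihood integrates the
binomial kernels over the normal random effects; this module evaluates that
integral by adaptive Gauss–Hermite product quadrature (nodes recentred and
rescaled at each study's posterior mode) and maximises it over
``(mu, sigma)`` with an unconstrained parameterisation
``(mu1, mu2, log sd1, log sd2, atanh rho)``.

Working on the exact binomial likelihood rather than a normal approximation
of the observed logits keeps studies with perfect sensitivity or specificity
in the model without continuity corrections.

From a fitted model the usual meta-analytic summaries follow: pooled Se/Sp
(inverse-logit of ``mu`` with Wald logit-scale intervals), likelihood ratios
and the diagnostic odds ratio (delta method on the log scale), and the
summary ROC curve with Wald confidence and prediction ellipses mapped
pointwise from logit space to the ROC plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateCurveError,
    InsufficientDataError,
    NumericalError,
    ValidationError,
)
from .io import Study2x2

__all__ = [
    "BivariateDiagnosticModel",
    "BivariateFit",
    "PooledSummary",
    "SROCResult",
    "EllipseSpec",
    "marginal_loglik",
    "fit_bivariate",
    "pooled_summary",
    "sroc",
    "refit_excluding",
    "ExclusionRefit",
]


# ---------------------------------------------------------------------------
# likelihood


def _as_counts(X: Any) -> np.ndarray:
    """Coerce studies to an (n, 4) integer array with columns tp, fp, fn, tn."""
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], Study2x2):
        arr = np.array([[s.tp, s.fp, s.fn, s.tn] for s in X], dtype=float)
    elif hasattr(X, "columns"):  # DataFrame
        arr = np.asarray(X[["tp", "fp", "fn", "tn"]], dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValidationError(
            f"expected studies as an (n, 4) table of tp, fp, fn, tn counts, "
            f"got shape {arr.shape}"
        )
    if (arr < 0).any() or not np.all(arr == np.round(arr)):
        raise ValidationError("counts must be non-negative integers")
    n_dis = arr[:, 0] + arr[:, 2]
    n_con = arr[:, 1] + arr[:, 3]
    if (n_dis < 1).any() or (n_con < 1).any():
        raise ValidationError("every study needs a non-empty diseased and control arm")
    return arr


def _binom_parts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Successes y=(tp, tn), trials n=(n_dis, n_con), log binomial coefs."""
    tp, fp, fn, tn = counts.T
    y = np.column_stack([tp, tn])
    n = np.column_stack([tp + fn, fp + tn])
    logc = (
        special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    ).sum(axis=1)
    return y, n, logc


def _binom_loglik_at(theta: np.ndarray, y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Sum over both arms of y*theta - n*log(1+e^theta); theta (..., 2)."""
    return (y * theta - n * np.logaddexp(0.0, theta)).sum(axis=-1)


def _posterior_modes(
    y: np.ndarray,
    n: np.ndarray,
    mu: np.ndarray,
    sigma_inv: np.ndarray,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised 2-D Newton for each study's integrand mode.

    Returns modes (K, 2) and the negative Hessians (K, 2, 2), which are
    always positive definite (binomial information >= 0 plus sigma_inv > 0).
    """
    K = y.shape[0]
    theta = np.tile(mu, (K, 1)).astype(float) if start is None else start.copy()
    for _ in range(100):
        p = special.expit(theta)
        grad = (y - n * p) - (theta - mu) @ sigma_inv
        w = n * p * (1.0 - p)
        # neg Hessian H = diag(w) + sigma_inv, per study
        a = w[:, 0] + sigma_inv[0, 0]
        b = np.full(K, sigma_inv[0, 1])
        d = w[:, 1] + sigma_inv[1, 1]
        det = a * d - b * b
        step0 = (d * grad[:, 0] - b * grad[:, 1]) / det
        step1 = (-b * grad[:, 0] + a * grad[:, 1]) / det
        step = np.column_stack([step0, step1])
        norm2 = step0**2 + step1**2
        scale = np.where(norm2 > 16.0, 4.0 / np.sqrt(np.maximum(norm2, 1e-300)), 1.0)
        theta = theta + step * scale[:, None]  # damped jumps far from the mode
        if np.abs(grad).max() < 1e-9 and norm2.max() < 1e-18:
            break
    p = special.expit(theta)
    w = n * p * (1.0 - p)
    neg_hess = np.empty((K, 2, 2))
    neg_hess[:, 0, 0] = w[:, 0] + sigma_inv[0, 0]
    neg_hess[:, 1, 1] = w[:, 1] + sigma_inv[1, 1]
    neg_hess[:, 0, 1] = neg_hess[:, 1, 0] = sigma_inv[0, 1]
    return theta, neg_hess


from functools import lru_cache


@lru_cache(maxsize=8)
def _gh_grid(quad_points: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Product Gauss–Hermite grid: nodes z (q^2, 2), log-weights, |z|^2."""
    x, w = hermgauss(quad_points)
    z1, z2 = np.meshgrid(x, x, indexing="ij")
    z = np.column_stack([z1.ravel(), z2.ravel()])
    logw = (np.log(w)[:, None] + np.log(w)[None, :]).ravel()
    return z, logw, (z**2).sum(axis=1)


def marginal_loglik(
    counts: Any, mu: Sequence[float], sigma: Any, quad_points: int = 15
) -> float:
    """Exact-binomial marginal log-likelihood at fixed ``(mu, sigma)``.

    ``sigma`` may be the zero matrix, in which case the random effects are
    degenerate at ``mu`` and the likelihood is the plain binomial one.
    """
    counts = _as_counts(counts)
    y, n, logc = _binom_parts(counts)
    return _marginal_loglik(y, n, logc, np.asarray(mu, float),
                            np.asarray(sigma, float), quad_points)


def _marginal_loglik(
    y: np.ndarray,
    n: np.ndarray,
    logc: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    quad_points: int,
    mode_start: np.ndarray | None = None,
) -> float:
    if np.allclose(sigma, 0.0):
        return float((logc + _binom_loglik_at(np.tile(mu, (len(y), 1)), y, n)).sum())
    eig_min = float(np.linalg.eigvalsh(sigma).min())
    if eig_min < -1e-8:
        raise ValidationError(
            "sigma must be positive semi-definite; smallest eigenvalue "
            f"{eig_min}"
        )
    if eig_min < 1e-10:
        # effectively degenerate direction: tiny ridge keeps the integral
        # well-defined and the likelihood smooth near the boundary
        sigma = sigma + (1e-10 - min(eig_min, 0.0)) * np.eye(2)
    sigma_inv = np.linalg.inv(sigma)
    _, logdet = np.linalg.slogdet(sigma)
    log_mvn_const = -np.log(2.0 * np.pi) - 0.5 * logdet

    modes, neg_hess = _posterior_modes(y, n, mu, sigma_inv, start=mode_start)
    # Cholesky of A = neg_hess^{-1}, done in closed form per study
    a = neg_hess[:, 0, 0]
    b = neg_hess[:, 0, 1]
    d = neg_hess[:, 1, 1]
    det = a * d - b * b
    # A = [[d, -b], [-b, a]] / det ; chol(A) lower-triangular
    l11 = np.sqrt(d / det)
    l21 = -b / det / l11
    l22 = np.sqrt(a / det - l21**2)
    log_det_l = np.log(l11) + np.log(l22)

    z, logw, z_sq = _gh_grid(quad_points)  # (q^2, 2), (q^2,), (q^2,)
    # theta_kj = mode_k + sqrt(2) * L_k @ z_j
    t1 = modes[:, None, 0] + np.sqrt(2.0) * l11[:, None] * z[None, :, 0]
    t2 = modes[:, None, 1] + np.sqrt(2.0) * (
        l21[:, None] * z[None, :, 0] + l22[:, None] * z[None, :, 1]
    )
    theta = np.stack([t1, t2], axis=-1)  # (K, q^2, 2)
    diff = theta - mu
    quad_form = np.einsum("kji,il,kjl->kj", diff, sigma_inv, diff)
    f = _binom_loglik_at(theta, y[:, None, :], n[:, None, :]) + log_mvn_const - 0.5 * quad_form
    # adaptive GH: integral = 2 |L| sum_j w_j exp(f_j + |z_j|^2)
    per_study = (
        np.log(2.0)
        + log_det_l
        + special.logsumexp(f + (z_sq + logw)[None, :], axis=1)
    )
    return float((logc + per_study).sum())


# ---------------------------------------------------------------------------
# parameterisation and fitting

_LOG_SD_MIN, _LOG_SD_MAX = -12.0, 4.0


def _unpack(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = params[:2]
    log_sd = np.clip(params[2:4], _LOG_SD_MIN, _LOG_SD_MAX)
    sd = np.exp(log_sd)
    rho = np.tanh(params[4])
    sigma = np.array(
        [
            [sd[0] ** 2, rho * sd[0] * sd[1]],
            [rho * sd[0] * sd[1], sd[1] ** 2],
        ]
    )
    return mu, sigma


def _start_values(counts: np.ndarray) -> np.ndarray:
    y, n, _ = _binom_parts(counts)
    logits = special.logit((y + 0.5) / (n + 1.0))
    mu0 = logits.mean(axis=0)
    sd0 = np.maximum(logits.std(axis=0, ddof=1) if len(y) > 1 else np.array([0.5, 0.5]), 0.1)
    if len(y) > 2:
        r = np.corrcoef(logits.T)[0, 1]
        r = 0.0 if not np.isfinite(r) else np.clip(r, -0.9, 0.9)
    else:
        r = 0.0
    return np.array([mu0[0], mu0[1], np.log(sd0[0]), np.log(sd0[1]), np.arctanh(r)])


@dataclass(frozen=True)
class BivariateFit:
    """Maximum-likelihood fit of the bivariate binomial-normal model."""

    mu: np.ndarray  # (2,): mean logit-sensitivity, mean logit-specificity
    sigma: np.ndarray  # (2,2) between-study covariance of the logits
    vcov_mu: np.ndarray  # (2,2) covariance of the estimated means
    loglik: float
    n_studies: int
    converged: bool
    quad_points: int
    fpr_range: tuple[float, float] = (0.05, 0.95)  # observed 1-sp range

    def __post_init__(self) -> None:
        for name, m in (("sigma", self.sigma), ("vcov_mu", self.vcov_mu)):
            if np.linalg.eigvalsh(np.asarray(m)).min() < -1e-10:
                raise NumericalError(f"{name} is not positive semi-definite")


class BivariateDiagnosticModel(BaseEstimator):
    """Bivariate random-effects pooling of Se/Sp, sklearn-style.

    Parameters
    ----------
    quad_points : nodes per dimension of the adaptive Gauss–Hermite rule.
    max_iter : optimizer iteration cap (per restart).
    tol : function tolerance for the optimizer.
    restarts : number of optimizations from perturbed starts; the best
        (highest likelihood) is kept.
    seed : seeds the restart perturbations.
    fix_sigma : optional fixed between-study covariance (2x2, PSD); the zero
        matrix collapses the model to common-effect binomial pooling.

    Attributes (after ``fit``)
    --------------------------
    mu_, sigma_, vcov_mu_, loglik_, n_studies_, converged_, fpr_range_.
    """

    def __init__(
        self,
        quad_points: int = 15,
        max_iter: int = 2000,
        tol: float = 1e-8,
        restarts: int = 5,
        seed: int | None = None,
        fix_sigma: Any = None,
    ):
        self.quad_points = quad_points
        self.max_iter = max_iter
        self.tol = tol
        self.restarts = restarts
        self.seed = seed
        self.fix_sigma = fix_sigma

    # -- fitting -----------------------------------------------------------
    def fit(self, X: Any, y: Any = None) -> "BivariateDiagnosticModel":
        counts = _as_counts(X)
        K = len(counts)
        fix_sigma = None if self.fix_sigma is None else np.asarray(self.fix_sigma, float)
        if fix_sigma is None and K < 2:
            raise InsufficientDataError(
                f"need >= 2 studies for a free between-study covariance, got {K}"
            )
        if K < 1:
            raise InsufficientDataError("no studies")

        yy, nn, logc = _binom_parts(counts)

        if fix_sigma is not None and np.allclose(fix_sigma, 0.0):
            # degenerate random effects: closed-form binomial MLE on each arm
            tot_y, tot_n = yy.sum(axis=0), nn.sum(axis=0)
            mu = special.logit(tot_y / tot_n)
            if not np.all(np.isfinite(mu)):
                raise NumericalError("pooled proportion on the boundary; mu infinite")
            p = special.expit(mu)
            info = tot_n * p * (1 - p)
            self._finalize(counts, mu, np.zeros((2, 2)), np.diag(1.0 / info),
                           marginal_loglik(counts, mu, np.zeros((2, 2))), True)
            return self

        emp_logits = special.logit((yy + 0.5) / (nn + 1.0))

        if fix_sigma is not None:

            def objective(p2: np.ndarray) -> float:
                return -_marginal_loglik(
                    yy, nn, logc, p2, fix_sigma, self.quad_points, mode_start=emp_logits
                )

            start = _start_values(counts)[:2]
            best = None
            rng = np.random.default_rng(self.seed)
            for i in range(max(1, self.restarts)):
                s = start if i == 0 else start + rng.normal(0, 0.3, size=2)
                res = self._minimize(objective, s)
                if best is None or res.fun < best.fun:
                    best = res
            mu = best.x
            vcov = self._wald_vcov(lambda p: -objective(p), mu)
            self._finalize(counts, mu, fix_sigma, vcov, -best.fun, bool(best.success))
            return self

        def objective(params: np.ndarray) -> float:
            mu, sigma = _unpack(params)
            try:
                return -_marginal_loglik(
                    yy, nn, logc, mu, sigma, self.quad_points, mode_start=emp_logits
                )
            except (ValidationError, FloatingPointError, np.linalg.LinAlgError):
                return np.inf

        start = _start_values(counts)
        rng = np.random.default_rng(self.seed)
        best = None
        for i in range(max(1, self.restarts)):
            s = start if i == 0 else start + rng.normal(0, 0.4, size=5)
            res = self._minimize(objective, s)
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise NumericalError(
                "non-finite marginal likelihood at every start; check the data "
                f"(K={K}, start={start.tolist()})"
            )
        mu, sigma = _unpack(best.x)

        def full_ll(p: np.ndarray) -> float:
            m, s = _unpack(p)
            return _marginal_loglik(
                yy, nn, logc, m, s, self.quad_points, mode_start=emp_logits
            )

        hess = _numerical_hessian(full_ll, best.x, 1e-4)
        vcov = _safe_inverse(-hess)[:2, :2]
        self._finalize(counts, mu, sigma, vcov, -best.fun, bool(best.success))
        return self

    def _minimize(self, objective, start: np.ndarray):
        """Quasi-Newton first (fast, FD gradients), simplex polish after
        (guards against finite-difference stalls on flat directions)."""
        res = optimize.minimize(
            objective, start, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol},
        )
        polish = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": self.tol,
                     "maxiter": self.max_iter, "maxfev": 400},
        )
        out = polish if polish.fun < res.fun else res
        out.success = bool(res.success or polish.success)
        return out

    def _wald_vcov(self, loglik, mu: np.ndarray, h: float = 1e-4) -> np.ndarray:
        hess = _numerical_hessian(loglik, mu, h)
        return _safe_inverse(-hess)

    def _finalize(self, counts, mu, sigma, vcov, loglik, converged) -> None:
        fpr = counts[:, 1] / (counts[:, 1] + counts[:, 3])
        self.mu_ = np.asarray(mu, float)
        self.sigma_ = np.asarray(sigma, float)
        self.vcov_mu_ = np.asarray(vcov, float)
        self.loglik_ = float(loglik)
        self.n_studies_ = len(counts)
        self.converged_ = bool(converged)
        self.fpr_range_ = (float(fpr.min()), float(fpr.max()))

    # -- views -------------------------------------------------------------
    def result_(self) -> BivariateFit:
        return BivariateFit(
            mu=self.mu_,
            sigma=self.sigma_,
            vcov_mu=self.vcov_mu_,
            loglik=self.loglik_,
            n_studies=self.n_studies_,
            converged=self.converged_,
            quad_points=self.quad_points,
            fpr_range=self.fpr_range_,
        )


def _numerical_hessian(f, x: np.ndarray, h: float) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    k = len(x)
    hess = np.empty((k, k))
    f0 = f(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        hess[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return hess


def _safe_inverse(m: np.ndarray) -> np.ndarray:
    """PSD-projected inverse: clips tiny/negative curvature directions."""
    m = 0.5 * (m + m.T)
    vals, vecs = np.linalg.eigh(m)
    vals = np.maximum(vals, 1e-10)
    inv = vecs @ np.diag(1.0 / vals) @ vecs.T
    return 0.5 * (inv + inv.T)


# ---------------------------------------------------------------------------
# functional wrappers and summaries


def fit_bivariate(studies: Iterable[Study2x2] | Any, **opts: Any) -> BivariateFit:
    """Fit the bivariate model; thin wrapper over the estimator class."""
    model = BivariateDiagnosticModel(**opts)
    model.fit(list(studies) if not hasattr(studies, "shape") else studies)
    return model.result_()


@dataclass(frozen=True)
class PooledSummary:
    """Pooled accuracy with CIs: Se/Sp, likelihood ratios, diagnostic OR."""

    se: float
    sp: float
    se_ci: tuple[float, float]
    sp_ci: tuple[float, float]
    plr: float
    nlr: float
    dor: float
    plr_ci: tuple[float, float]
    nlr_ci: tuple[float, float]
    dor_ci: tuple[float, float]
    level: float

    def as_dict(self) -> dict[str, Any]:
        return {
            "se": self.se, "se_ci": list(self.se_ci),
            "sp": self.sp, "sp_ci": list(self.sp_ci),
            "plr": self.plr, "plr_ci": list(self.plr_ci),
            "nlr": self.nlr, "nlr_ci": list(self.nlr_ci),
            "dor": self.dor, "dor_ci": list(self.dor_ci),
            "level": self.level,
        }


def pooled_summary(fit: BivariateFit, level: float = 0.95) -> PooledSummary:
    """Pooled Se/Sp (Wald on the logit scale) and PLR/NLR/DOR (delta method
    on the log scale), all at confidence ``level``."""
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    v = np.asarray(fit.vcov_mu, float)
    if np.linalg.eigvalsh(v).min() < -1e-10:
        raise NumericalError("vcov_mu is not positive semi-definite")
    z = stats.norm.ppf(0.5 + level / 2.0)
    mu1, mu2 = fit.mu
    se, sp = special.expit(mu1), special.expit(mu2)

    def logit_ci(m: float, var: float) -> tuple[float, float]:
        h = z * np.sqrt(max(var, 0.0))
        return (float(special.expit(m - h)), float(special.expit(m + h)))

    def log_scale_ci(log_val: float, grad: np.ndarray) -> tuple[float, float]:
        var = float(grad @ v @ grad)
        h = z * np.sqrt(max(var, 0.0))
        return (float(np.exp(log_val - h)), float(np.exp(log_val + h)))

    log_plr = float(np.log(se) - np.log(1 - sp))
    log_nlr = float(np.log(1 - se) - np.log(sp))
    log_dor = float(mu1 + mu2)  # logit se + logit sp
    return PooledSummary(
        se=float(se),
        sp=float(sp),
        se_ci=logit_ci(mu1, v[0, 0]),
        sp_ci=logit_ci(mu2, v[1, 1]),
        plr=float(np.exp(log_plr)),
        nlr=float(np.exp(log_nlr)),
        dor=float(np.exp(log_dor)),
        plr_ci=log_scale_ci(log_plr, np.array([1 - se, sp])),
        nlr_ci=log_scale_ci(log_nlr, np.array([-se, -(1 - sp)])),
        dor_ci=log_scale_ci(log_dor, np.array([1.0, 1.0])),
        level=level,
    )


@dataclass(frozen=True)
class EllipseSpec:
    """A bivariate-normal ellipse in logit (Se, Sp) space plus its image in
    ROC space, sampled as a closed polygon."""

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation: float
    polygon: np.ndarray  # (n, 2) columns (1-sp, se) in ROC space


@dataclass(frozen=True)
class SROCResult:
    curve: np.ndarray  # (n, 2) columns (1-sp, se)
    summary_point: tuple[float, float]
    conf_region: EllipseSpec
    pred_region: EllipseSpec
    level: float


def _ellipse(center: np.ndarray, cov: np.ndarray, level: float, n_points: int) -> EllipseSpec:
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    vals = np.maximum(vals, 0.0)
    r = np.sqrt(stats.chi2.ppf(level, df=2))
    t = np.linspace(0.0, 2.0 * np.pi, n_points)
    circle = np.column_stack([np.cos(t), np.sin(t)])
    pts_logit = center + r * (circle * np.sqrt(vals)) @ vecs.T
    polygon = np.column_stack(
        [1.0 - special.expit(pts_logit[:, 1]), special.expit(pts_logit[:, 0])]
    )
    return EllipseSpec(
        center=(float(center[0]), float(center[1])),
        axes=(float(r * np.sqrt(vals[1])), float(r * np.sqrt(vals[0]))),
        rotation=float(np.arctan2(vecs[1, 1], vecs[0, 1])),
        polygon=polygon,
    )


def sroc(fit: BivariateFit, level: float = 0.95, n_points: int = 200) -> SROCResult:
    """Summary ROC curve plus Wald confidence/prediction regions.

    The curve is the regression of logit(Se) on logit(Sp) implied by the
    between-study covariance, traced over the observed false-positive-rate
    range (always extended to include the summary point) and mapped to ROC
    space.  The confidence region uses ``vcov_mu``; the prediction region —
    where a new study's true (Se, Sp) is expected — uses ``vcov_mu + sigma``.
    """
    sigma = np.asarray(fit.sigma, float)
    if sigma[1, 1] <= 1e-12:
        raise DegenerateCurveError(
            "between-study variance of logit-specificity is ~0: the SROC "
            "curve is degenerate; use the pooled summary point instead"
        )
    slope = sigma[0, 1] / sigma[1, 1]
    mu1, mu2 = fit.mu
    lo, hi = fit.fpr_range
    lo = float(np.clip(min(lo, 1.0 - special.expit(mu2)), 1e-6, 1 - 1e-6))
    hi = float(np.clip(max(hi, 1.0 - special.expit(mu2)), 1e-6, 1 - 1e-6))
    logit_sp_grid = np.sort(
        np.unique(np.concatenate([
            np.linspace(special.logit(1.0 - hi), special.logit(1.0 - lo), n_points),
            [mu2],
        ]))
    )
    logit_se = mu1 + slope * (logit_sp_grid - mu2)
    curve = np.column_stack(
        [1.0 - special.expit(logit_sp_grid), special.expit(logit_se)]
    )
    curve = curve[np.argsort(curve[:, 0])]
    summary_point = (float(1.0 - special.expit(mu2)), float(special.expit(mu1)))
    center = np.asarray(fit.mu, float)
    conf = _ellipse(center, np.asarray(fit.vcov_mu), level, n_points)
    pred = _ellipse(center, np.asarray(fit.vcov_mu) + sigma, level, n_points)
    return SROCResult(
        curve=curve,
        summary_point=summary_point,
        conf_region=conf,
        pred_region=pred,
        level=level,
    )


@dataclass(frozen=True)
class ExclusionRefit:
    """A sensitivity refit: the model on the subset without given flags."""

    fit: BivariateFit
    summary: PooledSummary
    dropped_study_ids: tuple[str, ...]
    kept_study_ids: tuple[str, ...]
    flags: frozenset[str]


def refit_excluding(
    studies: Sequence[Study2x2],
    flags: Iterable[str],
    level: float = 0.95,
    **opts: Any,
) -> ExclusionRefit:
    """Refit after dropping every study carrying any of the given flags."""
    flags = frozenset(flags)
    kept = [s for s in studies if not (s.excl_flags & flags)]
    dropped = [s.study_id for s in studies if s.excl_flags & flags]
    if len(kept) < 2:
        raise InsufficientDataError(
            f"exclusion by {sorted(flags)} leaves {len(kept)} study/studies; "
            "need >= 2"
        )
    fit = fit_bivariate(kept, **opts)
    return ExclusionRefit(
        fit=fit,
        summary=pooled_summary(fit, level=level),
        dropped_study_ids=tuple(dropped),
        kept_study_ids=tuple(s.study_id for s in kept),
        flags=flags,
    )
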