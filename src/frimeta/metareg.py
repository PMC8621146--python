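"""Random-effects meta-regression of ln(OR) and its inversion into
required-FRI thresholds.

Model: for study k with observed log diagnostic odds ratio ``y_k`` and known
sampling variance ``v_k``,

    y_k = beta0 + x_k' beta + u_k + e_k,   u_k ~ N(0, tau2),  e_k ~ N(0, v_k)

with the between-study variance ``tau2`` estimated by REML (default) or the
DerSimonian–Laird moment estimator, and Wald z inference on the
coefficients.  With FRI as the single covariate the fitted line
``ln(OR) = slope * FRI + intercept`` can be inverted: given a target
(sensitivity, specificity) pair, the implied odds ratio is
``(Se * Sp) / ((1 - Se)(1 - Sp))`` and the FRI a disease must reach is
``(ln OR - intercept) / slope``.

Two published coefficient sets for that line ship as named constants:
``EQ2_COEFFS`` (slope 0.4960, intercept 1.459) and the table-caption variant
``TABLE3_CAPTION_COEFFS`` (0.4951, 1.46).  Neither is exactly consistent
with every printed 2-decimal threshold cell; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .bivariate import fit_bivariate, pooled_summary
from .exceptions import (
    InsufficientDataError,
    InversionError,
    NumericalError,
    ValidationError,
)
from .io import Study2x2, StudyAccuracy, summarize_study

#: Fitted accuracy/FRI relation, main (single-covariate) model.
EQ2_COEFFS: tuple[float, float] = (0.4960, 1.459)
#: Variant printed alongside the published threshold table.
TABLE3_CAPTION_COEFFS: tuple[float, float] = (0.4951, 1.46)
#: The five (Se, Sp) targets of the published threshold table.
TABLE3_TARGETS: tuple[tuple[float, float], ...] = (
    (0.85, 0.85),
    (0.90, 0.85),
    (0.90, 0.90),
    (0.95, 0.90),
    (0.95, 0.95),
)


def round2(x: float) -> float:
    """Presentation rounding: half-up to 2 decimals (tables only)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# estimator


class MetaRegression:
    """Random-effects meta-regression with known sampling variances.

    sklearn-style: construct with hyperparameters, ``fit(X, y, v)`` with
    ``X`` an (n, p) covariate matrix (p may be 0 for an intercept-only
    pooled mean), ``y`` the effect sizes and ``v`` their known variances.

    Attributes after ``fit``: ``intercept_``, ``coef_`` (p,), ``tau2_``,
    ``vcov_`` ((p+1, p+1), intercept first), ``se_``, ``zvalues_``,
    ``pvalues_``, ``n_studies_``.
    """

    def __init__(
        self,
        method: str = "reml",
        tol: float = 1e-10,
        max_iter: int = 200,
        fix_tau2: float | None = None,
    ):
        if method not in ("reml", "dl"):
            raise ValidationError(f"method must be 'reml' or 'dl', got {method!r}")
        self.method = method
        self.tol = tol
        self.max_iter = max_iter
        self.fix_tau2 = fix_tau2

    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {
            "method": self.method,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "fix_tau2": self.fix_tau2,
        }

    def set_params(self, **params: Any) -> "MetaRegression":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: Any, y: Any, v: Any) -> "MetaRegression":
        y = np.asarray(y, float).ravel()
        v = np.asarray(v, float).ravel()
        n = len(y)
        X = np.empty((n, 0)) if X is None else np.asarray(X, float).reshape(n, -1)
        if (v <= 0).any():
            raise ValidationError("sampling variances must be > 0")
        design = np.column_stack([np.ones(n), X])
        p = design.shape[1]
        if n < p:
            raise InsufficientDataError(
                f"{n} studies cannot identify {p} coefficients"
            )
        if np.linalg.matrix_rank(design) < p:
            raise NumericalError("design matrix is rank deficient (collinear covariates)")

        if self.fix_tau2 is not None:
            if self.fix_tau2 < 0:
                raise ValidationError("fix_tau2 must be >= 0")
            tau2 = float(self.fix_tau2)
        elif n == p:
            tau2 = 0.0  # saturated fit: no residual information for tau2
        elif self.method == "dl":
            tau2 = _tau2_dl(design, y, v)
        else:
            tau2 = _tau2_reml(design, y, v, self.tol, self.max_iter)

        w = 1.0 / (v + tau2)
        xtwx = design.T @ (design * w[:, None])
        vcov = np.linalg.inv(xtwx)
        beta = vcov @ (design.T @ (w * y))
        self.n_studies_ = n
        self.tau2_ = float(tau2)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.vcov_ = vcov
        self.se_ = np.sqrt(np.diag(vcov))
        self.zvalues_ = beta / self.se_
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(self.zvalues_))
        self._beta_full = beta
        return self

    def predict(self, X: Any) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X.reshape(-1, len(self.coef_)) if len(self.coef_) else X.reshape(-1, 0)
        return self.intercept_ + (X @ self.coef_ if X.shape[1] else np.zeros(len(X)))

    def ci(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack(
            [self._beta_full - z * self.se_, self._beta_full + z * self.se_]
        )

    def wald_block_test(self, indices: Sequence[int]) -> tuple[float, int, float]:
        """Wald chi-square that a block of coefficients (by full-design index,
        0 = intercept) is jointly zero; returns (stat, df, p)."""
        idx = np.asarray(indices, int)
        b = self._beta_full[idx]
        vb = self.vcov_[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(vb, b))
        df = len(idx)
        return stat, df, float(stats.chi2.sf(stat, df))


def _gls(design: np.ndarray, y: np.ndarray, w: np.ndarray):
    xtwx = design.T @ (design * w[:, None])
    beta = np.linalg.solve(xtwx, design.T @ (w * y))
    resid = y - design @ beta
    return beta, resid, xtwx


def _tau2_dl(design: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    n, p = design.shape
    w0 = 1.0 / v
    _, resid, xtwx0 = _gls(design, y, w0)
    q = float(np.sum(w0 * resid**2))
    # trace of the residual projection P = W - W X (X'WX)^{-1} X'W
    inner = np.linalg.solve(xtwx0, design.T @ (design * (w0**2)[:, None]))
    trace_p = float(np.sum(w0) - np.trace(inner))
    if trace_p <= 0:
        return 0.0
    return max(0.0, (q - (n - p)) / trace_p)


def _tau2_reml(
    design: np.ndarray, y: np.ndarray, v: np.ndarray, tol: float, max_iter: int
) -> float:
    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        _, resid, xtwx = _gls(design, y, w)
        sign, logdet = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        return 0.5 * (
            float(np.sum(np.log(v + tau2))) + logdet + float(np.sum(w * resid**2))
        )

    upper = max(10.0 * float(np.var(y)) + float(v.max()), 1.0)
    res = optimize.minimize_scalar(
        neg_restricted_ll,
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter * 10},
    )
    tau2 = float(res.x)
    # the bounded minimiser never lands exactly on 0; snap when 0 is as good
    if neg_restricted_ll(0.0) <= res.fun + tol:
        tau2 = 0.0
    return tau2


# ---------------------------------------------------------------------------
# spec-surface wrappers


@dataclass(frozen=True)
class CoefEstimate:
    beta: float
    se: float
    ci: tuple[float, float]
    p: float


@dataclass(frozen=True)
class MetaRegFit:
    """Coefficients, tau2 and Wald inference of a ln(OR) meta-regression."""

    coef: dict[str, CoefEstimate]
    intercept: CoefEstimate
    tau2: float
    n_studies: int
    method: str

    def slope_of(self, name: str) -> float:
        return self.coef[name].beta


def _study_accuracy(item: Any) -> tuple[Study2x2, StudyAccuracy]:
    if isinstance(item, tuple):
        return item
    return item, summarize_study(item)


def fit_metareg(
    studies: Sequence[Any],
    covariates: Sequence[str],
    method: str = "reml",
    level: float = 0.95,
    **opts: Any,
) -> MetaRegFit:
    """Meta-regression of per-study ln(OR) on named covariates.

    ``studies`` may be ``Study2x2`` records (summaries computed on the fly)
    or ``(Study2x2, StudyAccuracy)`` pairs.  Covariate values come from
    ``Study2x2.covariates``; studies missing a requested covariate raise an
    error listing the offending study ids.
    """
    pairs = [_study_accuracy(s) for s in studies]
    missing = [
        s.study_id
        for s, _ in pairs
        if any(c not in s.covariates or s.covariates[c] is None for c in covariates)
    ]
    if missing:
        raise ValidationError(
            f"studies missing covariate value(s) for {list(covariates)}: {missing}"
        )
    y = np.array([a.ln_or for _, a in pairs])
    v = np.array([a.var_ln_or for _, a in pairs])
    X = np.array([[float(s.covariates[c]) for c in covariates] for s, _ in pairs]).reshape(
        len(pairs), len(covariates)
    )
    model = MetaRegression(method=method, **opts)
    try:
        model.fit(X, y, v)
    except NumericalError:
        raise NumericalError(
            f"rank-deficient design for covariates {list(covariates)}"
        ) from None
    ci = model.ci(level)

    def estimate(i: int) -> CoefEstimate:
        return CoefEstimate(
            beta=float(model._beta_full[i]),
            se=float(model.se_[i]),
            ci=(float(ci[i, 0]), float(ci[i, 1])),
            p=float(model.pvalues_[i]),
        )

    return MetaRegFit(
        coef={name: estimate(i + 1) for i, name in enumerate(covariates)},
        intercept=estimate(0),
        tau2=model.tau2_,
        n_studies=model.n_studies_,
        method=method,
    )


def predict_lnor(fit: MetaRegFit, fri: float) -> float:
    """Predicted ln(OR) at a given FRI from a fitted single-line relation."""
    if "fri" not in fit.coef:
        raise ValidationError("fit has no 'fri' coefficient")
    return fit.intercept.beta + fit.coef["fri"].beta * fri


@dataclass(frozen=True)
class FriThreshold:
    """The FRI a disease must reach for a target (Se, Sp), by inverting the
    fitted ln(OR) = slope * FRI + intercept relation."""

    se_target: float
    sp_target: float
    or_implied: float
    ln_or: float
    fri_required: float

    def rounded(self) -> dict[str, float]:
        return {
            "se_target": self.se_target,
            "sp_target": self.sp_target,
            "or": round2(self.or_implied),
            "ln_or": round2(self.ln_or),
            "fri": round2(self.fri_required),
        }


def required_fri(
    se: float,
    sp: float,
    slope: float = EQ2_COEFFS[0],
    intercept: float = EQ2_COEFFS[1],
) -> FriThreshold:
    """Invert the accuracy/FRI line at one (Se, Sp) target.

    Full precision is kept; rounding happens only in ``FriThreshold.rounded``.
    """
    if not (0.0 < se < 1.0 and 0.0 < sp < 1.0):
        raise ValidationError(
            f"se and sp must be strictly inside (0, 1), got ({se}, {sp})"
        )
    if slope == 0:
        raise InversionError("slope is zero; the relation cannot be inverted")
    or_implied = (se * sp) / ((1.0 - se) * (1.0 - sp))
    ln_or = math.log(or_implied)
    return FriThreshold(
        se_target=se,
        sp_target=sp,
        or_implied=or_implied,
        ln_or=ln_or,
        fri_required=(ln_or - intercept) / slope,
    )


def required_fri_table(
    targets: Iterable[tuple[float, float]] = TABLE3_TARGETS,
    slope: float = EQ2_COEFFS[0],
    intercept: float = EQ2_COEFFS[1],
    fit: MetaRegFit | None = None,
) -> list[FriThreshold]:
    """Threshold table over (Se, Sp) targets; a fitted relation overrides the
    explicit coefficients when given."""
    if fit is not None:
        slope = fit.coef["fri"].beta
        intercept = fit.intercept.beta
    return [required_fri(se, sp, slope, intercept) for se, sp in targets]


# ---------------------------------------------------------------------------
# subgroup analysis


@dataclass(frozen=True)
class SubgroupEstimate:
    label: str
    n_studies: int
    se: float
    se_ci: tuple[float, float]
    sp: float
    sp_ci: tuple[float, float]
    degenerate: bool  # < 2 studies: raw pooled proportions, no model


@dataclass(frozen=True)
class SubgroupResult:
    variable: str
    groups: tuple[SubgroupEstimate, ...]
    p_interaction: float


def threshold_splitter(
    variable: str, cut: float, on_missing: str = "error"
) -> Callable[[Study2x2], str | None]:
    """Split on a numeric covariate at ``cut``: '<cut' vs '>=cut'.

    ``on_missing``: 'error' raises for a study without the covariate;
    'skip' returns None so the study is left out of the analysis.
    """

    def split(study: Study2x2) -> str | None:
        value = study.covariates.get(variable)
        if value is None:
            if on_missing == "skip":
                return None
            raise ValidationError(
                f"study {study.study_id!r} has no value for {variable!r}"
            )
        return f"<{cut:g}" if float(value) < cut else f">={cut:g}"

    return split


def categorical_splitter(
    variable: str,
    on_missing: str = "error",
    keep: Sequence[str] | None = None,
) -> Callable[[Study2x2], str | None]:
    """Split on a categorical covariate; ``keep`` optionally restricts the
    admitted labels (others are skipped)."""

    def split(study: Study2x2) -> str | None:
        value = study.covariates.get(variable)
        if value is None:
            if on_missing == "skip":
                return None
            raise ValidationError(
                f"study {study.study_id!r} has no value for {variable!r}"
            )
        label = str(value)
        if keep is not None and label not in keep:
            return None
        return label

    return split


def subgroup_analysis(
    studies: Sequence[Study2x2],
    variable: str,
    splitter: Callable[[Study2x2], str | None],
    level: float = 0.95,
    **fit_opts: Any,
) -> SubgroupResult:
    """Per-group bivariate pooling plus an interaction test.

    Studies for which the splitter returns None are left out.  Groups with
    >= 2 studies get a bivariate fit; singleton groups are reported with raw
    pooled proportions, flagged degenerate, and excluded from the
    interaction test.  The interaction p-value is a Wald test on the
    group-indicator coefficient(s) in a ln(OR) meta-regression (z-test for
    a binary split, chi-square block test otherwise).
    """
    grouped: dict[str, list[Study2x2]] = {}
    for s in studies:
        label = splitter(s)
        if label is None:
            continue
        grouped.setdefault(label, []).append(s)
    if len(grouped) < 2:
        raise ValidationError(
            f"splitter on {variable!r} produced a single group; nothing to compare"
        )

    estimates: list[SubgroupEstimate] = []
    testable: list[str] = []
    for label in sorted(grouped):
        members = grouped[label]
        if len(members) >= 2:
            fit = fit_bivariate(members, **fit_opts)
            summ = pooled_summary(fit, level=level)
            estimates.append(
                SubgroupEstimate(
                    label=label,
                    n_studies=len(members),
                    se=summ.se,
                    se_ci=summ.se_ci,
                    sp=summ.sp,
                    sp_ci=summ.sp_ci,
                    degenerate=False,
                )
            )
            testable.append(label)
        else:
            (s,) = members
            acc = summarize_study(s)
            estimates.append(
                SubgroupEstimate(
                    label=label,
                    n_studies=1,
                    se=acc.se_hat,
                    se_ci=acc.se_ci,
                    sp=acc.sp_hat,
                    sp_ci=acc.sp_ci,
                    degenerate=True,
                )
            )

    if len(testable) < 2:
        p_interaction = float("nan")
    else:
        test_studies = [s for lbl in testable for s in grouped[lbl]]
        labels = [lbl for lbl in testable for _ in grouped[lbl]]
        baseline = testable[0]
        others = testable[1:]
        pairs = [_study_accuracy(s) for s in test_studies]
        y = np.array([a.ln_or for _, a in pairs])
        v = np.array([a.var_ln_or for _, a in pairs])
        X = np.column_stack(
            [[1.0 if lbl == g else 0.0 for lbl in labels] for g in others]
        )
        model = MetaRegression(method="reml").fit(X, y, v)
        _, _, p_interaction = model.wald_block_test(range(1, 1 + len(others)))
        _ = baseline
    return SubgroupResult(
        variable=variable,
        groups=tuple(estimates),
        p_interaction=float(p_interaction),
    )
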