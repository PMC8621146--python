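"""Seeded synthetic study generator.

Generates study sets with exactly the statistical structure the pooling
model assumes: per study, a latent pair (logit Se, logit Sp) is drawn from a
bivariate normal around the set-level means, arm sizes are drawn uniformly
from a realistic testing-set range (default 17–242 subjects per arm, the
range reported across the facial-recognition diagnostic literature this
package targets), and the 2x2 counts are binomial.  Optionally, a linear
FRI -> ln(DOR) relation generates cohorts for meta-regression recovery:
each study draws an FRI value, its true log diagnostic odds ratio is
``slope * FRI + intercept`` plus N(0, tau^2) noise, and the pair (Se, Sp)
is recovered from the DOR by anchoring specificity (default 0.92) and
assigning the remainder to sensitivity, since a DOR alone does not fix the
split.

Every draw flows through one ``numpy`` generator seeded from the config, so
identical configs give byte-identical study lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import special

from .exceptions import ValidationError
from .io import Study2x2

#: Default set-level means: logit(0.89), logit(0.92) — the pooled operating
#: point this package's reference analyses centre on.
DEFAULT_MU: tuple[float, float] = (
    float(special.logit(0.89)),
    float(special.logit(0.92)),
)
DEFAULT_SIGMA: tuple[tuple[float, float], tuple[float, float]] = (
    (0.5, 0.0),
    (0.0, 0.5),
)
#: Testing-set sizes per arm observed in the target literature.
DEFAULT_ARM_RANGE: tuple[int, int] = (17, 242)
#: Reference FRI values of the seven packaged diseases.
DEFAULT_FRI_VALUES: tuple[float, ...] = (9.0, 8.0, 7.443, 6.0, 5.0, 4.0, 3.36)


@dataclass(frozen=True)
class FriLink:
    """A generative linear FRI -> ln(DOR) relation."""

    slope: float = 0.4960
    intercept: float = 1.459
    fri_values: tuple[float, ...] = DEFAULT_FRI_VALUES
    sp_anchor: float = 0.92
    tau: float = 0.0  # SD of study-level noise on ln(DOR)
    resample_out_of_range: bool = True
    max_resample: int = 100

    def __post_init__(self) -> None:
        if not self.fri_values:
            raise ValidationError("fri_link.fri_values must be non-empty")
        if not 0.0 < self.sp_anchor < 1.0:
            raise ValidationError(f"sp_anchor must be in (0, 1), got {self.sp_anchor}")
        if self.tau < 0:
            raise ValidationError(f"tau must be >= 0, got {self.tau}")


@dataclass(frozen=True)
class SyntheticConfig:
    n_studies: int = 20
    mu: tuple[float, float] = DEFAULT_MU
    sigma: Any = DEFAULT_SIGMA
    arm_size_range: tuple[int, int] = DEFAULT_ARM_RANGE
    fri_link: FriLink | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValidationError(f"n_studies must be >= 1, got {self.n_studies}")
        lo, hi = self.arm_size_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"invalid arm_size_range {self.arm_size_range}")
        sigma = np.asarray(self.sigma, float)
        if sigma.shape != (2, 2) or not np.allclose(sigma, sigma.T):
            raise ValidationError("sigma must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(sigma).min() < -1e-10:
            raise ValidationError("sigma must be positive semi-definite")


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent per-study logits and the config that generated them."""

    theta_se: np.ndarray
    theta_sp: np.ndarray
    config: SyntheticConfig
    fri: np.ndarray | None = None


def _sample_counts(
    rng: np.random.Generator, cfg: SyntheticConfig, theta: np.ndarray,
    fri: np.ndarray | None = None,
) -> tuple[list[Study2x2], SyntheticTruth]:
    lo, hi = cfg.arm_size_range
    n_dis = rng.integers(lo, hi + 1, size=cfg.n_studies)
    n_con = rng.integers(lo, hi + 1, size=cfg.n_studies)
    se = special.expit(theta[:, 0])
    sp = special.expit(theta[:, 1])
    tp = rng.binomial(n_dis, se)
    tn = rng.binomial(n_con, sp)
    studies = []
    for k in range(cfg.n_studies):
        covariates: dict[str, Any] = {}
        if fri is not None:
            covariates["fri"] = float(fri[k])
        studies.append(
            Study2x2(
                study_id=f"sim{k + 1:03d}",
                disease=f"synthetic-{k + 1:03d}",
                tp=int(tp[k]),
                fp=int(n_con[k] - tn[k]),
                fn=int(n_dis[k] - tp[k]),
                tn=int(tn[k]),
                covariates=covariates,
            )
        )
    truth = SyntheticTruth(
        theta_se=theta[:, 0].copy(), theta_sp=theta[:, 1].copy(), config=cfg,
        fri=None if fri is None else np.asarray(fri, float),
    )
    return studies, truth


def simulate_studies(cfg: SyntheticConfig) -> tuple[list[Study2x2], SyntheticTruth]:
    """Draw a study set from the bivariate binomial-normal model."""
    rng = np.random.default_rng(cfg.seed)
    sigma = np.asarray(cfg.sigma, float)
    theta = rng.multivariate_normal(
        np.asarray(cfg.mu, float), sigma, size=cfg.n_studies, method="svd"
    )
    return _sample_counts(rng, cfg, theta)


def simulate_fri_cohort(cfg: SyntheticConfig) -> tuple[list[Study2x2], SyntheticTruth]:
    """Draw a cohort whose true ln(DOR) follows the linear FRI relation.

    Per study: FRI ~ uniform over ``fri_link.fri_values``; true
    ``ln DOR = slope * FRI + intercept + N(0, tau^2)``; specificity is fixed
    at the anchor so ``logit Se = ln DOR - logit sp_anchor`` (the log-DOR is
    the sum of the two logits).  Draws whose implied Se falls outside (0, 1)
    on the logit scale cannot occur for finite values, but extreme noise can
    push Se numerically to 1; those draws are resampled (bounded attempts)
    when ``resample_out_of_range`` is set, else they raise.
    """
    link = cfg.fri_link
    if link is None:
        raise ValidationError("simulate_fri_cohort requires cfg.fri_link")
    rng = np.random.default_rng(cfg.seed)
    logit_sp = float(special.logit(link.sp_anchor))
    fri = np.empty(cfg.n_studies)
    theta = np.empty((cfg.n_studies, 2))
    for k in range(cfg.n_studies):
        for attempt in range(link.max_resample + 1):
            f = float(rng.choice(np.asarray(link.fri_values, float)))
            ln_dor = link.slope * f + link.intercept + (
                rng.normal(0.0, link.tau) if link.tau > 0 else 0.0
            )
            theta_se = ln_dor - logit_sp
            se = special.expit(theta_se)
            if 0.0 < se < 1.0:
                break
            if not link.resample_out_of_range:
                raise ValidationError(
                    f"implied sensitivity {se} outside (0, 1) for FRI={f}"
                )
        else:
            raise ValidationError(
                f"could not draw an in-range sensitivity in {link.max_resample} attempts"
            )
        fri[k] = f
        theta[k] = (theta_se, logit_sp)
    return _sample_counts(rng, cfg, theta, fri=fri)


def with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy a config with a different seed (replicate ladders)."""
    return replace(cfg, seed=seed)
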