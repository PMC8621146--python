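"""Full-analysis orchestration: pool -> SROC -> meta-regression ->
required-FRI thresholds -> subgroups -> stratified summaries -> sensitivity
refits, with provenance, structured logging and YAML config.

The report mirrors the shape of a complete diagnostic-accuracy synthesis:
every section records the study ids it used, provenance carries the seed,
package version and a hash of the effective config, and identical inputs
plus config give identical numeric sections (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bivariate import (
    BivariateFit,
    ExclusionRefit,
    PooledSummary,
    SROCResult,
    fit_bivariate,
    pooled_summary,
    refit_excluding,
    sroc,
)
from .exceptions import FrimetaError, ValidationError
from .fri import compute_fri, load_phenotype_table, load_reference_phenotypes
from .io import Study2x2, read_studies, summarize_study
from .metareg import (
    EQ2_COEFFS,
    TABLE3_TARGETS,
    FriThreshold,
    MetaRegFit,
    SubgroupResult,
    categorical_splitter,
    fit_metareg,
    required_fri_table,
    subgroup_analysis,
    threshold_splitter,
)


class AnalysisStageError(FrimetaError):
    """A pipeline stage failed; earlier artifacts are preserved on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Every knob of the full analysis; YAML-mirrorable."""

    level: float = 0.95
    seed: int = 0
    quad_points: int = 15
    restarts: int = 5
    cc: float = 0.5
    # thresholds
    threshold_targets: tuple[tuple[float, float], ...] = TABLE3_TARGETS
    threshold_coeffs: str | tuple[float, float] = "eq2"  # or "fitted" or (slope, intercept)
    # meta-regression
    metareg_covariates: tuple[str, ...] = ("fri",)
    metareg_method: str = "reml"
    single_disease_only: bool = True
    # subgroups: (variable, cut or None for categorical)
    subgroups: tuple[tuple[str, float | None], ...] = (
        ("resolution_px", 30000),
        ("training_n", 1000),
        ("model_class", None),
        ("n_diseases", 2),
        ("control_type", None),
        ("fri", 6),
    )
    # strata
    fri_bands: tuple[float, ...] = (6.0, 8.0)
    size_bands: tuple[float, ...] = (100.0, 1000.0)
    by_model: bool = True
    # sensitivity refits
    exclusion_sets: tuple[tuple[str, ...], ...] = (
        ("external_validation",),
        ("unclear_model",),
        ("unclear_reference",),
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.threshold_targets = tuple(tuple(t) for t in cfg.threshold_targets)
        if not isinstance(cfg.threshold_coeffs, str):
            cfg.threshold_coeffs = tuple(cfg.threshold_coeffs)
        cfg.metareg_covariates = tuple(cfg.metareg_covariates)
        cfg.subgroups = tuple((v, c) for v, c in cfg.subgroups)
        cfg.fri_bands = tuple(cfg.fri_bands)
        cfg.size_bands = tuple(cfg.size_bands)
        cfg.exclusion_sets = tuple(tuple(s) for s in cfg.exclusion_sets)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return json.loads(json.dumps(asdict(self)))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class AnalysisReport:
    pooled: PooledSummary
    sroc: SROCResult
    metareg: MetaRegFit | None
    thresholds: list[FriThreshold]
    subgroups: list[SubgroupResult]
    strata: pd.DataFrame
    sensitivity: list[ExclusionRefit]
    forest: pd.DataFrame
    fit: BivariateFit
    study_ids: dict[str, list[str]]
    provenance: dict[str, Any]

    def as_dict(self) -> dict[str, Any]:
        """JSON-native view (round-trips through json exactly)."""

        def ci(pair):  # tuples -> lists
            return [float(pair[0]), float(pair[1])]

        d: dict[str, Any] = {
            "pooled": self.pooled.as_dict(),
            "sroc": {
                "summary_point": list(self.sroc.summary_point),
                "level": self.sroc.level,
                "curve": self.sroc.curve.tolist(),
                "conf_polygon": self.sroc.conf_region.polygon.tolist(),
                "pred_polygon": self.sroc.pred_region.polygon.tolist(),
            },
            "metareg": None
            if self.metareg is None
            else {
                "intercept": asdict(self.metareg.intercept),
                "coef": {k: asdict(v) for k, v in self.metareg.coef.items()},
                "tau2": self.metareg.tau2,
                "n_studies": self.metareg.n_studies,
                "method": self.metareg.method,
            },
            "thresholds": [t.rounded() | {"fri_exact": t.fri_required} for t in self.thresholds],
            "subgroups": [
                {
                    "variable": r.variable,
                    "p_interaction": r.p_interaction,
                    "groups": [asdict(g) for g in r.groups],
                }
                for r in self.subgroups
            ],
            "strata": self.strata.to_dict(orient="records"),
            "sensitivity": [
                {
                    "flags": sorted(r.flags),
                    "dropped": list(r.dropped_study_ids),
                    "pooled": r.summary.as_dict(),
                }
                for r in self.sensitivity
            ],
            "forest": self.forest.to_dict(orient="records"),
            "study_ids": self.study_ids,
            "provenance": self.provenance,
        }
        return json.loads(json.dumps(d, default=_native))


def _native(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set, frozenset)):
        return list(obj)
    if obj != obj:  # NaN -> null
        return None
    raise TypeError(type(obj))


# ---------------------------------------------------------------------------
# stratified accuracy


def _band_label(value: float, cuts: Sequence[float]) -> str:
    """Bands are right-open except the last closed one: with cuts (a, b) the
    labels are '<a', 'a-b' (meaning [a, b]) and '>b'."""
    if value < cuts[0]:
        return f"<{cuts[0]:g}"
    if value > cuts[-1]:
        return f">{cuts[-1]:g}"
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if (value < hi) or hi == cuts[-1]:
            if value >= lo:
                return f"{lo:g}-{hi:g}"
    return f"{cuts[-2]:g}-{cuts[-1]:g}"


def _band_labels(cuts: Sequence[float]) -> list[str]:
    labels = [f"<{cuts[0]:g}"]
    labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(cuts[:-1], cuts[1:])]
    labels.append(f">{cuts[-1]:g}")
    return labels


def stratified_accuracy(
    studies: Sequence[Study2x2],
    fri_bands: Sequence[float] = (6.0, 8.0),
    size_bands: Sequence[float] = (100.0, 1000.0),
    by_model: bool = False,
) -> pd.DataFrame:
    """Median (min, max) of per-study Se/Sp by FRI band crossed with
    training-set-size band (and optionally AI-model class).

    Studies without an FRI value (multi-disease studies) are left out.
    Empty strata are kept as rows with ``n_studies = 0``.
    """
    for cuts, name in ((fri_bands, "fri_bands"), (size_bands, "size_bands")):
        if list(cuts) != sorted(set(cuts)):
            raise ValidationError(f"{name} must be strictly increasing, got {cuts}")
    rows = []
    scored = [s for s in studies if s.covariates.get("fri") is not None]

    def stat_row(members: list[Study2x2]) -> dict[str, Any]:
        if not members:
            return {
                "n_studies": 0,
                "se_median": np.nan, "se_min": np.nan, "se_max": np.nan,
                "sp_median": np.nan, "sp_min": np.nan, "sp_max": np.nan,
            }
        se = np.array([summarize_study(s).se_hat for s in members])
        sp = np.array([summarize_study(s).sp_hat for s in members])
        return {
            "n_studies": len(members),
            "se_median": float(np.median(se)), "se_min": float(se.min()),
            "se_max": float(se.max()),
            "sp_median": float(np.median(sp)), "sp_min": float(sp.min()),
            "sp_max": float(sp.max()),
        }

    second_axes: list[tuple[str, list[str], Any]] = [
        (
            "training_n",
            _band_labels(size_bands),
            lambda s: _band_label(float(s.covariates.get("training_n", np.nan)), size_bands)
            if s.covariates.get("training_n") is not None
            else None,
        )
    ]
    if by_model:
        second_axes.append(
            (
                "model_class",
                ["deep_learning", "non_deep_learning"],
                lambda s: s.covariates.get("model_class")
                if s.covariates.get("model_class") in ("deep_learning", "non_deep_learning")
                else None,
            )
        )
    fri_labels = list(reversed(_band_labels(fri_bands)))  # high-FRI first
    for fri_label in fri_labels:
        in_band = [
            s for s in scored
            if _band_label(float(s.covariates["fri"]), fri_bands) == fri_label
        ]
        for dim, labels, selector in second_axes:
            for label in labels:
                members = [s for s in in_band if selector(s) == label]
                rows.append(
                    {"fri_band": fri_label, "dimension": dim, "stratum": label}
                    | stat_row(members)
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


class _StageLog:
    def __init__(self, path: Path | None, seed: int, config_hash: str):
        self.path = path
        self.seed = seed
        self.config_hash = config_hash
        self.records: list[dict[str, Any]] = []

    def stage(self, name: str, **info: Any) -> None:
        record = {
            "stage": name,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "elapsed_s": round(time.perf_counter() - getattr(self, "_t0", time.perf_counter()), 3),
            **info,
        }
        if not hasattr(self, "_t0"):
            self._t0 = time.perf_counter()
        self.records.append(record)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(record, default=_native) + "\n")


def attach_fri(
    studies: Sequence[Study2x2], fri_by_disease: dict[str, float]
) -> list[Study2x2]:
    """Fill each study's ``fri`` covariate from a disease lookup (existing
    explicit values win)."""
    out = []
    for s in studies:
        cov = dict(s.covariates)
        if cov.get("fri") is None and s.disease in fri_by_disease:
            cov["fri"] = fri_by_disease[s.disease]
        out.append(
            Study2x2(
                study_id=s.study_id, disease=s.disease,
                tp=s.tp, fp=s.fp, fn=s.fn, tn=s.tn, covariates=cov,
            )
        )
    return out


def run_full_analysis(
    studies_path: str | Path,
    phenotypes_path: str | Path | None = None,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Execute the complete analysis and (optionally) write all artifacts.

    Artifacts in ``out_dir``: report.json, forest.csv, sroc.csv,
    thresholds.csv, subgroups.csv, strata.csv, log.jsonl.  A failing stage
    raises :class:`AnalysisStageError` naming the stage; artifacts of
    completed stages are already on disk.
    """
    cfg = config or AnalysisConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        log_path = out / "log.jsonl"
        log_path.unlink(missing_ok=True)
    log = _StageLog(out / "log.jsonl" if out else None, cfg.seed, cfg.hash())
    started = time.strftime("%Y-%m-%dT%H:%M:%S%z")

    def run_stage(name: str, fn):
        try:
            result = fn()
        except Exception as e:  # noqa: BLE001 - rewrap with stage name
            log.stage(name, error=str(e))
            raise AnalysisStageError(name, e) from e
        log.stage(name, ok=True)
        return result

    # -- inputs
    studies = run_stage("read_studies", lambda: read_studies(studies_path))
    if phenotypes_path is not None:
        profiles = run_stage(
            "load_phenotypes", lambda: load_phenotype_table(phenotypes_path)
        )
    else:
        profiles = run_stage("load_phenotypes", load_reference_phenotypes)
    fri_map = {p.disease: compute_fri(p).fri for p in profiles}
    studies = attach_fri(studies, fri_map)
    all_ids = [s.study_id for s in studies]

    fit_opts = dict(
        quad_points=cfg.quad_points, restarts=cfg.restarts, seed=cfg.seed
    )

    # -- forest
    def make_forest() -> pd.DataFrame:
        rows = []
        for s in studies:
            a = summarize_study(s, cc=cfg.cc, ci_level=cfg.level)
            rows.append(
                {
                    "study_id": s.study_id, "disease": s.disease,
                    "tp": s.tp, "fp": s.fp, "fn": s.fn, "tn": s.tn,
                    "se": a.se_hat, "se_lo": a.se_ci[0], "se_hi": a.se_ci[1],
                    "sp": a.sp_hat, "sp_lo": a.sp_ci[0], "sp_hi": a.sp_ci[1],
                    "ln_or": a.ln_or, "var_ln_or": a.var_ln_or,
                    "corrected": a.corrected,
                }
            )
        return pd.DataFrame(rows)

    forest = run_stage("forest", make_forest)
    if out is not None:
        forest.to_csv(out / "forest.csv", index=False)

    # -- pooling and SROC
    fit = run_stage("pool", lambda: fit_bivariate(studies, **fit_opts))
    pooled = run_stage("pooled_summary", lambda: pooled_summary(fit, level=cfg.level))
    sroc_result = run_stage("sroc", lambda: sroc(fit, level=cfg.level))
    if out is not None:
        frames = [
            pd.DataFrame(sroc_result.curve, columns=["fpr", "se"]).assign(component="curve"),
            pd.DataFrame(sroc_result.conf_region.polygon, columns=["fpr", "se"]).assign(component="conf"),
            pd.DataFrame(sroc_result.pred_region.polygon, columns=["fpr", "se"]).assign(component="pred"),
        ]
        pd.concat(frames).to_csv(out / "sroc.csv", index=False)

    # -- meta-regression
    def make_metareg() -> tuple[MetaRegFit | None, list[str]]:
        eligible = [
            s for s in studies
            if s.covariates.get("fri") is not None
            and (not cfg.single_disease_only or s.covariates.get("n_diseases", 1) == 1)
        ]
        needed = len(cfg.metareg_covariates) + 2
        if len(eligible) < needed:
            return None, []
        mr = fit_metareg(
            eligible, cfg.metareg_covariates, method=cfg.metareg_method,
            level=cfg.level,
        )
        return mr, [s.study_id for s in eligible]

    metareg, metareg_ids = run_stage("metareg", make_metareg)

    # -- thresholds
    def make_thresholds() -> list[FriThreshold]:
        if cfg.threshold_coeffs == "eq2":
            slope, intercept = EQ2_COEFFS
        elif cfg.threshold_coeffs == "fitted":
            if metareg is None or "fri" not in metareg.coef:
                raise ValidationError("no fitted FRI relation for thresholds")
            slope, intercept = metareg.coef["fri"].beta, metareg.intercept.beta
        else:
            slope, intercept = cfg.threshold_coeffs
        return required_fri_table(cfg.threshold_targets, slope, intercept)

    thresholds = run_stage("thresholds", make_thresholds)
    if out is not None:
        pd.DataFrame([t.rounded() for t in thresholds]).to_csv(
            out / "thresholds.csv", index=False
        )

    # -- subgroups
    def make_subgroups() -> list[SubgroupResult]:
        results = []
        for variable, cut in cfg.subgroups:
            if variable == "model_class":
                splitter = categorical_splitter(
                    variable, on_missing="skip",
                    keep=("deep_learning", "non_deep_learning"),
                )
            elif cut is None:
                splitter = categorical_splitter(variable, on_missing="skip")
            else:
                splitter = threshold_splitter(variable, cut, on_missing="skip")
            try:
                results.append(
                    subgroup_analysis(studies, variable, splitter, level=cfg.level, **fit_opts)
                )
            except (ValidationError, FrimetaError):
                continue  # e.g. a variable absent from this dataset
        return results

    subgroups = run_stage("subgroups", make_subgroups)
    if out is not None:
        rows = [
            {
                "variable": r.variable, "label": g.label, "n_studies": g.n_studies,
                "se": g.se, "se_lo": g.se_ci[0], "se_hi": g.se_ci[1],
                "sp": g.sp, "sp_lo": g.sp_ci[0], "sp_hi": g.sp_ci[1],
                "degenerate": g.degenerate, "p_interaction": r.p_interaction,
            }
            for r in subgroups for g in r.groups
        ]
        pd.DataFrame(rows).to_csv(out / "subgroups.csv", index=False)

    # -- strata
    strata = run_stage(
        "strata",
        lambda: stratified_accuracy(
            studies, cfg.fri_bands, cfg.size_bands, by_model=cfg.by_model
        ),
    )
    if out is not None:
        strata.to_csv(out / "strata.csv", index=False)

    # -- sensitivity
    def make_sensitivity() -> list[ExclusionRefit]:
        results = []
        for flags in cfg.exclusion_sets:
            if not flags:
                results.append(
                    ExclusionRefit(
                        fit=fit, summary=pooled, dropped_study_ids=(),
                        kept_study_ids=tuple(all_ids), flags=frozenset(),
                    )
                )
            else:
                results.append(
                    refit_excluding(studies, flags, level=cfg.level, **fit_opts)
                )
        return results

    sensitivity = run_stage("sensitivity", make_sensitivity)

    provenance = {
        "seed": cfg.seed,
        "version": __version__,
        "config_hash": cfg.hash(),
        "config": cfg.to_dict(),
        "started": started,
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    report = AnalysisReport(
        pooled=pooled,
        sroc=sroc_result,
        metareg=metareg,
        thresholds=thresholds,
        subgroups=subgroups,
        strata=strata,
        sensitivity=sensitivity,
        forest=forest,
        fit=fit,
        study_ids={
            "pooled": all_ids,
            "sroc": all_ids,
            "metareg": metareg_ids,
            "thresholds": [],
            "subgroups": all_ids,
            "strata": [s.study_id for s in studies if s.covariates.get("fri") is not None],
            "sensitivity": all_ids,
        },
        provenance=provenance,
    )
    if out is not None:
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report.as_dict(), fh, indent=2)
    log.stage("done")
    return report
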