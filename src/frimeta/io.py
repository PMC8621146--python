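"""Study-level records: reading, validation, per-study accuracy summaries.

The atomic record of a diagnostic-test-accuracy meta-analysis is one study's
2x2 table — true positives (tp), false positives (fp), false negatives (fn),
true negatives (tn) — plus covariates describing how the study was run.
This module reads and writes those records (versioned CSV schema) and turns
each table into the per-study summary that every downstream stage consumes:
observed sensitivity and specificity with exact Clopper–Pearson intervals,
and the log diagnostic odds ratio with its Woolf variance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateArmError,
    EmptyInputError,
    SchemaError,
    ValidationError,
)

SCHEMA_VERSION = "1"

#: Mandatory columns of the versioned studies.csv schema.
REQUIRED_COLUMNS = ("study_id", "disease", "tp", "fp", "fn", "tn")

#: Optional covariate columns recognised by the schema.  Anything else in the
#: file is preserved verbatim under ``Study2x2.covariates``.
COVARIATE_COLUMNS = (
    "fri",
    "training_n",
    "resolution_px",
    "model_class",
    "control_type",
    "n_diseases",
    "validation",
    "excl_flags",
)

MODEL_CLASSES = frozenset({"deep_learning", "non_deep_learning", "unreported"})
CONTROL_TYPES = frozenset({"healthy", "other_diseases", "mixed"})
VALIDATION_TYPES = frozenset({"internal", "external"})
EXCL_FLAGS = frozenset(
    {"unclear_model", "unclear_reference", "external_validation", "unclear_sampling"}
)


@dataclass
class Study2x2:
    """One study's 2x2 diagnostic table plus covariates.

    Both arms must be non-empty: ``tp + fn >= 1`` (a diseased arm exists)
    and ``fp + tn >= 1`` (a control arm exists).
    """

    study_id: str
    disease: str
    tp: int
    fp: int
    fn: int
    tn: int
    covariates: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            value = getattr(self, name)
            if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
                raise ValidationError(
                    f"study {self.study_id!r}: count {name} must be an integer, "
                    f"got {value!r}"
                )
            if value < 0:
                raise ValidationError(
                    f"study {self.study_id!r}: count {name} must be >= 0, got {value}"
                )
            setattr(self, name, int(value))
        if self.tp + self.fn < 1:
            raise ValidationError(
                f"study {self.study_id!r}: diseased arm is empty (tp + fn = 0)"
            )
        if self.fp + self.tn < 1:
            raise ValidationError(
                f"study {self.study_id!r}: control arm is empty (fp + tn = 0)"
            )
        _validate_covariates(self.study_id, self.covariates)

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_control(self) -> int:
        return self.fp + self.tn

    @property
    def excl_flags(self) -> frozenset[str]:
        return frozenset(self.covariates.get("excl_flags", frozenset()))


@dataclass(frozen=True)
class StudyAccuracy:
    """Per-study accuracy summary derived from a :class:`Study2x2`.

    ``se_hat``/``sp_hat`` are raw proportions (never continuity-corrected);
    ``ln_or`` and its Woolf variance ``var_ln_or`` come from the table with a
    continuity correction added to every cell iff any cell is zero, in which
    case ``corrected`` is True.
    """

    se_hat: float
    sp_hat: float
    se_ci: tuple[float, float]
    sp_ci: tuple[float, float]
    ln_or: float
    var_ln_or: float
    corrected: bool


def _validate_covariates(study_id: str, cov: Mapping[str, Any]) -> None:
    def _bad(key: str, why: str) -> ValidationError:
        return ValidationError(f"study {study_id!r}: covariate {key!r} {why}")

    if "fri" in cov and cov["fri"] is not None:
        if not float(cov["fri"]) >= 0:
            raise _bad("fri", f"must be >= 0, got {cov['fri']!r}")
    for key in ("training_n", "resolution_px", "n_diseases"):
        if key in cov and cov[key] is not None:
            value = cov[key]
            if int(value) != value or int(value) < 1:
                raise _bad(key, f"must be a positive integer, got {value!r}")
    for key, allowed in (
        ("model_class", MODEL_CLASSES),
        ("control_type", CONTROL_TYPES),
        ("validation", VALIDATION_TYPES),
    ):
        if key in cov and cov[key] is not None and cov[key] not in allowed:
            raise _bad(key, f"must be one of {sorted(allowed)}, got {cov[key]!r}")
    flags = cov.get("excl_flags")
    if flags:
        unknown = set(flags) - EXCL_FLAGS
        if unknown:
            raise _bad("excl_flags", f"contains unknown flags {sorted(unknown)}")


def _parse_count(raw: Any, column: str, study_id: str) -> int:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"study {study_id!r}: column {column!r} is not a number: {raw!r}"
        ) from None
    if not value.is_integer():
        raise ValidationError(
            f"study {study_id!r}: column {column!r} must be an integer count, "
            f"got {raw!r} (fractional counts are rejected, not rounded)"
        )
    if value < 0:
        raise ValidationError(
            f"study {study_id!r}: column {column!r} must be >= 0, got {raw!r}"
        )
    return int(value)


def read_studies(path: str | Path, schema_version: str = SCHEMA_VERSION) -> list[Study2x2]:
    """Read a studies.csv file into validated :class:`Study2x2` records.

    Unknown columns are preserved under ``covariates``; row order is kept.
    ``excl_flags`` is parsed from a semicolon-separated token list.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {schema_version!r}; this build reads "
            f"version {SCHEMA_VERSION!r}"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, dtype=object, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty (no header)") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    if len(frame) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    studies: list[Study2x2] = []
    extra_columns = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
    for _, row in frame.iterrows():
        study_id = str(row["study_id"])
        counts = {c: _parse_count(row[c], c, study_id) for c in ("tp", "fp", "fn", "tn")}
        covariates: dict[str, Any] = {}
        for column in extra_columns:
            raw = row[column]
            if raw is None or (isinstance(raw, str) and raw.strip() == ""):
                continue
            covariates[column] = _parse_covariate(column, raw)
        studies.append(
            Study2x2(study_id=study_id, disease=str(row["disease"]), covariates=covariates, **counts)
        )
    return studies


def _parse_covariate(column: str, raw: Any) -> Any:
    if column == "excl_flags":
        return frozenset(t.strip() for t in str(raw).split(";") if t.strip())
    if column == "fri":
        return float(raw)
    if column in ("training_n", "resolution_px", "n_diseases"):
        return int(float(raw))
    return raw


def write_studies(studies: Iterable[Study2x2], path: str | Path) -> None:
    """Write records back to the versioned CSV schema (round-trip safe)."""
    rows = []
    for s in studies:
        row: dict[str, Any] = {
            "study_id": s.study_id,
            "disease": s.disease,
            "tp": s.tp,
            "fp": s.fp,
            "fn": s.fn,
            "tn": s.tn,
        }
        for key, value in s.covariates.items():
            if key == "excl_flags":
                value = ";".join(sorted(value))
            row[key] = value
        rows.append(row)
    columns = list(REQUIRED_COLUMNS) + sorted(
        {k for r in rows for k in r} - set(REQUIRED_COLUMNS)
    )
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def summarize_study(s: Study2x2, cc: float = 0.5, ci_level: float = 0.95) -> StudyAccuracy:
    """Per-study sensitivity/specificity with exact CIs and ln(OR) + variance.

    The continuity correction ``cc`` is added to *all four* cells, for the
    ln(OR) and its variance only, iff at least one cell is zero.  ``se_hat``
    and ``sp_hat`` always come from the raw counts; their intervals are
    Clopper–Pearson exact binomial at ``ci_level``.
    """
    if cc < 0:
        raise ValidationError(f"continuity correction must be >= 0, got {cc}")
    if not 0 < ci_level < 1:
        raise ValidationError(f"ci_level must be in (0, 1), got {ci_level}")
    if s.n_diseased == 0 or s.n_control == 0:
        raise DegenerateArmError(f"study {s.study_id!r}: one arm has no subjects")

    se_hat = s.tp / s.n_diseased
    sp_hat = s.tn / s.n_control
    cells = np.array([s.tp, s.fp, s.fn, s.tn], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + cc
    tp, fp, fn, tn = cells
    ln_or = math.log(tp * tn) - math.log(fp * fn)
    var_ln_or = float((1.0 / cells).sum())
    return StudyAccuracy(
        se_hat=se_hat,
        sp_hat=sp_hat,
        se_ci=clopper_pearson(s.tp, s.n_diseased, ci_level),
        sp_ci=clopper_pearson(s.tn, s.n_control, ci_level),
        ln_or=ln_or,
        var_ln_or=var_ln_or,
        corrected=corrected,
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion k/n."""
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lower, upper)


def write_report(results: Any, path: str | Path, format: str = "json") -> None:
    """Serialise a results object (mapping or list of mappings) losslessly.

    JSON keeps full float precision via repr round-tripping; CSV writes one
    row per record with full-precision floats.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(results, fh, indent=2, default=_jsonify)
    elif format == "csv":
        records = results if isinstance(results, list) else [results]
        flat = [_flatten(r) for r in records]
        columns: list[str] = []
        for r in flat:
            columns.extend(k for k in r if k not in columns)
        pd.DataFrame(flat, columns=columns).to_csv(
            path, index=False, float_format="%.17g"
        )
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "json") -> Any:
    path = Path(path)
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    if format == "csv":
        return pd.read_csv(path, float_precision="round_trip").to_dict(orient="records")
    raise ValidationError(f"unknown report format {format!r}")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialise {type(obj)!r}")


def _flatten(record: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, value in record.items():
        name = f"{prefix}{key}"
        if isinstance(value, Mapping):
            out.update(_flatten(value, prefix=f"{name}."))
        elif isinstance(value, (tuple, list)) and len(value) == 2 and all(
            isinstance(v, (int, float, np.floating)) for v in value
        ):
            out[f"{name}.lo"], out[f"{name}.hi"] = float(value[0]), float(value[1])
        else:
            out[name] = value
    return out
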