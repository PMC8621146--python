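"""Facial recognition intensity (FRI).

FRI scores how strongly a disease is written into the face:

    FRI = Nf x Pmax

where Nf is the number of *independent* facial phenotypes of the disease
(phenotypes that co-occur for anatomical reasons — e.g. a small jaw and
crowded teeth — share a correlation group and count once) and Pmax is the
maximum penetrance among all its facial phenotypes, i.e. the largest
fraction of patients exhibiting any single one of them.  A phenotype that is
definitional for a patient group has penetrance 1.

The packaged reference table covers the seven syndromes with published
phenotype inventories used throughout this package: Down syndrome (FRI 9),
acromegaly (8), Cornelia de Lange syndrome (7.443), Angelman syndrome (6),
Cushing's syndrome (5), fetal alcohol spectrum disorders (4) and Turner
syndrome (3.36).  Per-phenotype penetrances below the maximum are not
published for these inventories, so the reference table assigns each
disease's Pmax to every phenotype — a synthetic detail that leaves Nf, Pmax
and FRI exact.

The published record for Angelman syndrome is internally inconsistent: its
reference table prints FRI = 6 (six phenotypes, Pmax 100%) while the
accompanying text states FRI = 8.  The packaged fixture follows the table
and :func:`load_reference_phenotypes` raises a
:class:`~frimeta.exceptions.PublishedValueWarning` so the discrepancy is
never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import PublishedValueWarning, ValidationError

ANGELMAN_NOTE = (
    "Angelman syndrome: the published reference table prints FRI = 6 "
    "(Nf = 6, Pmax = 100%) but the accompanying text states FRI = 8; this "
    "package follows the table (FRI = 6)."
)


@dataclass(frozen=True)
class Phenotype:
    name: str
    penetrance: float  # fraction in (0, 1]
    group_id: str

    def __post_init__(self) -> None:
        if not 0 < self.penetrance <= 1:
            raise ValidationError(
                f"phenotype {self.name!r}: penetrance must be in (0, 1], "
                f"got {self.penetrance}"
            )
        if not self.group_id:
            raise ValidationError(f"phenotype {self.name!r}: empty group_id")


@dataclass(frozen=True)
class PhenotypeProfile:
    """A disease's facial phenotypes with penetrances and correlation groups."""

    disease: str
    phenotypes: tuple[Phenotype, ...]

    def __post_init__(self) -> None:
        if not self.phenotypes:
            raise ValidationError(f"disease {self.disease!r}: no phenotypes listed")
        names = [p.name for p in self.phenotypes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(
                f"disease {self.disease!r}: duplicate phenotype(s) {dupes}"
            )


@dataclass(frozen=True)
class FRIResult:
    disease: str
    nf: int
    pmax: float
    fri: float


def compute_fri(profile: PhenotypeProfile) -> FRIResult:
    """FRI = Nf x Pmax for one disease.

    Nf counts distinct correlation groups (correlated phenotypes count once);
    Pmax is the maximum penetrance over *all* listed phenotypes, not one
    representative per group.
    """
    nf = len({p.group_id for p in profile.phenotypes})
    pmax = max(p.penetrance for p in profile.phenotypes)
    return FRIResult(disease=profile.disease, nf=nf, pmax=pmax, fri=nf * pmax)


def load_phenotype_table(path: str | Path) -> list[PhenotypeProfile]:
    """Load a phenotype CSV (disease, phenotype, penetrance_pct, group_id).

    ``penetrance_pct`` is given in percent in files and stored as a fraction;
    values outside (0, 100] and duplicate (disease, phenotype) pairs are
    rejected.  Profiles come back in first-appearance order of the disease.
    """
    frame = pd.read_csv(path)
    required = {"disease", "phenotype", "penetrance_pct", "group_id"}
    missing = sorted(required - set(frame.columns))
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    bad = frame[(frame["penetrance_pct"] <= 0) | (frame["penetrance_pct"] > 100)]
    if len(bad):
        raise ValidationError(
            f"{path}: penetrance_pct outside (0, 100] for "
            f"{bad['phenotype'].tolist()}"
        )
    profiles: list[PhenotypeProfile] = []
    for disease, group in frame.groupby("disease", sort=False):
        profiles.append(
            PhenotypeProfile(
                disease=str(disease),
                phenotypes=tuple(
                    Phenotype(
                        name=str(row.phenotype),
                        penetrance=float(row.penetrance_pct) / 100.0,
                        group_id=str(row.group_id),
                    )
                    for row in group.itertuples()
                ),
            )
        )
    return profiles


def load_reference_phenotypes() -> list[PhenotypeProfile]:
    """The packaged seven-disease reference table (warns about Angelman)."""
    warnings.warn(ANGELMAN_NOTE, PublishedValueWarning, stacklevel=2)
    with resources.as_file(
        resources.files("frimeta.data").joinpath("phenotypes.csv")
    ) as path:
        return load_phenotype_table(path)


def reference_fri() -> dict[str, FRIResult]:
    """FRI for every disease in the packaged reference table, keyed by name."""
    return {p.disease: compute_fri(p) for p in load_reference_phenotypes()}
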