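"""Patient molecular profiles.

A profile is a list of pre-interpreted, gene-level biomarker calls
(gene symbol + alteration class + pathogenicity flag), together with the
clinical metadata that gates drug eligibility (diagnosis, age class,
allergies, accepted routes of administration). Inputs are interpreted
calls as found in published case reports; no variant-level nomenclature
or coordinates are modelled.

The *scoreable* biomarkers of a profile — pathogenic alterations that are
not negative/normal findings — define the denominator of the matching
score: a regimen that fully covers every scoreable biomarker scores 100%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

#: Closed vocabulary of alteration classes. Unknown classes are a load-time
#: error, never silently ignored.
ALTERATION_CLASSES = frozenset(
    {
        "mutation_activating",
        "mutation_loss",
        "amplification",
        "copy_loss",
        "fusion",
        "expression_positive",
        "expression_high",
        "expression_negative",
        "other",
    }
)

#: Classes that describe a negative/normal finding rather than an
#: alteration; retained in profiles for reporting but never scored.
NON_SCOREABLE_CLASSES = frozenset({"expression_negative"})

AGE_CLASSES = frozenset({"adult", "pediatric"})
ROUTES = frozenset({"oral", "iv", "other"})


@dataclass(frozen=True)
class MolecularAlteration:
    """A single gene-level biomarker call.

    Parameters
    ----------
    gene : str
        Gene symbol, upper-cased on construction.
    alteration_class : str
        One of :data:`ALTERATION_CLASSES`.
    pathogenic : bool
        Whether the call was interpreted as pathogenic.
    detail : str
        Free-text annotation (e.g. a protein change).
    """

    gene: str
    alteration_class: str
    pathogenic: bool = True
    detail: str = ""

    def __post_init__(self):
        if not self.gene:
            raise ValidationError("gene symbol must be non-empty", field="gene")
        object.__setattr__(self, "gene", self.gene.upper())
        if self.alteration_class not in ALTERATION_CLASSES:
            raise ValidationError(
                f"unknown alteration_class {self.alteration_class!r}",
                field="alteration_class",
            )


@dataclass(frozen=True)
class PatientProfile:
    """A patient's molecular profile plus eligibility-relevant metadata."""

    patient_id: str
    diagnosis: str = ""
    age_years: float | None = None
    age_class: str = "adult"
    alterations: tuple[MolecularAlteration, ...] = ()
    allergies: frozenset[str] = frozenset()
    accepted_routes: frozenset[str] | None = None

    def __post_init__(self):
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty", field="patient_id")
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"age_class must be one of {sorted(AGE_CLASSES)}", field="age_class"
            )
        if self.age_years is not None and self.age_years < 0:
            raise ValidationError("age_years must be non-negative", field="age_years")
        object.__setattr__(self, "alterations", tuple(self.alterations))
        object.__setattr__(self, "allergies", frozenset(self.allergies))
        if self.accepted_routes is not None:
            routes = frozenset(self.accepted_routes)
            if not routes <= ROUTES:
                raise ValidationError(
                    f"unknown routes {sorted(routes - ROUTES)}", field="accepted_routes"
                )
            object.__setattr__(self, "accepted_routes", routes)


def scoreable_biomarkers(profile: PatientProfile) -> list[MolecularAlteration]:
    """Return the alterations that enter the matching-score denominator.

    A biomarker is scoreable when it is pathogenic and not a
    negative/normal finding (``expression_negative``). This is a pure,
    order-preserving filter; its output length is the score denominator.
    """
    return [
        a
        for a in profile.alterations
        if a.pathogenic and a.alteration_class not in NON_SCOREABLE_CLASSES
    ]


def _profiles_from_rows(
    rows: Iterable[dict], meta: dict[str, dict], source: str
) -> list[PatientProfile]:
    """Group per-alteration rows into profiles, preserving file order."""
    by_patient: dict[str, list[MolecularAlteration]] = {}
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(rows):
        pid = str(row["patient_id"])
        try:
            alt = MolecularAlteration(
                gene=str(row["gene"]),
                alteration_class=str(row["alteration_class"]),
                pathogenic=_parse_bool(row.get("pathogenic", True)),
                detail=str(row.get("detail", "") or ""),
            )
        except ValidationError as exc:
            raise ValidationError(str(exc.args[0]), source=source, record=i) from exc
        key = (pid, alt.gene, alt.alteration_class)
        if key in seen:
            raise ValidationError(
                f"duplicate alteration row {key}", source=source, record=i
            )
        seen.add(key)
        by_patient.setdefault(pid, []).append(alt)
    profiles = []
    for pid, alts in by_patient.items():
        extra = meta.get(pid, {})
        profiles.append(
            PatientProfile(patient_id=pid, alterations=tuple(alts), **extra)
        )
    return profiles


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ValidationError(f"cannot parse boolean {value!r}", field="pathogenic")


def load_patient_metadata(path) -> dict[str, dict]:
    """Read a ``patients.tsv`` table (patient_id, diagnosis, age_years, age_class)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    meta = {}
    for _, row in df.iterrows():
        entry: dict = {}
        if row.get("diagnosis"):
            entry["diagnosis"] = row["diagnosis"]
        if row.get("age_years"):
            entry["age_years"] = float(row["age_years"])
        if row.get("age_class"):
            entry["age_class"] = row["age_class"]
        meta[str(row["patient_id"])] = entry
    return meta


def load_profiles(path, format: str | None = None, patients_path=None) -> list[PatientProfile]:
    """Load patient profiles from a TSV or JSON file.

    TSV dialect: tab-delimited with header
    ``patient_id  gene  alteration_class  pathogenic  detail``, one row per
    alteration, ``#`` comment lines ignored. Rows are grouped by
    ``patient_id`` preserving file order. JSON dialect: a list of profile
    objects mirroring :class:`PatientProfile` fields.

    Parameters
    ----------
    path : path-like
    format : {"tsv", "json"}, optional
        Inferred from the file suffix when omitted.
    patients_path : path-like, optional
        Companion ``patients.tsv`` with per-patient metadata (TSV only).
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        profiles = []
        for i, entry in enumerate(payload):
            try:
                alts = tuple(
                    MolecularAlteration(**a) for a in entry.get("alterations", [])
                )
                profiles.append(
                    PatientProfile(
                        patient_id=entry["patient_id"],
                        diagnosis=entry.get("diagnosis", ""),
                        age_years=entry.get("age_years"),
                        age_class=entry.get("age_class", "adult"),
                        alterations=alts,
                        allergies=frozenset(entry.get("allergies", ())),
                        accepted_routes=(
                            frozenset(entry["accepted_routes"])
                            if entry.get("accepted_routes") is not None
                            else None
                        ),
                    )
                )
            except (KeyError, ValidationError) as exc:
                raise ValidationError(
                    f"bad profile entry: {exc}", source=str(path), record=i
                ) from exc
        _check_unique_ids(profiles, str(path))
        return profiles
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"patient_id", "gene", "alteration_class"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(
                f"missing columns {sorted(missing)}", source=str(path)
            )
        meta = load_patient_metadata(patients_path) if patients_path else {}
        rows = df.fillna("").to_dict("records")
        profiles = _profiles_from_rows(rows, meta, str(path))
        _check_unique_ids(profiles, str(path))
        return profiles
    raise ValidationError(f"unknown profile format {format!r}", source=str(path))


def _check_unique_ids(profiles: Sequence[PatientProfile], source: str) -> None:
    seen = set()
    for p in profiles:
        if p.patient_id in seen:
            raise ValidationError(
                f"duplicate patient_id {p.patient_id!r}", source=source
            )
        seen.add(p.patient_id)


def patient51_profile() -> PatientProfile:
    """The packaged worked-example profile.

    A 38-year-old hormone-receptor-positive breast cancer case: ER and PR
    expression-positive, PTEN copy loss, and CCND1/FGFR1/PRKDC
    amplifications (six scoreable biomarkers), plus a Her2-negative finding
    that is reported but never scored. Whether the PR and Her2 statuses
    enter the denominator is not stated in the source case narrative; the
    six-biomarker denominator is the only reading under which the published
    single-agent and combination scores both reproduce, and it is the
    reading adopted here.
    """
    from importlib import resources

    ref = resources.files("oncomatch.data").joinpath("patient51_profile.tsv")
    with resources.as_file(ref) as path:
        (profile,) = load_profiles(path, format="tsv")
    return PatientProfile(
        patient_id=profile.patient_id,
        diagnosis="metastatic breast cancer, hormone receptor positive",
        age_years=38,
        age_class="adult",
        alterations=profile.alterations,
    )


def write_profiles_tsv(profiles: Sequence[PatientProfile], path) -> None:
    """Write profiles in the one-row-per-alteration TSV dialect."""
    rows = [
        {
            "patient_id": p.patient_id,
            "gene": a.gene,
            "alteration_class": a.alteration_class,
            "pathogenic": str(a.pathogenic).lower(),
            "detail": a.detail,
        }
        for p in profiles
        for a in p.alterations
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "gene", "alteration_class", "pathogenic", "detail"]
    ).to_csv(path, sep="\t", index=False)
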