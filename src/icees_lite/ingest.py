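"""Readers and writers for the two supported clinical interchange formats.

Flat CSV tables (patients, conditions, encounters, procedures) and a minimal
FHIR-R4-shaped JSON bundle both load into the same :class:`ClinicalDataset`,
and the two readers are observationally equivalent on fixtures written by
this package. Unknown CSV columns and unsupported FHIR fields are ignored;
unsupported FHIR resource types are skipped and counted, never fatal.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .model import (
    ClinicalDataset,
    ConditionRecord,
    EncounterRecord,
    ENCOUNTER_CLASSES,
    ETHNICITIES,
    IntegrityError,
    PatientRecord,
    ProcedureRecord,
    RACES,
    SEXES,
)

log = logging.getLogger(__name__)

RACE_EXT_URL = "http://hl7.org/fhir/us/core/StructureDefinition/us-core-race"
ETHNICITY_EXT_URL = "http://hl7.org/fhir/us/core/StructureDefinition/us-core-ethnicity"
GEOLOCATION_EXT_URL = "http://hl7.org/fhir/StructureDefinition/geolocation"
BLOCK_GROUP_EXT_URL = "urn:icees-lite:block-group"
GEOCODE_DATE_EXT_URL = "urn:icees-lite:geocode-date"

_FHIR_CLASS = {"ED": "EMER", "inpatient": "IMP", "outpatient": "AMB", "NICU": "NICU"}
_FHIR_CLASS_INV = {v: k for k, v in _FHIR_CLASS.items()}
_FHIR_GENDER = {"Male": "male", "Female": "female", "Unknown": "unknown"}
_FHIR_GENDER_INV = {v: k for k, v in _FHIR_GENDER.items()}

GESTATIONAL_AGE_EXT_URL = "urn:icees-lite:gestational-age-weeks"


@dataclass
class Violation:
    kind: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy when clean
        return not self.violations

    def kinds(self) -> list[str]:
        return [v.kind for v in self.violations]


def _parse_date(value: str, context: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise ValueError(f"{context}: unparseable date {value!r}") from exc


def _coerce_sex(value: str) -> str:
    if value in SEXES:
        return value
    log.warning("unrecognized sex value %r mapped to Unknown", value)
    return "Unknown"


def _coerce_race(value: str) -> str:
    if value in RACES:
        return value
    log.warning("unrecognized race value %r mapped to Other", value)
    return "Other"


def _coerce_ethnicity(value: str) -> str:
    if value in ETHNICITIES:
        return value
    log.warning("unrecognized ethnicity value %r mapped to Missing", value)
    return "Missing"


# -- flat CSV -----------------------------------------------------------------

PATIENT_HEADER = ["patient_id", "birth_date", "sex", "race", "ethnicity",
                  "latitude", "longitude", "block_group_id", "geocode_timestamp"]
CONDITION_HEADER = ["patient_id", "code", "date"]
ENCOUNTER_HEADER = ["patient_id", "encounter_class", "date", "location_tag",
                    "reason_codes", "gestational_age_weeks"]
PROCEDURE_HEADER = ["patient_id", "code", "date"]


def read_flat_tables(directory) -> ClinicalDataset:
    """Load the four flat CSVs into one dataset, enforcing referential integrity."""
    directory = Path(directory)
    for name in ("patients.csv", "conditions.csv", "encounters.csv", "procedures.csv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing clinical table: {directory / name}")

    ds = ClinicalDataset(provenance=f"csv:{directory}")
    seen: set[str] = set()
    with open(directory / "patients.csv", newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            pid = row["patient_id"]
            if pid in seen:
                raise IntegrityError(f"patients.csv: duplicate patient_id {pid!r}")
            seen.add(pid)
            lat, lon = row.get("latitude", ""), row.get("longitude", "")
            geopoint = (float(lat), float(lon)) if lat and lon else None
            gts = row.get("geocode_timestamp", "")
            ds.patients.append(PatientRecord(
                patient_id=pid,
                birth_date=_parse_date(row["birth_date"], f"patients.csv row {i}"),
                sex=_coerce_sex(row.get("sex", "Unknown")),
                race=_coerce_race(row.get("race", "Unknown")),
                ethnicity=_coerce_ethnicity(row.get("ethnicity", "Missing")),
                geopoint=geopoint,
                block_group_id=row.get("block_group_id") or None,
                geocode_timestamp=_parse_date(gts, f"patients.csv row {i}") if gts else None,
            ))

    with open(directory / "conditions.csv", newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            ds.conditions.append(ConditionRecord(
                patient_id=row["patient_id"], code=row["code"],
                date=_parse_date(row["date"], f"conditions.csv row {i}"),
            ))
    with open(directory / "encounters.csv", newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            gest = row.get("gestational_age_weeks", "")
            ds.encounters.append(EncounterRecord(
                patient_id=row["patient_id"],
                encounter_class=row["encounter_class"],
                date=_parse_date(row["date"], f"encounters.csv row {i}"),
                location_tag=row.get("location_tag") or None,
                reason_codes=[c for c in row.get("reason_codes", "").split(";") if c],
                gestational_age_weeks=float(gest) if gest else None,
            ))
    with open(directory / "procedures.csv", newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            ds.procedures.append(ProcedureRecord(
                patient_id=row["patient_id"], code=row["code"],
                date=_parse_date(row["date"], f"procedures.csv row {i}"),
            ))

    orphans = sorted(
        {r.patient_id for r in (*ds.conditions, *ds.encounters, *ds.procedures)} - seen
    )
    if orphans:
        raise IntegrityError(f"event records reference unknown patient ids: {orphans}")
    return ds


def write_flat_tables(ds: ClinicalDataset, directory) -> None:
    """Write the four CSVs; floats use repr so a read-back is exact."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "patients.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PATIENT_HEADER)
        for p in ds.patients:
            lat, lon = (repr(p.geopoint[0]), repr(p.geopoint[1])) if p.geopoint else ("", "")
            w.writerow([
                p.patient_id, p.birth_date.isoformat(), p.sex, p.race, p.ethnicity,
                lat, lon, p.block_group_id or "",
                p.geocode_timestamp.isoformat() if p.geocode_timestamp else "",
            ])
    with open(directory / "conditions.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CONDITION_HEADER)
        for c in ds.conditions:
            w.writerow([c.patient_id, c.code, c.date.isoformat()])
    with open(directory / "encounters.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ENCOUNTER_HEADER)
        for e in ds.encounters:
            w.writerow([
                e.patient_id, e.encounter_class, e.date.isoformat(),
                e.location_tag or "", ";".join(e.reason_codes),
                repr(e.gestational_age_weeks) if e.gestational_age_weeks is not None else "",
            ])
    with open(directory / "procedures.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PROCEDURE_HEADER)
        for p in ds.procedures:
            w.writerow([p.patient_id, p.code, p.date.isoformat()])


# -- FHIR-subset bundle -------------------------------------------------------


def _patient_resource(p: PatientRecord) -> dict:
    ext: list[dict] = [
        {"url": RACE_EXT_URL, "valueString": p.race},
        {"url": ETHNICITY_EXT_URL, "valueString": p.ethnicity},
    ]
    if p.geopoint is not None:
        ext.append({"url": GEOLOCATION_EXT_URL, "extension": [
            {"url": "latitude", "valueDecimal": p.geopoint[0]},
            {"url": "longitude", "valueDecimal": p.geopoint[1]},
        ]})
    if p.block_group_id is not None:
        ext.append({"url": BLOCK_GROUP_EXT_URL, "valueString": p.block_group_id})
    if p.geocode_timestamp is not None:
        ext.append({"url": GEOCODE_DATE_EXT_URL, "valueDate": p.geocode_timestamp.isoformat()})
    return {
        "resourceType": "Patient",
        "id": p.patient_id,
        "birthDate": p.birth_date.isoformat(),
        "gender": _FHIR_GENDER[p.sex],
        "extension": ext,
    }


def _encounter_resource(e: EncounterRecord) -> dict:
    res: dict = {
        "resourceType": "Encounter",
        "subject": {"reference": f"Patient/{e.patient_id}"},
        "class": {"code": _FHIR_CLASS[e.encounter_class]},
        "period": {"start": e.date.isoformat()},
    }
    if e.location_tag:
        res["serviceType"] = {"text": e.location_tag}
    if e.reason_codes:
        res["reasonCode"] = [{"coding": [{"code": c}]} for c in e.reason_codes]
    if e.gestational_age_weeks is not None:
        res["extension"] = [{"url": GESTATIONAL_AGE_EXT_URL,
                             "valueDecimal": e.gestational_age_weeks}]
    return res


def write_fhir_bundle(ds: ClinicalDataset, path) -> None:
    entries = [{"resource": _patient_resource(p)} for p in ds.patients]
    entries += [{"resource": {
        "resourceType": "Condition",
        "subject": {"reference": f"Patient/{c.patient_id}"},
        "code": {"coding": [{"code": c.code}]},
        "onsetDateTime": c.date.isoformat(),
    }} for c in ds.conditions]
    entries += [{"resource": _encounter_resource(e)} for e in ds.encounters]
    entries += [{"resource": {
        "resourceType": "Procedure",
        "subject": {"reference": f"Patient/{p.patient_id}"},
        "code": {"coding": [{"code": p.code}]},
        "performedDateTime": p.date.isoformat(),
    }} for p in ds.procedures]
    with open(path, "w") as fh:
        json.dump({"resourceType": "Bundle", "type": "collection", "entry": entries},
                  fh, indent=1)


def _subject_id(resource: dict) -> str:
    try:
        ref = resource["subject"]["reference"]
    except KeyError as exc:
        raise ValueError(
            f"{resource.get('resourceType')} entry missing subject reference"
        ) from exc
    return ref.split("/", 1)[1] if "/" in ref else ref


def read_fhir_bundle(path) -> ClinicalDataset:
    """Parse a minimal FHIR bundle; unsupported resource types are counted in
    ``dataset.metadata['skipped_resources']``."""
    with open(path) as fh:
        bundle = json.load(fh)
    ds = ClinicalDataset(provenance=f"fhir:{path}")
    skipped = 0
    for entry in bundle.get("entry", []):
        res = entry.get("resource", {})
        rtype = res.get("resourceType")
        if rtype == "Patient":
            geopoint = block_group = geodate = None
            race, ethnicity = "Unknown", "Missing"
            for ext in res.get("extension", []):
                url = ext.get("url")
                if url == RACE_EXT_URL:
                    race = _coerce_race(ext.get("valueString", "Unknown"))
                elif url == ETHNICITY_EXT_URL:
                    ethnicity = _coerce_ethnicity(ext.get("valueString", "Missing"))
                elif url == GEOLOCATION_EXT_URL:
                    coords = {e["url"]: e["valueDecimal"] for e in ext.get("extension", [])}
                    geopoint = (coords["latitude"], coords["longitude"])
                elif url == BLOCK_GROUP_EXT_URL:
                    block_group = ext.get("valueString")
                elif url == GEOCODE_DATE_EXT_URL:
                    geodate = dt.date.fromisoformat(ext["valueDate"])
            ds.patients.append(PatientRecord(
                patient_id=res["id"],
                birth_date=dt.date.fromisoformat(res["birthDate"]),
                sex=_FHIR_GENDER_INV.get(res.get("gender", "unknown"), "Unknown"),
                race=race, ethnicity=ethnicity,
                geopoint=geopoint, block_group_id=block_group, geocode_timestamp=geodate,
            ))
        elif rtype == "Condition":
            ds.conditions.append(ConditionRecord(
                patient_id=_subject_id(res),
                code=res["code"]["coding"][0]["code"],
                date=dt.date.fromisoformat(res["onsetDateTime"][:10]),
            ))
        elif rtype == "Encounter":
            gest = None
            for ext in res.get("extension", []):
                if ext.get("url") == GESTATIONAL_AGE_EXT_URL:
                    gest = float(ext["valueDecimal"])
            ds.encounters.append(EncounterRecord(
                patient_id=_subject_id(res),
                encounter_class=_FHIR_CLASS_INV.get(res["class"]["code"], "outpatient"),
                date=dt.date.fromisoformat(res["period"]["start"][:10]),
                location_tag=res.get("serviceType", {}).get("text") or None,
                reason_codes=[rc["coding"][0]["code"] for rc in res.get("reasonCode", [])],
                gestational_age_weeks=gest,
            ))
        elif rtype == "Procedure":
            ds.procedures.append(ProcedureRecord(
                patient_id=_subject_id(res),
                code=res["code"]["coding"][0]["code"],
                date=dt.date.fromisoformat(res["performedDateTime"][:10]),
            ))
        else:
            skipped += 1
    ds.metadata["skipped_resources"] = skipped
    return ds


def validate_dataset(ds: ClinicalDataset) -> ValidationReport:
    """Report-only integrity audit; an empty report means all invariants hold."""
    report = ValidationReport()
    seen: set[str] = set()
    for p in ds.patients:
        if p.patient_id in seen:
            report.violations.append(Violation(
                "duplicate-id", f"duplicate patient_id {p.patient_id!r}"))
        seen.add(p.patient_id)
        if p.geopoint is not None:
            lat, lon = p.geopoint
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                report.violations.append(Violation(
                    "coordinate-range",
                    f"patient {p.patient_id}: coordinate out of range ({lat}, {lon})"))
        if p.birth_date > dt.date.today():
            report.violations.append(Violation(
                "impossible-date", f"patient {p.patient_id}: birth date in the future"))
    for label, records in (("condition", ds.conditions), ("encounter", ds.encounters),
                           ("procedure", ds.procedures)):
        for r in records:
            if r.patient_id not in seen:
                report.violations.append(Violation(
                    "orphan-event",
                    f"{label} record references unknown patient {r.patient_id!r}"))
    for e in ds.encounters:
        if e.encounter_class not in ENCOUNTER_CLASSES:
            report.violations.append(Violation(
                "encounter-class", f"unknown encounter class {e.encounter_class!r}"))
    return report
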