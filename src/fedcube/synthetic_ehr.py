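"""Seeded multi-site synthetic bulk-FHIR generator.

Emulates what a network of healthcare sites would export over Bulk FHIR for
a respiratory-disease surveillance study, with known ground truth so every
downstream stage (de-identification, note NLP, phenotyping, aggregation,
epidemiological measures) can be tested for parameter recovery without an
EHR.  The generative model, per patient:

* disease status ~ Bernoulli(``disease_prevalence``);
* each symptom is truly present with a probability conditional on disease
  status (``symptom_profile``);
* each encounter's clinical note mentions a truly present symptom with
  probability ``note_mention_sensitivity`` (affirmed template) and an absent
  symptom with probability ``negated_mention_rate`` (negated template,
  e.g. "Patient denies fever.");
* a truly present symptom receives an ICD-10 Condition record with
  probability ``icd_coding_sensitivity`` — deliberately lower than the note
  mention sensitivity by default, so text-derived surveillance detects more
  symptoms than claims-style coding, a well-documented property of real
  EHR data;
* blood-pressure Observations are drawn from per-stratum normal
  distributions (hypertensive vs normotensive patients).

The disease itself is ICD-coded with probability 1.0 by default, so the
cohort selected by a code-based case definition is an unbiased sample and
aggregate-derived prevalence estimates ``disease_prevalence``.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so a fixed seed yields byte-identical NDJSON.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fedcube.errors import ConfigurationError, ValidationError
from fedcube.fhir_io import BulkExport, ResourceRecord, write_export
from fedcube.nlp import SymptomDictionary, load_default_dictionary

DISEASE_CODE = "U07.1"  # ICD-10 code for the study disease (COVID-19 style)
SYSTOLIC_LOINC = "8480-6"
DIASTOLIC_LOINC = "8462-4"

_GIVEN_NAMES = ["Avery", "Blake", "Casey", "Devon", "Emery", "Finley", "Harper", "Jordan"]
_FAMILY_NAMES = ["Whitfield", "Okafor", "Marchetti", "Lindqvist", "Abernathy", "Castellanos"]
_STREETS = ["Maplecrest Ave", "Ironwood Ln", "Silverbirch Rd", "Coppergate St"]
_CITIES = ["Springfield", "Riverton", "Lakeshore", "Fairview"]


@dataclass
class SyntheticConfig:
    """Population parameters governing the generator.

    Defaults encode the study conditions used throughout the test suite:
    a five-site network, 30% disease prevalence, note-mention sensitivity
    0.9 versus ICD coding sensitivity 0.5.
    """

    n_patients: int = 1000
    n_sites: int = 5
    study_window: tuple[str, str] = ("2020-03-01", "2021-02-28")
    disease_prevalence: float = 0.3
    #: symptom label -> (P(symptom | disease), P(symptom | no disease))
    symptom_profile: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "fever": (0.60, 0.05),
            "chills": (0.30, 0.02),
            "cough": (0.70, 0.10),
            "dyspnea": (0.40, 0.03),
            "headache": (0.50, 0.15),
        }
    )
    icd_coding_sensitivity: float = 0.5
    note_mention_sensitivity: float = 0.9
    negated_mention_rate: float = 0.3
    disease_coding_sensitivity: float = 1.0
    hypertension_prevalence: float = 0.25
    #: stratum -> {"systolic": (mean, sd), "diastolic": (mean, sd)}
    vitals_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "hypertensive": {"systolic": (152.0, 10.0), "diastolic": (96.0, 8.0)},
            "normotensive": {"systolic": (118.0, 8.0), "diastolic": (74.0, 6.0)},
        }
    )
    extra_encounter_rate: float = 0.2  # mean extra encounters per patient (Poisson)
    antihypertensive_rx_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.disease_prevalence,
            self.icd_coding_sensitivity,
            self.note_mention_sensitivity,
            self.negated_mention_rate,
            self.disease_coding_sensitivity,
            self.hypertension_prevalence,
            self.antihypertensive_rx_rate,
        ]
        for label, (p1, p0) in self.symptom_profile.items():
            probs.extend([p1, p0])
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability out of [0,1]: {p}")
        if self.n_patients < 1 or self.n_sites < 1:
            raise ConfigurationError("n_patients and n_sites must be positive")
        start, end = (date.fromisoformat(d) for d in self.study_window)
        if end < start:
            raise ConfigurationError("study_window end precedes start")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "study_window" in raw:
            raw["study_window"] = tuple(raw["study_window"])
        if "symptom_profile" in raw:
            raw["symptom_profile"] = {k: tuple(v) for k, v in raw["symptom_profile"].items()}
        return cls(**raw)

    @property
    def months(self) -> list[str]:
        start, end = (date.fromisoformat(d) for d in self.study_window)
        out = []
        y, m = start.year, start.month
        while (y, m) <= (end.year, end.month):
            out.append(f"{y:04d}-{m:02d}")
            m += 1
            if m > 12:
                y, m = y + 1, 1
        return out


@dataclass
class GroundTruth:
    """Line-level oracle for parameter-recovery tests; never fed to the pipeline."""

    patients: pd.DataFrame  # patient_id, site, disease, hypertensive, symptom flags
    encounters: pd.DataFrame  # encounter_id, patient_id, site, month

    def write_csv(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out_dir / "truth_patients.csv", index=False)
        self.encounters.to_csv(out_dir / "truth_encounters.csv", index=False)


def _month_days(month: str) -> int:
    y, m = (int(x) for x in month.split("-"))
    if m == 12:
        nxt = date(y + 1, 1, 1)
    else:
        nxt = date(y, m + 1, 1)
    return (nxt - date(y, m, 1)).days


def _note_text(
    rng: np.random.Generator,
    given: str,
    family: str,
    mentioned: list[str],
    negated: list[str],
    dictionary: SymptomDictionary,
) -> str:
    """Build a note from templates using only registered surface forms."""
    parts = [f"Emergency department visit. Patient {given} {family} evaluated today."]
    for label in mentioned:
        form = dictionary.forms_for_label(label)[int(rng.integers(len(dictionary.forms_for_label(label))))]
        tmpl = int(rng.integers(3))
        if tmpl == 0:
            parts.append(f"Patient reports {form}.")
        elif tmpl == 1:
            parts.append(f"Presenting with {form} since yesterday.")
        else:
            parts.append(f"Positive for {form} on exam.")
    for label in negated:
        form = dictionary.forms_for_label(label)[int(rng.integers(len(dictionary.forms_for_label(label))))]
        tmpl = int(rng.integers(3))
        if tmpl == 0:
            parts.append(f"Patient denies {form}.")
        elif tmpl == 1:
            parts.append(f"No {form}.")
        else:
            parts.append(f"Negative for {form} at triage.")
    parts.append("Plan discussed with patient.")
    return " ".join(parts)


def generate_population(
    config: SyntheticConfig, dictionary: SymptomDictionary | None = None
) -> tuple[list[BulkExport], GroundTruth]:
    """Generate one :class:`BulkExport` per site plus line-level ground truth.

    Patients are assigned to sites round-robin so exactly ``n_patients``
    Patient records exist across the network; every patient has at least one
    encounter inside the study window, and every encounter carries one
    clinical note, a blood-pressure pair, and probabilistic symptom coding.
    """
    dictionary = dictionary or load_default_dictionary()
    for label in config.symptom_profile:
        if dictionary.code_for_label(label) is None:
            raise ConfigurationError(f"symptom {label!r} not in dictionary")
    rng = np.random.default_rng(config.seed)
    months = config.months
    symptom_labels = list(config.symptom_profile)

    site_names = [f"site{i + 1}" for i in range(config.n_sites)]
    exports = {
        s: BulkExport(records={t: [] for t in
                               ("Patient", "Encounter", "Condition", "Observation",
                                "DocumentReference", "MedicationRequest")},
                      source_site=s,
                      export_time="2021-03-01T00:00:00")
        for s in site_names
    }
    truth_pat_rows: list[dict] = []
    truth_enc_rows: list[dict] = []

    start_year = int(config.study_window[0][:4])
    for i in range(config.n_patients):
        site = site_names[i % config.n_sites]
        ex = exports[site]
        pid = f"pat-{i:06d}"
        given = _GIVEN_NAMES[int(rng.integers(len(_GIVEN_NAMES)))]
        family = _FAMILY_NAMES[int(rng.integers(len(_FAMILY_NAMES)))]
        gender = "female" if rng.random() < 0.5 else "male"
        age = int(rng.integers(0, 90))  # capped at 89
        birth_year = start_year - age
        birth_date = f"{birth_year:04d}-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"
        phone = f"555-{int(rng.integers(100, 1000)):03d}-{int(rng.integers(1000, 10000)):04d}"
        street = f"{int(rng.integers(1, 999))} {_STREETS[int(rng.integers(len(_STREETS)))]}"
        city = _CITIES[int(rng.integers(len(_CITIES)))]

        diseased = bool(rng.random() < config.disease_prevalence)
        true_symptoms = {
            s: bool(rng.random() < (config.symptom_profile[s][0] if diseased else config.symptom_profile[s][1]))
            for s in symptom_labels
        }
        hypertensive = bool(rng.random() < config.hypertension_prevalence)
        stratum = "hypertensive" if hypertensive else "normotensive"

        ex.records["Patient"].append(ResourceRecord("Patient", pid, {
            "resourceType": "Patient",
            "id": pid,
            "name": [{"family": family, "given": [given]}],
            "telecom": [{"system": "phone", "value": phone}],
            "address": [{"line": [street], "city": city, "state": "MA"}],
            "gender": gender,
            "birthDate": birth_date,
        }))
        truth_pat_rows.append({
            "patient_id": pid, "site": site, "disease": diseased,
            "hypertensive": hypertensive,
            **{f"sym_{s}": true_symptoms[s] for s in symptom_labels},
        })

        n_enc = 1 + int(rng.poisson(config.extra_encounter_rate))
        for j in range(n_enc):
            eid = f"enc-{i:06d}-{j}"
            month = months[int(rng.integers(len(months)))]
            day = int(rng.integers(1, _month_days(month) + 1))
            enc_date = f"{month}-{day:02d}"
            ex.records["Encounter"].append(ResourceRecord("Encounter", eid, {
                "resourceType": "Encounter",
                "id": eid,
                "subject": {"reference": f"Patient/{pid}"},
                "class": {"code": "EMER"},
                "period": {"start": enc_date, "end": enc_date},
            }))
            truth_enc_rows.append({"encounter_id": eid, "patient_id": pid, "site": site, "month": month})

            if diseased and rng.random() < config.disease_coding_sensitivity:
                cid = f"cond-{eid}-dx"
                ex.records["Condition"].append(_condition(cid, pid, eid, DISEASE_CODE, enc_date))
            mentioned, negated = [], []
            for s in symptom_labels:
                if true_symptoms[s]:
                    if rng.random() < config.icd_coding_sensitivity:
                        code = dictionary.code_for_label(s)
                        cid = f"cond-{eid}-{code}"
                        ex.records["Condition"].append(_condition(cid, pid, eid, code, enc_date))
                    if rng.random() < config.note_mention_sensitivity:
                        mentioned.append(s)
                elif rng.random() < config.negated_mention_rate:
                    negated.append(s)

            sys_mu, sys_sd = config.vitals_model[stratum]["systolic"]
            dia_mu, dia_sd = config.vitals_model[stratum]["diastolic"]
            systolic = int(round(rng.normal(sys_mu, sys_sd)))
            diastolic = int(round(rng.normal(dia_mu, dia_sd)))
            for code, value in ((SYSTOLIC_LOINC, systolic), (DIASTOLIC_LOINC, diastolic)):
                oid = f"obs-{eid}-{code}"
                ex.records["Observation"].append(ResourceRecord("Observation", oid, {
                    "resourceType": "Observation",
                    "id": oid,
                    "subject": {"reference": f"Patient/{pid}"},
                    "encounter": {"reference": f"Encounter/{eid}"},
                    "code": {"coding": [{"system": "http://loinc.org", "code": code}]},
                    "valueQuantity": {"value": value, "unit": "mm[Hg]"},
                    "effectiveDateTime": enc_date,
                }))

            text = _note_text(rng, given, family, mentioned, negated, dictionary)
            did = f"doc-{eid}"
            ex.records["DocumentReference"].append(ResourceRecord("DocumentReference", did, {
                "resourceType": "DocumentReference",
                "id": did,
                "subject": {"reference": f"Patient/{pid}"},
                "context": {"encounter": [{"reference": f"Encounter/{eid}"}]},
                "date": enc_date,
                "content": [{"attachment": {
                    "contentType": "text/plain",
                    "data": base64.b64encode(text.encode("utf-8")).decode("ascii"),
                }}],
            }))

            if hypertensive and j == 0 and rng.random() < config.antihypertensive_rx_rate:
                mid = f"rx-{eid}"
                ex.records["MedicationRequest"].append(ResourceRecord("MedicationRequest", mid, {
                    "resourceType": "MedicationRequest",
                    "id": mid,
                    "subject": {"reference": f"Patient/{pid}"},
                    "encounter": {"reference": f"Encounter/{eid}"},
                    "medicationCodeableConcept": {
                        "coding": [{"system": "http://www.nlm.nih.gov/research/umls/rxnorm",
                                    "code": "29046", "display": "lisinopril"}]},
                    "authoredOn": enc_date,
                }))

    truth = GroundTruth(
        patients=pd.DataFrame(truth_pat_rows),
        encounters=pd.DataFrame(truth_enc_rows),
    )
    return [exports[s] for s in site_names], truth


def _condition(cid: str, pid: str, eid: str, code: str, recorded: str) -> ResourceRecord:
    return ResourceRecord("Condition", cid, {
        "resourceType": "Condition",
        "id": cid,
        "subject": {"reference": f"Patient/{pid}"},
        "encounter": {"reference": f"Encounter/{eid}"},
        "code": {"coding": [{"system": "http://hl7.org/fhir/sid/icd-10-cm", "code": code}]},
        "recordedDate": recorded,
    })


def rare_combination_cohort(n: int = 500, seed: int = 0) -> pd.DataFrame:
    """A skewed three-variable discrete cohort engineered so that many joint
    level combinations hold only 1-9 units — the regime where small-cell
    suppression must bite."""
    rng = np.random.default_rng(seed)
    levels = ["a", "b", "c", "d", "e"]
    probs = [0.55, 0.25, 0.12, 0.05, 0.03]
    return pd.DataFrame({
        f"v{i + 1}": rng.choice(levels, size=n, p=probs) for i in range(3)
    })


def write_site_exports(
    exports: list[BulkExport], out_dir: str | Path, overwrite: bool = False
) -> list[Path]:
    """Write one subdirectory per site, each holding the six NDJSON files."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise ValidationError(f"output directory {out_dir} exists and is non-empty (pass overwrite=True)")
    paths = []
    for ex in exports:
        paths.append(write_export(ex, out_dir / ex.source_site))
    return paths
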