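"""Tabular study library: flatten de-identified resources and evaluate
computable phenotypes.

Raw FHIR resources are nested and awkward to query, so the library reduces
them to flat tables (patients, encounters, conditions, observations,
text-derived symptoms, medications).  A study is defined by three parts: a
case definition (boolean combination of code-in-value-set,
numeric-threshold, and medication criteria), study variables (boolean /
categorical / binned-integer / month), and a study period.  Only events
inside the study period can influence case status or variables.

The shipped hypertension phenotype follows the blood-pressure arm of the
CMS controlled-hypertension quality measure: an encounter qualifies when
systolic >= 140 mm Hg OR diastolic >= 90 mm Hg, both comparators inclusive.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from fedcube.errors import ConfigurationError, ValidationError
from fedcube.fhir_io import ResourceRecord

logger = logging.getLogger(__name__)

SYSTOLIC_LOINC = "8480-6"
DIASTOLIC_LOINC = "8462-4"


# ---------------------------------------------------------------------------
# value sets


@dataclass
class ValueSet:
    """A named collection of terminology codes (VSAC style)."""

    id: str
    system: str
    codes: set[str]

    def __post_init__(self) -> None:
        if not self.codes:
            raise ConfigurationError(f"value set {self.id!r} has no codes")

    @classmethod
    def from_csv(cls, vs_id: str, path: str | Path) -> "ValueSet":
        """Two-column (system, code) CSV mirroring a VSAC export."""
        systems, codes = set(), set()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() == "system":
                    continue
                systems.add(row[0].strip())
                codes.add(row[1].strip())
        return cls(id=vs_id, system="|".join(sorted(systems)) or "unknown", codes=codes)


# ---------------------------------------------------------------------------
# flat tables


@dataclass
class StudyTableSet:
    """Simplified tabular representations of the de-identified resources."""

    patients: pd.DataFrame      # patient_id, sex, birth_year
    encounters: pd.DataFrame    # encounter_id, patient_id, month, enc_class
    conditions: pd.DataFrame    # encounter_id, patient_id, system, code
    observations: pd.DataFrame  # encounter_id, patient_id, code, value, unit
    symptoms: pd.DataFrame      # encounter_id, patient_id, code, month, source
    medications: pd.DataFrame   # encounter_id, patient_id, system, code

    def write_csv(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("patients", "encounters", "conditions", "observations",
                     "symptoms", "medications"):
            getattr(self, name).to_csv(out_dir / f"{name}.csv", index=False)

    @classmethod
    def read_csv(cls, in_dir: str | Path) -> "StudyTableSet":
        in_dir = Path(in_dir)
        frames = {}
        for name in ("patients", "encounters", "conditions", "observations",
                     "symptoms", "medications"):
            frames[name] = pd.read_csv(in_dir / f"{name}.csv", dtype=str)
        for col in ("value",):
            if not frames["observations"].empty:
                frames["observations"]["value"] = frames["observations"]["value"].astype(float)
        if not frames["patients"].empty:
            frames["patients"]["birth_year"] = frames["patients"]["birth_year"].astype(int)
        return cls(**frames)


def _ref_id(body: dict, fname: str) -> str | None:
    ref = body.get(fname, {}).get("reference")
    if ref is None:
        return None
    return ref.split("/", 1)[-1]


def _enc_ref_id(body: dict) -> str | None:
    # DocumentReference keeps encounter under context; others use a direct field
    direct = _ref_id(body, "encounter")
    if direct:
        return direct
    ctx = body.get("context", {}).get("encounter", [])
    if ctx:
        return ctx[0].get("reference", "").split("/", 1)[-1] or None
    return None


def _is_nlp_record(body: dict) -> bool:
    tags = body.get("meta", {}).get("tag", [])
    return any(t.get("code") == "nlp" for t in tags)


def flatten(records_by_type: dict[str, list[ResourceRecord]]) -> StudyTableSet:
    """Reduce de-identified resources to the flat study tables.

    Row counts equal input counts per type minus rows failing minimal-field
    validation (logged); text-derived symptom Observations (tagged
    ``nlp``) are routed to the symptom table rather than the numeric
    observation table.  Dangling references are retained as nulls with a
    warning so downstream joins can surface them.
    """
    pat_rows, enc_rows, cond_rows, obs_rows, sym_rows, med_rows = [], [], [], [], [], []
    for rec in records_by_type.get("Patient", []):
        b = rec.body
        birth = b.get("birthDate", "")
        if len(birth) < 4:
            logger.warning("Patient/%s lacks a birth date; row dropped", rec.id)
            continue
        pat_rows.append({"patient_id": rec.id, "sex": b.get("gender", "unknown"),
                         "birth_year": int(birth[:4])})
    for rec in records_by_type.get("Encounter", []):
        b = rec.body
        start = b.get("period", {}).get("start", "")
        if len(start) < 7:
            logger.warning("Encounter/%s lacks a period start; row dropped", rec.id)
            continue
        pid = _ref_id(b, "subject")
        if pid is None:
            logger.warning("Encounter/%s has a dangling subject reference", rec.id)
        enc_rows.append({"encounter_id": rec.id, "patient_id": pid,
                         "month": start[:7], "enc_class": b.get("class", {}).get("code", "")})
    for rec in records_by_type.get("Condition", []):
        b = rec.body
        coding = b.get("code", {}).get("coding", [])
        if not coding:
            logger.warning("Condition/%s has no coding; row dropped", rec.id)
            continue
        cond_rows.append({"encounter_id": _enc_ref_id(b), "patient_id": _ref_id(b, "subject"),
                          "system": coding[0].get("system", ""), "code": coding[0].get("code", "")})
    for rec in records_by_type.get("Observation", []):
        b = rec.body
        coding = b.get("code", {}).get("coding", [])
        code = coding[0].get("code", "") if coding else ""
        if _is_nlp_record(b):
            sym_rows.append({"encounter_id": _enc_ref_id(b), "patient_id": _ref_id(b, "subject"),
                             "code": code, "month": (b.get("effectiveDateTime") or "")[:7],
                             "source": "nlp"})
            continue
        vq = b.get("valueQuantity")
        if vq is None or "value" not in vq:
            logger.warning("Observation/%s lacks a numeric value; row dropped", rec.id)
            continue
        obs_rows.append({"encounter_id": _enc_ref_id(b), "patient_id": _ref_id(b, "subject"),
                         "code": code, "value": float(vq["value"]), "unit": vq.get("unit", "")})
    for rec in records_by_type.get("MedicationRequest", []):
        b = rec.body
        coding = b.get("medicationCodeableConcept", {}).get("coding", [])
        if not coding:
            logger.warning("MedicationRequest/%s has no coding; row dropped", rec.id)
            continue
        med_rows.append({"encounter_id": _enc_ref_id(b), "patient_id": _ref_id(b, "subject"),
                         "system": coding[0].get("system", ""), "code": coding[0].get("code", "")})

    def frame(rows, columns):
        return pd.DataFrame(rows, columns=columns)

    return StudyTableSet(
        patients=frame(pat_rows, ["patient_id", "sex", "birth_year"]),
        encounters=frame(enc_rows, ["encounter_id", "patient_id", "month", "enc_class"]),
        conditions=frame(cond_rows, ["encounter_id", "patient_id", "system", "code"]),
        observations=frame(obs_rows, ["encounter_id", "patient_id", "code", "value", "unit"]),
        symptoms=frame(sym_rows, ["encounter_id", "patient_id", "code", "month", "source"]),
        medications=frame(med_rows, ["encounter_id", "patient_id", "system", "code"]),
    )


# ---------------------------------------------------------------------------
# case-definition criteria


class Criterion:
    """Base: evaluates to the set of in-period encounter ids satisfying it."""

    def encounter_ids(self, tables: StudyTableSet, universe: set[str]) -> set[str]:
        raise NotImplementedError


@dataclass
class CodeInValueSet(Criterion):
    """Encounter has a row in the condition/symptom/medication table whose
    code is in the value set."""

    table: str  # condition | symptom | medication
    valueset: ValueSet

    def encounter_ids(self, tables: StudyTableSet, universe: set[str]) -> set[str]:
        frame = {"condition": tables.conditions, "symptom": tables.symptoms,
                 "medication": tables.medications}.get(self.table)
        if frame is None:
            raise ConfigurationError(f"unknown criterion table {self.table!r}")
        hits = frame[frame["code"].isin(self.valueset.codes)]
        return set(hits["encounter_id"].dropna()) & universe


_COMPARATORS = {
    ">=": lambda s, v: s >= v,
    ">": lambda s, v: s > v,
    "<=": lambda s, v: s <= v,
    "<": lambda s, v: s < v,
    "==": lambda s, v: s == v,
}


@dataclass
class NumericThreshold(Criterion):
    """Encounter has a numeric observation of *code* meeting the comparator."""

    code: str
    comparator: str
    value: float

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ConfigurationError(f"unknown comparator {self.comparator!r}")

    def encounter_ids(self, tables: StudyTableSet, universe: set[str]) -> set[str]:
        obs = tables.observations
        rows = obs[(obs["code"] == self.code)
                   & _COMPARATORS[self.comparator](obs["value"], self.value)]
        return set(rows["encounter_id"].dropna()) & universe


@dataclass
class AllEncounters(Criterion):
    """Matches every in-period encounter — the inclusion criterion for
    whole-population surveillance cohorts."""

    def encounter_ids(self, tables, universe):
        return set(universe)


@dataclass
class AnyOf(Criterion):
    criteria: list[Criterion]

    def encounter_ids(self, tables, universe):
        out: set[str] = set()
        for c in self.criteria:
            out |= c.encounter_ids(tables, universe)
        return out


@dataclass
class AllOf(Criterion):
    criteria: list[Criterion]

    def encounter_ids(self, tables, universe):
        out = set(universe)
        for c in self.criteria:
            out &= c.encounter_ids(tables, universe)
        return out


@dataclass
class Not(Criterion):
    criterion: Criterion

    def encounter_ids(self, tables, universe):
        return set(universe) - self.criterion.encounter_ids(tables, universe)


@dataclass
class CaseDefinition:
    """Inclusion criteria minus exclusion criteria (exclusion applied after)."""

    inclusion: Criterion
    exclusion: Criterion | None = None

    def case_encounters(self, tables: StudyTableSet, universe: set[str]) -> set[str]:
        cases = self.inclusion.encounter_ids(tables, universe)
        if self.exclusion is not None:
            cases -= self.exclusion.encounter_ids(tables, universe)
        return cases


# ---------------------------------------------------------------------------
# study variables and spec


@dataclass
class StudyVariable:
    """One discrete element of the aggregate-matrix variable set.

    kinds:
      * ``boolean``     — a :class:`Criterion`; true iff the unit has (any)
                          qualifying in-period encounter
      * ``categorical`` — a patient-table column (e.g. sex)
      * ``binned_age``  — age at encounter bucketed by ``bins`` edges
                          (strictly increasing, right-open intervals)
      * ``month``       — encounter month, formatted YYYY-MM
    """

    name: str
    kind: str
    criterion: Criterion | None = None
    column: str | None = None
    bins: list[int] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("boolean", "categorical", "binned_age", "month"):
            raise ConfigurationError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "boolean" and self.criterion is None:
            raise ConfigurationError(f"variable {self.name!r}: boolean kind needs a criterion")
        if self.kind == "categorical" and not self.column:
            raise ConfigurationError(f"variable {self.name!r}: categorical kind needs a column")
        if self.kind == "binned_age":
            if len(self.bins) < 2 or any(b >= c for b, c in zip(self.bins, self.bins[1:])):
                raise ConfigurationError(
                    f"variable {self.name!r}: bin edges must be strictly increasing")


@dataclass
class StudySpec:
    """Case definition + ordered study variables + study period."""

    case_definition: CaseDefinition
    variables: list[StudyVariable]
    study_period: tuple[str, str]  # inclusive YYYY-MM bounds
    count_unit: str = "patients"   # patients | encounters

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(names) != len(set(names)):
            raise ConfigurationError("study variable names must be unique")
        if self.count_unit not in ("patients", "encounters"):
            raise ConfigurationError(f"count_unit must be patients|encounters, got {self.count_unit!r}")
        lo, hi = self.study_period
        if hi < lo:
            raise ConfigurationError("study period is empty")


def bin_label(value: int, bins: list[int]) -> str:
    """Right-open interval label, e.g. value 7 with edges [0,5,12,...] -> '5-11'."""
    for lo, hi in zip(bins, bins[1:]):
        if lo <= value < hi:
            return f"{lo}-{hi - 1}"
    return "out-of-range"


def _in_period(tables: StudyTableSet, period: tuple[str, str]) -> pd.DataFrame:
    lo, hi = (p[:7] for p in period)
    enc = tables.encounters
    return enc[(enc["month"] >= lo) & (enc["month"] <= hi)]


def evaluate_case(
    tables: StudyTableSet, spec: StudySpec, include_comparison: bool = False
) -> pd.DataFrame:
    """Label each counting unit (patient or encounter) as case / non-case.

    Only encounters inside the study period participate.  Non-case units
    are retained only when a comparison cohort is requested.
    """
    enc = _in_period(tables, spec.study_period)
    universe = set(enc["encounter_id"])
    case_encs = spec.case_definition.case_encounters(tables, universe)
    enc = enc.assign(case=enc["encounter_id"].isin(case_encs))
    if spec.count_unit == "encounters":
        cohort = enc[["encounter_id", "patient_id", "month", "case"]].copy()
    else:
        # a patient is a case iff any in-period encounter qualifies
        flags = enc.groupby("patient_id")["case"].any()
        cohort = flags.reset_index().rename(columns={"case": "case"})
    if not include_comparison:
        cohort = cohort[cohort["case"]].copy()
    return cohort.reset_index(drop=True)


def derive_variables(
    cohort: pd.DataFrame, tables: StudyTableSet, spec: StudySpec
) -> pd.DataFrame:
    """Attach one column per study variable; every unit gets exactly one value."""
    enc = _in_period(tables, spec.study_period)
    universe = set(enc["encounter_id"])
    out = cohort.copy()
    unit_col = "encounter_id" if spec.count_unit == "encounters" else "patient_id"
    # per-patient helper frames
    pat = tables.patients.set_index("patient_id") if not tables.patients.empty else None
    first_month = enc.sort_values(["month", "encounter_id"]).groupby("patient_id")["month"].first()

    for var in spec.variables:
        if var.kind == "boolean":
            hits = var.criterion.encounter_ids(tables, universe)
            if spec.count_unit == "encounters":
                values = out["encounter_id"].isin(hits)
            else:
                pats_with_hit = set(enc[enc["encounter_id"].isin(hits)]["patient_id"])
                values = out["patient_id"].isin(pats_with_hit)
            out[var.name] = values.map({True: "true", False: "false"})
        elif var.kind == "categorical":
            if pat is None or var.column not in pat.columns:
                raise ConfigurationError(f"variable {var.name!r}: column {var.column!r} not found")
            mapped = out["patient_id"].map(pat[var.column])
            if mapped.isna().any():
                raise ValidationError(f"variable {var.name!r} yields no value for some units")
            out[var.name] = mapped.astype(str)
        elif var.kind == "month":
            if spec.count_unit == "encounters":
                out[var.name] = out["month"]
            else:
                out[var.name] = out["patient_id"].map(first_month)
        elif var.kind == "binned_age":
            if pat is None:
                raise ConfigurationError(f"variable {var.name!r}: patient table is empty")
            birth = out["patient_id"].map(pat["birth_year"])
            if spec.count_unit == "encounters":
                enc_year = out["month"].str[:4].astype(int)
            else:
                enc_year = out["patient_id"].map(first_month).str[:4].astype(int)
            age = enc_year - birth
            out[var.name] = age.map(lambda a: bin_label(int(a), var.bins))
        nun = out.groupby(unit_col)[var.name].nunique()
        if (nun > 1).any():
            raise ValidationError(f"variable {var.name!r} yields multiple values per unit")
    return out


# ---------------------------------------------------------------------------
# YAML loading and the shipped hypertension phenotype


def _criterion_from_yaml(node: dict, value_sets: dict[str, ValueSet]) -> Criterion:
    if "any_of" in node:
        return AnyOf([_criterion_from_yaml(c, value_sets) for c in node["any_of"]])
    if "all_of" in node:
        return AllOf([_criterion_from_yaml(c, value_sets) for c in node["all_of"]])
    if "not" in node:
        return Not(_criterion_from_yaml(node["not"], value_sets))
    if "numeric_threshold" in node:
        nt = node["numeric_threshold"]
        return NumericThreshold(code=str(nt["code"]), comparator=nt["comparator"],
                                value=float(nt["value"]))
    if "code_in_valueset" in node:
        cv = node["code_in_valueset"]
        vs_id = cv["valueset"]
        if vs_id not in value_sets:
            raise ConfigurationError(f"value set {vs_id!r} referenced but not loaded")
        return CodeInValueSet(table=cv["table"], valueset=value_sets[vs_id])
    raise ConfigurationError(f"unrecognised criterion node: {sorted(node)}")


def study_spec_from_yaml(path: str | Path,
                         value_sets: dict[str, ValueSet] | None = None) -> StudySpec:
    """Load a study spec; inline value sets are registered before criteria."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    value_sets = dict(value_sets or {})
    for vs in raw.get("value_sets", []):
        value_sets[vs["id"]] = ValueSet(id=vs["id"], system=vs.get("system", "unknown"),
                                        codes=set(map(str, vs["codes"])))
    cd_raw = raw["case_definition"]
    case_def = CaseDefinition(
        inclusion=_criterion_from_yaml(cd_raw["inclusion"], value_sets),
        exclusion=_criterion_from_yaml(cd_raw["exclusion"], value_sets)
        if cd_raw.get("exclusion") else None,
    )
    variables = []
    for v in raw.get("variables", []):
        crit = _criterion_from_yaml(v["criterion"], value_sets) if "criterion" in v else None
        variables.append(StudyVariable(name=v["name"], kind=v["kind"], criterion=crit,
                                       column=v.get("column"), bins=v.get("bins", [])))
    return StudySpec(case_definition=case_def, variables=variables,
                     study_period=tuple(raw["study_period"]),
                     count_unit=raw.get("count_unit", "patients"))


def hypertension_case_definition(
    systolic_threshold: float = 140.0, diastolic_threshold: float = 90.0
) -> CaseDefinition:
    """Vital-sign hypertension phenotype: systolic >= 140 OR diastolic >= 90.

    Both comparators inclusive; either arm alone qualifies the encounter.
    A medication-in-value-set exclusion can be attached by the caller.
    """
    return CaseDefinition(inclusion=AnyOf([
        NumericThreshold(code=SYSTOLIC_LOINC, comparator=">=", value=systolic_threshold),
        NumericThreshold(code=DIASTOLIC_LOINC, comparator=">=", value=diastolic_threshold),
    ]))
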