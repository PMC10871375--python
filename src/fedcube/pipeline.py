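"""End-to-end site and network orchestration.

One site's run is: read the bulk-FHIR export, extract symptom mentions from
the clinical notes (notes are consumed here and go no further), de-identify
everything, flatten to study tables, evaluate the study spec, and emit a
suppressed aggregate matrix.  The coordinating step merges site matrices
and the analytics step computes measures from the merged aggregate.  Every
run writes a manifest with per-stage row counts so reruns can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from fedcube import analytics
from fedcube.aggregate import AggregateMatrix, MatrixMetadata, cube_counts, merge, suppress
from fedcube.deid import Codebook, DeidRules, deidentify_export, load_default_rules
from fedcube.errors import FedcubeError, ResolutionError
from fedcube.fhir_io import read_export, resolve_note_text
from fedcube.library import (
    AllEncounters,
    CaseDefinition,
    CodeInValueSet,
    StudySpec,
    StudyTableSet,
    StudyVariable,
    ValueSet,
    derive_variables,
    evaluate_case,
    flatten,
)
from fedcube.nlp import SymptomDictionary, classify_mentions, load_default_cues, load_default_dictionary, mentions_to_records
from fedcube.synthetic_ehr import DISEASE_CODE

COMPILED_STAMP = "2021-03-01T00:00:00"  # fixed for byte-stable artifacts


@dataclass
class RunManifest:
    """Provenance for one pipeline invocation; enough to re-run bit-identically."""

    command: str
    inputs: dict = dc_field(default_factory=dict)
    outputs: dict = dc_field(default_factory=dict)
    counts: dict = dc_field(default_factory=dict)
    seed: int | None = None
    suppression_threshold: int | None = None
    failed_stage: str | None = None

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def run_etl(
    site_dir: str | Path,
    out_dir: str | Path,
    codebook_secret: str,
    rules: DeidRules | None = None,
    dictionary: SymptomDictionary | None = None,
) -> tuple[StudyTableSet, RunManifest]:
    """Site-local ETL: NLP on notes, de-identification, flatten to tables.

    Note text is read and discarded inside this function; only structured
    symptom records survive.  Output tables are written as CSV under
    *out_dir*/tables plus a manifest.
    """
    site_dir, out_dir = Path(site_dir), Path(out_dir)
    manifest = RunManifest(command="etl", inputs={"site_dir": str(site_dir)})
    rules = rules or load_default_rules()
    dictionary = dictionary or load_default_dictionary()
    cues = load_default_cues()
    codebook = Codebook(secret=codebook_secret)
    try:
        export = read_export(site_dir)
        if not export.of_type("Patient"):
            raise ResolutionError(f"{site_dir}: Patient.ndjson missing or empty")
        manifest.counts["read"] = {t: len(v) for t, v in export.records.items()}

        nlp_records = []
        for doc in export.of_type("DocumentReference"):
            text = resolve_note_text(doc, site_dir)
            mentions = classify_mentions(text, dictionary, cues)
            nlp_records.extend(mentions_to_records(mentions, doc))
        manifest.counts["nlp_symptom_records"] = len(nlp_records)

        records = {t: list(v) for t, v in export.records.items()}
        records["Observation"] = records.get("Observation", []) + nlp_records
        deid_records = deidentify_export(records, rules, codebook)
        manifest.counts["deidentified"] = {t: len(v) for t, v in deid_records.items()}

        tables = flatten(deid_records)
        tables.write_csv(out_dir / "tables")
        manifest.counts["tables"] = {
            "patients": len(tables.patients),
            "encounters": len(tables.encounters),
            "conditions": len(tables.conditions),
            "observations": len(tables.observations),
            "symptoms": len(tables.symptoms),
            "medications": len(tables.medications),
        }
        manifest.outputs["tables"] = str(out_dir / "tables")
    except FedcubeError:
        manifest.failed_stage = manifest.failed_stage or "etl"
        manifest.write(out_dir / "manifest.json")
        raise
    manifest.write(out_dir / "manifest.json")
    return tables, manifest


def run_study(
    tables: StudyTableSet,
    spec: StudySpec,
    site_name: str,
    threshold: int = 10,
    include_comparison: bool = True,
) -> AggregateMatrix:
    """Evaluate the study spec on one site's tables and return the
    suppressed site matrix ready to share."""
    cohort = evaluate_case(tables, spec, include_comparison=include_comparison)
    labelled = derive_variables(cohort, tables, spec)
    metadata = MatrixMetadata(sites=[site_name], study_period=spec.study_period,
                              compiled=COMPILED_STAMP,
                              variable_descriptions={v.name: v.kind for v in spec.variables})
    matrix = cube_counts(labelled, [v.name for v in spec.variables], metadata=metadata)
    return suppress(matrix, threshold)


def run_merge(matrix_paths: list[str | Path]) -> AggregateMatrix:
    return merge([AggregateMatrix.read_csv(p) for p in matrix_paths])


def surveillance_study_spec(
    count_unit: str = "patients",
    study_period: tuple[str, str] = ("2020-03", "2021-02"),
    symptom_label: str = "fever",
    symptom_code: str = "R50.9",
) -> StudySpec:
    """The default whole-population surveillance study.

    Cohort: every unit with an in-period encounter.  Variables: disease
    status from the diagnosis code, one symptom by each detection method
    (note-text NLP vs ICD coding), encounter month, age group, and sex.
    """
    disease_vs = ValueSet(id="disease", system="ICD-10-CM", codes={DISEASE_CODE})
    symptom_vs = ValueSet(id=symptom_label, system="ICD-10-CM", codes={symptom_code})
    variables = [
        StudyVariable(name="disease", kind="boolean",
                      criterion=CodeInValueSet("condition", disease_vs)),
        StudyVariable(name=f"{symptom_label}_nlp", kind="boolean",
                      criterion=CodeInValueSet("symptom", symptom_vs)),
        StudyVariable(name=f"{symptom_label}_icd", kind="boolean",
                      criterion=CodeInValueSet("condition", symptom_vs)),
        StudyVariable(name="month", kind="month"),
        StudyVariable(name="age_group", kind="binned_age", bins=[0, 18, 45, 65, 90]),
        StudyVariable(name="sex", kind="categorical", column="sex"),
    ]
    return StudySpec(
        case_definition=CaseDefinition(inclusion=AllEncounters()),
        variables=variables,
        study_period=study_period,
        count_unit=count_unit,
    )


def compute_measure(matrix: AggregateMatrix, measure: str, **kwargs) -> dict:
    """Dispatch one named measure against a matrix; returns plain values."""
    if measure == "prevalence":
        value = analytics.prevalence(matrix, kwargs["variable"], kwargs["level"])
        return {"measure": "prevalence", "value": value}
    t = analytics.crosstab(matrix, kwargs["exposure"], kwargs["outcome"])
    if measure == "or":
        r = analytics.odds_ratio(t)
        return {"measure": "odds_ratio", "value": r.estimate,
                "ci95": [r.ci_low, r.ci_high], "corrected": r.corrected}
    if measure == "rr":
        r = analytics.relative_risk(t)
        return {"measure": "relative_risk", "value": r.estimate,
                "ci95": [r.ci_low, r.ci_high], "corrected": r.corrected}
    if measure == "chi2":
        r = analytics.chi_square(t, yates=kwargs.get("yates", False))
        return {"measure": "chi_square", "value": r.estimate, "p_value": r.p_value}
    if measure == "cond_prob":
        return {"measure": "conditional_probability",
                "value": analytics.conditional_probability(
                    t, kwargs.get("direction", "outcome_given_exposure"))}
    raise FedcubeError(f"unknown measure {measure!r}")
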