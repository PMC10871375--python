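import pandas as pd
import pytest

from fedcube.deid import Codebook, deidentify_export, load_default_rules
from fedcube.errors import ConfigurationError, ValidationError
from fedcube.fhir_io import ResourceRecord
from fedcube.library import (
    AllEncounters,
    AnyOf,
    CaseDefinition,
    CodeInValueSet,
    NumericThreshold,
    StudySpec,
    StudyTableSet,
    StudyVariable,
    ValueSet,
    bin_label,
    derive_variables,
    evaluate_case,
    flatten,
    hypertension_case_definition,
)


def bp_tables(readings, month="2020-06"):
    """Tiny table set: one encounter per (systolic, diastolic) reading."""
    enc, obs, pat = [], [], []
    for i, (sys, dia) in enumerate(readings):
        pid, eid = f"P{i}", f"E{i}"
        pat.append({"patient_id": pid, "sex": "female", "birth_year": 1980})
        enc.append({"encounter_id": eid, "patient_id": pid, "month": month,
                    "enc_class": "AMB"})
        obs.append({"encounter_id": eid, "patient_id": pid, "code": "8480-6",
                    "value": float(sys), "unit": "mm[Hg]"})
        obs.append({"encounter_id": eid, "patient_id": pid, "code": "8462-4",
                    "value": float(dia), "unit": "mm[Hg]"})
    empty = pd.DataFrame(columns=["encounter_id", "patient_id", "system", "code"])
    return StudyTableSet(
        patients=pd.DataFrame(pat), encounters=pd.DataFrame(enc),
        conditions=empty.copy(), observations=pd.DataFrame(obs),
        symptoms=pd.DataFrame(columns=["encounter_id", "patient_id", "code", "month", "source"]),
        medications=empty.copy())


def hypertension_spec(count_unit="encounters"):
    return StudySpec(case_definition=hypertension_case_definition(),
                     variables=[], study_period=("2020-01", "2020-12"),
                     count_unit=count_unit)


class TestHypertensionPhenotype:
    @pytest.mark.parametrize("sys,dia,is_case", [
        (142, 85, True),    # systolic arm
        (139, 89, False),   # both strictly below threshold
        (120, 95, True),    # diastolic arm
        (140, 60, True),    # systolic boundary inclusive
        (110, 90, True),    # diastolic boundary inclusive
        (139, 60, False),
        (110, 89, False),
    ])
    def test_140_90_boundary(self, sys, dia, is_case):
        tables = bp_tables([(sys, dia)])
        cohort = evaluate_case(tables, hypertension_spec())
        assert (len(cohort) == 1) == is_case

    def test_or_combination_either_arm_qualifies(self):
        tables = bp_tables([(150, 70), (120, 95), (120, 80)])
        cohort = evaluate_case(tables, hypertension_spec())
        assert sorted(cohort["encounter_id"]) == ["E0", "E1"]


class TestFlatten:
    def test_counts_conserved_and_joins_intact(self, small_population):
        exports, _ = small_population
        deid = deidentify_export(exports[0].records, load_default_rules(),
                                 Codebook(secret="k"))
        tables = flatten(deid)
        assert len(tables.patients) == len(deid["Patient"])
        assert len(tables.encounters) == len(deid["Encounter"])
        joined = tables.encounters.merge(tables.patients, on="patient_id")
        assert len(joined) == len(tables.encounters)

    def test_observation_without_numeric_value_dropped(self):
        rec = ResourceRecord("Observation", "o1", {
            "resourceType": "Observation", "id": "o1",
            "code": {"coding": [{"code": "8480-6"}]}})
        tables = flatten({"Observation": [rec]})
        assert tables.observations.empty

    def test_nlp_tagged_observations_route_to_symptom_table(self):
        rec = ResourceRecord("Observation", "n1", {
            "resourceType": "Observation", "id": "n1",
            "meta": {"tag": [{"system": "fedcube/source", "code": "nlp"}]},
            "code": {"coding": [{"code": "R50.9"}]},
            "encounter": {"reference": "Encounter/e1"},
            "effectiveDateTime": "2020-04"})
        tables = flatten({"Observation": [rec]})
        assert tables.observations.empty
        assert tables.symptoms.iloc[0]["code"] == "R50.9"
        assert tables.symptoms.iloc[0]["source"] == "nlp"


class TestCaseEvaluation:
    def test_period_filter_excludes_out_of_period_events(self):
        tables = bp_tables([(150, 95)], month="2019-01")
        cohort = evaluate_case(tables, hypertension_spec())
        assert cohort.empty

    def test_out_of_period_perturbation_leaves_output_unchanged(self):
        base = bp_tables([(150, 95), (120, 70)])
        spec = hypertension_spec()
        before = evaluate_case(base, spec)
        # add an out-of-period hypertensive encounter for the non-case patient
        extra_enc = pd.DataFrame([{"encounter_id": "EX", "patient_id": "P1",
                                   "month": "2019-05", "enc_class": "AMB"}])
        extra_obs = pd.DataFrame([{"encounter_id": "EX", "patient_id": "P1",
                                   "code": "8480-6", "value": 190.0, "unit": "mm[Hg]"}])
        perturbed = StudyTableSet(
            patients=base.patients, encounters=pd.concat([base.encounters, extra_enc]),
            conditions=base.conditions,
            observations=pd.concat([base.observations, extra_obs]),
            symptoms=base.symptoms, medications=base.medications)
        after = evaluate_case(perturbed, spec)
        pd.testing.assert_frame_equal(before, after)

    def test_patient_level_case_if_any_encounter_qualifies(self):
        tables = bp_tables([(150, 95)])
        # same patient, second normal encounter
        tables.encounters = pd.concat([tables.encounters, pd.DataFrame(
            [{"encounter_id": "E9", "patient_id": "P0", "month": "2020-07",
              "enc_class": "AMB"}])])
        cohort = evaluate_case(tables, hypertension_spec(count_unit="patients"))
        assert list(cohort["patient_id"]) == ["P0"]

    def test_exclusion_applied_after_inclusion(self):
        vs = ValueSet(id="acei", system="RxNorm", codes={"29046"})
        tables = bp_tables([(150, 95), (160, 100)])
        tables.medications = pd.DataFrame([
            {"encounter_id": "E1", "patient_id": "P1", "system": "rx", "code": "29046"}])
        cd = CaseDefinition(inclusion=hypertension_case_definition().inclusion,
                            exclusion=CodeInValueSet("medication", vs))
        spec = StudySpec(case_definition=cd, variables=[],
                         study_period=("2020-01", "2020-12"), count_unit="encounters")
        cohort = evaluate_case(tables, spec)
        assert list(cohort["encounter_id"]) == ["E0"]

    def test_inclusion_monotone_in_valueset(self, small_network):
        """Adding codes to an inclusion value set never removes cases."""
        tables = small_network["tables"]["site1"]
        small_vs = ValueSet(id="s", system="ICD-10-CM", codes={"R50.9"})
        big_vs = ValueSet(id="b", system="ICD-10-CM", codes={"R50.9", "R05"})
        period = ("2020-03", "2021-02")

        def cases(vs):
            spec = StudySpec(
                case_definition=CaseDefinition(inclusion=CodeInValueSet("condition", vs)),
                variables=[], study_period=period, count_unit="patients")
            return set(evaluate_case(tables, spec)["patient_id"])

        assert cases(small_vs) <= cases(big_vs)


class TestVariables:
    def test_age_binning_interval_labels(self):
        assert bin_label(7, [0, 5, 12, 18, 65, 90]) == "5-11"
        assert bin_label(0, [0, 5, 12, 18, 65, 90]) == "0-4"
        assert bin_label(89, [0, 5, 12, 18, 65, 90]) == "65-89"

    def test_month_and_boolean_variable_derivation(self):
        tables = bp_tables([(150, 95), (120, 70)])
        tables.symptoms = pd.DataFrame([
            {"encounter_id": "E0", "patient_id": "P0", "code": "R50.9",
             "month": "2020-06", "source": "nlp"}])
        fever_vs = ValueSet(id="fever", system="ICD-10-CM", codes={"R50.9"})
        spec = StudySpec(
            case_definition=CaseDefinition(inclusion=AllEncounters()),
            variables=[
                StudyVariable(name="fever", kind="boolean",
                              criterion=CodeInValueSet("symptom", fever_vs)),
                StudyVariable(name="month", kind="month"),
                StudyVariable(name="age_group", kind="binned_age", bins=[0, 18, 65, 90]),
            ],
            study_period=("2020-01", "2020-12"), count_unit="encounters")
        cohort = derive_variables(evaluate_case(tables, spec), tables, spec)
        row0 = cohort[cohort["encounter_id"] == "E0"].iloc[0]
        row1 = cohort[cohort["encounter_id"] == "E1"].iloc[0]
        assert row0["fever"] == "true" and row1["fever"] == "false"
        assert row0["month"] == "2020-06"
        assert row0["age_group"] == "18-64"  # born 1980, seen 2020

    def test_bin_edges_must_increase(self):
        with pytest.raises(ConfigurationError):
            StudyVariable(name="bad", kind="binned_age", bins=[0, 5, 5])

    def test_boolean_variable_requires_criterion(self):
        with pytest.raises(ConfigurationError):
            StudyVariable(name="b", kind="boolean")


def test_valueset_from_csv(tmp_path):
    f = tmp_path / "vs.csv"
    f.write_text("system,code\nICD-10-CM,R05\nICD-10-CM,R50.9\n")
    vs = ValueSet.from_csv("symptoms", f)
    assert vs.codes == {"R05", "R50.9"}
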