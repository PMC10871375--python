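# Reviewed de-identification rule template: allow-list semantics, any field
# not named here is dropped.  References (subject, encounter, patient) are
# pseudonymized so joins survive; dates are generalized to year-month.
default_action: drop
resources:
  Patient:
    id: pseudonymize
    gender: keep
    birthDate: generalize_date_to_month
  Encounter:
    id: pseudonymize
    subject: pseudonymize
    class: keep
    period: generalize_date_to_month
  Condition:
    id: pseudonymize
    subject: pseudonymize
    encounter: pseudonymize
    code: keep
    recordedDate: generalize_date_to_month
  Observation:
    id: pseudonymize
    subject: pseudonymize
    encounter: pseudonymize
    code: keep
    meta: keep            # carries the nlp-source tag on text-derived records
    valueQuantity: keep
    valueBoolean: keep
    effectiveDateTime: generalize_date_to_month
  MedicationRequest:
    id: pseudonymize
    subject: pseudonymize
    encounter: pseudonymize
    medicationCodeableConcept: keep
    authoredOn: generalize_date_to_month
  # DocumentReference bodies never cross the site boundary; the whole
  # resource is dropped at de-identification (NLP consumes it beforehand).
  DocumentReference: {}
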