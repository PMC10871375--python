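# Symptom value set: one ICD-10-CM code per concept plus the lowercase
# surface forms the note-text matcher recognises.  Shared by the synthetic
# note generator, the NLP stage, and the study library, so note templates
# use only registered forms.
- code: R50.9
  label: fever
  system: ICD-10-CM
  surface_forms: [fever, febrile]
- code: R68.83
  label: chills
  system: ICD-10-CM
  surface_forms: [chills, rigors]
- code: R05
  label: cough
  system: ICD-10-CM
  surface_forms: [cough]
- code: R06.0
  label: dyspnea
  system: ICD-10-CM
  surface_forms: [dyspnea, shortness of breath]
- code: R51
  label: headache
  system: ICD-10-CM
  surface_forms: [headache]
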