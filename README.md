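# fedcube

Desk-scale federated analytics over electronic health record exports.

Public-health surveillance across hospital networks runs into a hard
constraint: line-level patient data cannot leave the institution. `fedcube`
implements the push-model alternative end to end, at a scale that fits on a
laptop: each simulated site ingests a bulk-FHIR NDJSON export, de-identifies
it, extracts symptoms from clinical note text, evaluates computable
phenotypes, and publishes **only a table of counts** — from which a
coordinating party can still compute prevalence, odds ratios, relative
risks, conditional probabilities and chi-square tests.

## The aggregate matrix

For an ordered set *S* of discrete study variables (disease status, symptom
flags, encounter month, age group, sex, …), a site publishes one count for
every observed level combination of every subset *T* ⊆ *S*:

> rows of the matrix ↔ assignments over the power set *P(S) = { T : T ⊆ S }*

including the empty subset, whose single row is the total cohort size. This
is the data cube over *S*: any marginal, conditional or joint frequency a
count-based measure needs can be read off (or obtained by subtraction)
without ever touching line-level data. Two protections apply:

* **Small-cell suppression** — every row with fewer than 10 patients is
  removed outright before the matrix leaves the site, and again after the
  cross-site merge. A suppressed cell is indistinguishable from an absent
  one, and the analytics layer refuses (rather than imputes) any measure
  that needs a missing cell.
* **Keyed pseudonymization** — identifiers are replaced by HMAC-SHA256
  pseudonyms under a site-held secret, so joins survive de-identification
  but no mapping table exists. Clinical note text never crosses the site
  boundary at all: the NLP stage (dictionary matching plus NegEx-style
  negation rules) converts notes to coded symptom records in place.

A seeded synthetic multi-site generator stands in for the EHR, with known
disease prevalence, per-symptom conditional probabilities, blood-pressure
distributions, and — deliberately — a higher probability that a symptom is
mentioned in the note (0.9) than that it is ICD-coded (0.5), so text-derived
surveillance visibly outperforms claims-style coding.

## Worked example

A five-site network of 2,000 synthetic patients, end to end:

```bash
export FEDCUBE_SECRET=demo-secret
printf 'n_patients: 2000\nn_sites: 5\nseed: 11\n' > cfg.yaml
fedcube generate --config cfg.yaml --out net
for i in 1 2 3 4 5; do
  fedcube etl   --site net/site$i --out etl$i
  fedcube study --etl etl$i --site-name site$i --out m$i.csv
done
fedcube merge m1.csv m2.csv m3.csv m4.csv m5.csv --out network.csv
fedcube analyze --matrix network.csv --measure prevalence \
                --variable disease --level true
```

prints

```json
{"measure": "prevalence", "value": 0.3035}
```

— the network-wide disease prevalence recovered from counts alone (the
generator's true value is 0.30; the residual is binomial sampling error).
The merged `network.csv` holds 735 suppressed cells over six variables, its
null-set row is the full cohort of 2,000, and its metadata sidecar lists
all five contributing sites. Asking for the association between disease and
NLP-detected fever,

```bash
fedcube analyze --matrix network.csv --measure or \
                --exposure disease=true --outcome fever_nlp=true
```

reports an odds ratio of 32.4 with a log-scale Wald 95% interval of
[23.5, 44.6] — a strong association, as built into the generator (fever occurs in 60% of
diseased vs 5% of healthy patients). The corresponding chi-square statistic
is 726.9 (1 df). Note what suppression costs: `--measure trend` on this
2,000-patient run reports a monthly NLP-vs-ICD detection series for only
one month and lists eleven as omitted, because per-site month × symptom
cells fall under 10 patients — exactly the privacy/accuracy trade-off the
push model accepts. At 10,000 patients the full series appears and the NLP
percentage exceeds the ICD percentage in every month.

## Layout

| module | role |
|---|---|
| `fedcube.fhir_io` | bulk-FHIR NDJSON read/write, note-text resolution |
| `fedcube.synthetic_ehr` | seeded multi-site generator with ground truth |
| `fedcube.deid` | allow-list field rules + keyed codebook pseudonyms |
| `fedcube.nlp` | dictionary symptom matcher + negation rules |
| `fedcube.library` | flat study tables, value sets, phenotype evaluation |
| `fedcube.aggregate` | power-set cube, suppression, cross-site merge |
| `fedcube.analytics` | count-based epidemiological measures |
| `fedcube.cli` / `fedcube.pipeline` | orchestration: generate → etl → study → merge → analyze |

See `docs/methods.md` for the model, parameter choices, and limitations.
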