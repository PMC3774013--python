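# va2012

The 2012 WHO verbal autopsy (VA) standard as machine-readable, validated
data, plus the computation that makes it usable:

- **`va2012.standard`** — the packaged standard: the 62-category VA cause
  list with ICD-10 certification codes and source ranges, a 221-item
  CoD-related indicator registry with its four-level skip topology
  (adult 56/37/27/10, child 34/35/22/10, neonate 44/35/15/10, plus 26
  personal / 3 respondent / 10 context items per group), the 27-entry
  2007→2012 cause subsumption map, and the structural constants every
  loader is audited against. The indicator registry is a stub
  instrument — stable ids and short symptom-domain labels satisfying
  every published count constraint — and is plain JSON data, swappable
  for the official WHO item list without code change
  (`scripts/build_indicator_registry.py` regenerates it).
- **`va2012.icd`** — ICD-10 code algebra (parse, ranges, total order) and
  precedence-resolved bidirectional mapping: most-specific rule wins,
  residual categories lose to specific ones, remaining ties break by
  table order; P95 deliberately maps ambiguously to both stillbirth
  categories; unmatched codes are reported unmapped rather than coerced
  to VA-99. `coverage_audit` scans a code universe for gaps and
  conflicts.
- **`va2012.questionnaire`** — skip-pattern logic: applicable-indicator
  fixpoint per record, record validation (answers behind closed gates,
  missing answers, maternal-block consistency), and maximal open-gate
  question counts (130 adult maternal / 104 neonate / 101 child).
- **`va2012.interpret`** — automated cause assignment: a Bayesian engine
  (positive-only or full-Bernoulli likelihood, log-space, floored
  probabilities, undetermined threshold τ) and a Tariff-style additive
  scorer with robust (median/IQR) scaling fitted from training data;
  CSMF estimation by top-cause tally or posterior averaging.
- **`va2012.metrics`** — sensitivity/specificity/PPV/NPV, Cohen's kappa,
  CSMF accuracy, per-cause and average chance-corrected concordance,
  Lin's concordance correlation, rank-based AUC. Degenerate
  denominators return `None` flags, never silent zeros.
- **`va2012.simulate`** — skip-consistent synthetic cohorts from a known
  CSMF and cause-conditional endorsement matrix (per-record seed
  substreams, sharpening-controlled separability), plus
  parameter-recovery experiments.

## CLI

```bash
va2012 standard audit                       # consistency report, exit 1 on violation
va2012 map --from-icd B22                   # -> VAs-01.03 (HIV/AIDS related death)
va2012 map --to-icd VAs-09.04 --context postpartum   # -> O72
va2012 map audit --universe A00-Y98         # unmapped codes + conflicts
va2012 validate records.csv                 # per-record skip-logic report
va2012 interpret records.csv --engine bayes --matrix m.csv --prior p.csv \
    --tau 0.0 --out assignments.csv
va2012 simulate --config sim.yaml --out cohort.csv --truth truth.csv
va2012 evaluate --truth truth.csv --assigned assignments.csv --out metrics.json
```

Record CSV dialect: columns `record_id, age_group, sex`, then one column
per indicator id with values `Y/N/DK/NA` (empty = not asked). Matrix
CSV: first column `indicator_id`, remaining columns VA cause codes.

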