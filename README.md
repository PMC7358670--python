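# vacuoquant

Quantification of lymphocyte vacuolization and lysosomal LAMP-1 accumulation
as a measure of CLN3 disease severity.

CLN3 disease (juvenile neuronal ceroid lipofuscinosis, Batten disease) is a
lysosomal storage disorder whose phenotype ranges from classical
childhood-onset neurodegeneration to an isolated retinal dystrophy, depending
on the severity of the two *CLN3* alleles.  Vacuolated blood lymphocytes are
pathognomonic for the classical disease, and the *degree* of vacuolization —
measurable on an ordinary blood smear or, via the lysosomal membrane protein
LAMP-1 (CD107a), by flow cytometry — tracks phenotypic severity.  This
package implements that quantification end to end for laboratory scientists
and biostatisticians working on lysosomal storage biomarkers:

* **Smear scoring** (`vacuoquant.smear`) — combines repeated observer counts
  (% vacuolated of 100 lymphocytes; vacuoles per cell in ≤ 20 vacuolated
  cells) into per-sample two-axis scores and per-class summaries.
* **Flow gating** (`vacuoquant.gating`) — assigns B / CD4-T / CD8-T / NK
  subsets from 1-D marker thresholds and computes, per subset, the fraction
  of *affected* cells, defined as LAMP-1⁺ perforin⁻.  The positivity gates
  are anchored on the NK population, an internal positive control that
  constitutively co-expresses LAMP-1 and perforin; LAMP-1⁺ perforin⁺ cells
  indicate cytotoxic activation and are excluded.
* **Image quantification** (`vacuoquant.imaging`) — for channel-separated
  8-bit single-cell images (imaging flow cytometry exports): whole-cell
  masks by Otsu thresholding of the surface CD4 channel, per-cell mean
  LAMP-1, sliding-threshold curves (% of cell area ≥ each level 0–255) and
  population percentile bands.
* **Severity modelling** (`vacuoquant.severity`) — a linear mixed model
  `outcome ~ age + phenotype class` with a per-patient random intercept and
  an AIC-selected random age slope, REML-estimated; plus the genotype →
  phenotype-class rule (two truncating alleles → classical; truncating +
  mild missense → delayed classical; two particularly mild missense →
  retina-only; otherwise protracted).
* **Synthetic data** (`vacuoquant.synth`) — generators for cohorts, flow
  samples and cell images with recorded ground truth, parameterized to the
  published per-class levels, so the whole pipeline is testable without
  patient data.

## Worked example

```python
from vacuoquant import synth, smear, gating, severity

cfg = synth.CohortConfig(seed=1)                  # default study-like cohort
cohort, patients = synth.generate_cohort(cfg)
scores = smear.score_cohort(cohort)
print(scores.groupby("severity_class")["pct_vacuolated"].median().round(1))

events = synth.generate_flow_sample("classical", 10000, cfg, seed=2)
gates = gating.auto_marker_gates(events)
labeled = gating.assign_subsets(events, gates)
gates = gating.derive_lamp1_gate(labeled, gates)  # NK-anchored, 5th pctile
report = gating.affected_fractions(labeled, gates, sample_id="demo")
for name, s in report.subsets.items():
    print(f"{name}: {s['pct_affected']:.1f}% affected of {s['n_events']} events")

fit = severity.fit_severity_model(scores, "pct_vacuolated")
fe = fit.fixed_effects
print(f"classical vs control: +{fe['class[classical]']['estimate']:.1f}% "
      f"(p = {fe['class[classical]']['p']:.2g})")
```

Output:

```
severity_class
carrier               3.3
classical            33.3
control               1.7
delayed_classical    16.3
protracted            7.0
retina_only           2.7
Name: pct_vacuolated, dtype: float64
B: 19.4% affected of 1446 events
T4: 51.9% affected of 4034 events
T8: 53.8% affected of 2436 events
NK: 1.0% affected of 1053 events
classical vs control: +30.9% (p = 1.3e-13)
```

Reading this: smear medians separate the severity strata (controls ~2 %,
protracted ~7 %, classical ~33 % vacuolated lymphocytes); in the classical
flow sample roughly half of T cells are LAMP-1⁺ perforin⁻ while the NK
control population is, by construction of the gate, almost entirely positive
(its "affected" rate is near zero because NK cells are also perforin-high);
and the mixed model attributes a ~31-percentage-point excess to classical
disease over controls, with no age effect.

A command-line interface wraps the same functions:

```sh
vacuoquant run-all --seed 1 --out runs/demo       # full synthetic pipeline
vacuoquant simulate cohort --seed 1 --out cohort.csv
vacuoquant smear-score --in cohort.csv --out scores.csv
vacuoquant gate --in flow.csv --nk-quantile 0.05 --out report.json
vacuoquant fit-severity --in merged.csv --outcome pct_affected_T4 --out fit.json
```

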