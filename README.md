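# metabias

A reporting-bias audit pipeline for meta-analytic literatures. It is aimed at
meta-researchers who have a corpus of published meta-analyses — for example
the exposure–outcome associations pooled across an umbrella review of
behavior- and statin-mortality systematic reviews — and want to quantify how
much of that body of evidence looks distorted by selective publication.

For each meta-analysis the pipeline:

1. **Re-pools** the primary studies with an inverse-variance random-effects
   model. Each study contributes a log effect *yᵢ* = ln(RRᵢ) and standard
   error *sᵢ* = (ln Uᵢ − ln Lᵢ)/(2·z₀.₉₇₅) back-calculated from its 95% CI.
   The between-study variance τ² is the DerSimonian–Laird moment estimator
   τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)), with Cochran's Q and I² reported
   alongside the pooled estimate Σw\*ᵢyᵢ/Σw\*ᵢ, w\*ᵢ = 1/(sᵢ² + τ²).
2. **Screens for small-study effects** with the Egger regression asymmetry
   test: OLS of the standardized effect yᵢ/sᵢ on precision 1/sᵢ; an intercept
   with two-sided *p* < 0.10 (t, k−2 df) flags the meta-analysis.
3. **Screens for excess significance**: the observed number O of primary
   studies with *p* < 0.05 is compared against the expected number
   E = Σᵢ power(sᵢ; θ\*), where θ\* is the effect of the most precise study,
   via χ² = (O−E)²/E + (O−E)²/(k−E) on 1 df; bias is flagged only when O > E
   with one-sided *p* < 0.05.
4. **Tabulates** flags per research area (physical activity, sedentary
   behavior, alcohol, smoking, diet, statin) with eligibility-aware
   denominators, and applies sensitivity filters (≥10 studies per
   meta-analysis; dropping primary studies with <200 deaths).
5. **Tallies ROBIS judgments** (low/high/unclear risk of bias per review
   domain); a packaged table carries the domain judgments of the 49
   systematic reviews of the behavior/statin mortality literatures.

A synthetic-corpus generator with a known true effect, heterogeneity, and a
file-drawer selection mechanism (nonsignificant studies published with
probability *p*₍pub₎) makes every stage testable with ground truth and lets
you estimate the operating characteristics of both bias tests.

## Worked example

```python
import math
from metabias import (SyntheticConfig, generate_corpus, run_audit, AuditConfig,
                      parse_robis_csv, robis_tabulate)
from metabias.study_data import bundled_robis_path

cfg = SyntheticConfig(theta=math.log(0.8), tau=0.15, k_published=9,
                      p_publish_nonsig=0.3, n_metas=30, seed=42)
corpus = generate_corpus(cfg)
result = run_audit(corpus, AuditConfig())
cols = ["research_area", "n_total", "n_sig", "pct_sig",
        "n_egger_flag", "pct_egger", "n_excess_flag", "pct_excess"]
print(result.area_summary[cols].to_string(index=False))

summary = robis_tabulate(parse_robis_csv(bundled_robis_path()))
print("domain 1 low:", summary.count("d1", "low"), f"({summary.percent('d1','low'):.0f}%)")
print("domain 2 high:", summary.count("d2", "high"), f"({summary.percent('d2','high'):.0f}%)")
```

prints

```
research_area  n_total  n_sig  pct_sig  n_egger_flag  pct_egger  n_excess_flag  pct_excess
         diet       30     29     97.0             2        7.0             11        37.0
      overall       30     29     97.0             2        7.0             11        37.0

domain 1 low: 32 (65%)
domain 2 high: 40 (82%)
```

Under this strong file-drawer selection (only 30% of nonsignificant results
published, true RR 0.8), 29 of the 30 simulated meta-analyses pool to a
nominally significant result and the excess-significance test flags 37% of
them, while the Egger test — less sensitive at nine studies per
meta-analysis — flags 7%. The ROBIS tallies show that 32 of the 49 audited
reviews (65%) were judged at low risk of bias on study-eligibility criteria,
but 40 (82%) at high risk on study identification and selection.

The same workflow is available from a shell:

```bash
metabias simulate --seed 42 --out sim/            # corpus.csv
metabias run --corpus sim/corpus.csv --robis src/metabias/data/robis_cvd_mortality_reviews.csv --out audit/
metabias tabulate-robis --robis src/metabias/data/robis_cvd_mortality_reviews.csv --out robis/
```

`metabias run` writes `per_meta.csv`, `area_summary.csv`, `robis_summary.csv`
and a machine-readable `run_log.json` recording the configuration and every
eligibility/exclusion decision.

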