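# discountclass

Tools for characterizing **delay-discounting response patterns** in
adjusting-amount task data, for behavioral-economics and clinical
researchers working with indifference-point series.

In a delay-discounting task a participant reports, for each of several
delays, the immediate amount judged equal in value to a fixed delayed
reward (the *indifference point*). Most people devalue delayed rewards
— their series decreases with delay — but real cohorts always contain
responders who deviate. This package implements, end to end, the two
complementary ways of characterizing such cohorts:

1. **Rule-based screening** with the Johnson–Bickel criteria. With
   undiscounted amount `A` and indifference points `v_1..v_m`:
   * *JB1 (local):* a violation when `v_j > v_{j−1} + 0.2·A` (strict);
   * *JB2 (global):* pass when `v_1 − v_m ≥ 0.1·A` (weak);

   plus the model-free **point-based AUC**, the trapezoid area under the
   series after normalizing delays to [0, 1] and values by `A`.

2. **Latent-class linear mixed models (LCMM)**: a finite mixture of
   mixed-effects lines over normalized time `t = d/120`,

       y_ij | class g = β0_g + β1_g·t_j + b_i + e_ij,
       b_i ~ N(0, σ_b²),  e_ij ~ N(0, σ²),

   fit by EM with multiple starts, swept over class counts `G`, and
   compared with the sample-size-adjusted BIC
   (`SABIC = −2ℓ + p·ln((N+2)/24)`); the lowest SABIC selects `G`.

The pipeline cross-tabulates the selected latent classes against the
criteria flags and AUC, flagging any class whose within-class pass rate
reveals a *characteristically distinct* subgroup (e.g., responders whose
value *rises* with delay).

The package also simulates the **adjusting-amount staircase** itself
(SSR starts at `A/2`, adjustment halves after each of five choices, so
indifference points live on the grid `{A·j/64 : j odd}`) and generates
**synthetic cohorts** with planted class structure for validation —
including a default 1 198-subject cohort shaped like the large
public-repository discounting datasets ($200 and $40 000 tasks, delays
of 1, 6, 12, 36, 60 and 120 months).

## Worked example

```python
from discountclass import hcp_like_recipe, PipelineConfig, run_pipeline

recipe = hcp_like_recipe(200, seed=1)   # 1198 subjects, planted classes
result = run_pipeline(recipe, PipelineConfig(seed=1), out_dir="run")
print(result.screen_summary.to_string(index=False))
print(open("run/summary.txt").read())
```

prints

```
              criterion  count  percentage
 Systematic Local (JB1)   1073       89.57
Systematic Global (JB2)   1096       91.49
        Both Systematic    983       82.05
N participants: 1198
Selected number of latent classes (lowest SABIC): 4
Mean maximum posterior: 0.9660
Class 4 flagged as characteristically distinct (n=59, both-criteria pass rate 5.1% < 50%)
```

Reading this: 89.6% of the simulated cohort passes the local criterion,
91.5% the global one, 82.1% both. The class-count sweep picks a
four-class solution; classes are numbered by fitted slope (ascending),
so class 4 — the highest-slope class — collects the planted rising
responders plus flat ones, and only 5.1% of its members pass both
criteria, which trips the distinct-subgroup flag. The `run/` directory
holds the criteria summary, the G-sweep table (log-likelihood, AIC, BIC,
SABIC, class percentages), the class-by-criteria and AUC-by-class
tables, per-participant posteriors, and a JSON run manifest.

The same flow is available from the shell:

```sh
discountclass simulate --magnitude 200 --n-subjects 1198 --seed 1 --out cohort.csv
discountclass screen   --input cohort.csv --magnitude 200 --out screened.csv
discountclass fit      --input cohort.csv --magnitude 200 --classes 1:8 --seed 1 --out fits/
discountclass pipeline --input cohort.csv --magnitude 200 --seed 1 --out run/
```

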