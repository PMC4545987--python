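# raschkit

Rasch-model psychometric evaluation of ordinal patient-reported-outcome
questionnaires — calibration, fit diagnostics, dimensionality, targeting,
ceiling/floor, Wright maps and differential item functioning — built for
instruments like the St. George's Respiratory Questionnaire (SGRQ) that
mix dichotomous and polytomous items across several domains.

## Who this is for

Researchers validating or revising multi-domain health questionnaires who
want the standard Rasch evidence chain (the one produced by Winsteps-style
software) as a scriptable, testable Python library: does each domain
behave as a single dimension, do the items fit, how well do item
difficulties cover the patients' range, which categories malfunction, and
do items measure equivalently across age or disease-severity subgroups.

## The model

Responses follow the mixed rating-scale / partial-credit Rasch model.
For person $n$ and item $i$ with $m_i$ ordered categories,

$$
P(X_{ni}=k)=\frac{\exp\sum_{j\le k}(\theta_n-\delta_i-\tau_{gj})}
{\sum_h \exp\sum_{j\le h}(\theta_n-\delta_i-\tau_{gj})},
$$

where $\theta_n$ is the person measure, $\delta_i$ the item difficulty and
$\tau_{gj}$ the step thresholds shared by all items of response-format
group $g$ (a single-item group is the partial-credit case; a dichotomous
item reduces to the 1-PL logistic model).  Estimation is joint maximum
likelihood with items mean-centred per domain; persons and items land on
one logit metric, which is what makes targeting, gaps, ceiling/floor and
Wright maps meaningful.  Details, conventions and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic SGRQ-like dataset (48 items in Symptom / Activity /
Impact domains, N = 240, known truth), calibrate one domain, and screen
for severity-related DIF:

```python
import raschkit as rk

spec = rk.sgrq_like_spec()
matrix, truth = rk.generate(rk.GenerationConfig(spec=spec), seed=1)

result = rk.RaschModel(matrix, spec, domain="Symptom").fit()
print(result.summary())
```

```
Rasch calibration (Symptom)
===========================
persons: 227 calibrated, 13 extreme; items: 6 calibrated, 0 extreme
converged: True in 14 iterations (max change 0.00365 logits)
person reliability (separation): 0.87 (2.53)

item          difficulty      SE   infit  class
S_a1               -1.15    0.10    0.98  fit
S_a2               -0.51    0.09    0.95  fit
S_a3               -0.13    0.09    1.07  fit
S_a4                0.20    0.09    1.05  fit
S_a5                0.71    0.10    0.92  fit
S_a7                0.89    0.10    1.03  fit
thresholds[sym_attack]: -1.56, 0.03, 1.52
thresholds[sym_days]: -1.32, -0.15, 1.46
thresholds[sym_freq]: -1.95, -0.59, 0.62, 1.93
```

Reading this: the six Symptom items are ordered on the logit scale from
the most commonly endorsed (S_a1, −1.15) to the least (S_a7, +0.89), all
with infit mean squares inside the 0.6–1.4 band; person reliability 0.87
corresponds to a separation index of 2.53 (the instrument distinguishes
about two to three strata of respondents); 13 of 240 persons hit a
floor/ceiling raw score and carry extrapolated measures.

```python
ev = result.evaluate()
print(f"targeting {ev.targeting_index:.2f} ({ev.targeting_band}); "
      f"coverage {ev.coverage_pct:.2f}%")
print(f"ceiling {ev.ceiling_pct:.2f}%  floor {ev.floor_pct:.2f}%")

a, b, names = rk.split_groups(matrix, "severity_stage")
tab = rk.dif_contrast(matrix, spec, (a, b), domain="Symptom",
                      pooled=result, grouping="severity_stage",
                      group_names=names)
print(rk.dif_summary(tab).to_string())
```

```
targeting 0.70 (slight mis-targeting); coverage 80.83%
ceiling 17.50%  floor 1.67%
         n_flagged  n_testable  display
domain
Symptom          0           6  0 (0 %)
```

The sample sits 0.70 logits above the item centre (slight mis-targeting),
the item thresholds cover 80.83 % of respondents (below the 95 %
criterion), the ceiling effect (17.50 %) exceeds the 15 % flag, and no
Symptom item shows a severity DIF contrast beyond 0.5 logits.
`result.wright_map()` renders the joint item–person map; threshold labels
like `S_a1.2` mark where adjacent categories are equally probable.

The same pipeline runs from the shell:

```bash
raschkit simulate --out-dir data --n 240 --seed 1
raschkit report data/responses.csv data/instrument.yaml --out-dir report
raschkit dif data/responses.csv data/instrument.yaml \
    --domain Activity --grouping age_75
```

`report/report.txt` contains, per domain, the calibration table ordered
by difficulty, reliability/separation, residual-PCA eigenvalues and
local-dependence pairs, targeting/range/coverage/gap/ceiling-floor
statistics, DIF tables for both built-in groupings and the Wright map —
with every decision criterion echoed from the configuration.

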