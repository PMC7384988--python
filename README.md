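# magee-triage

Scoring engine and triage rule for deciding when an ER+/HER2-negative
early-stage breast cancer can safely forgo Oncotype DX® recurrence-score
testing, together with the validation machinery used to evaluate such a
rule on a cohort.

The package is aimed at breast pathologists, biostatisticians and health
systems evaluating decision rules built on routine pathology data: it
computes the Magee Equation™ scores, applies the Magee Decision
Algorithm™, and reproduces a full validation analysis — concordance and
accuracy tables, clinicopathologic group comparisons, distant-recurrence-
free-survival curves for discordant cases, and an avoided-test cost
estimate — on either a user-supplied case table or a calibrated synthetic
cohort.

## The model

The Magee Equations are published linear models that estimate the 21-gene
assay recurrence score (RS, 0–100) from routine pathology variables. With
Nottingham score $N$, tumor size $s$ (cm), ER and PR H-scores $E, P$
(0–300), Ki-67 labeling index $K$ (%) and a HER2-category offset
$h_{\mathrm{eq}}$:

$$\mathrm{ME1} = 15.314 + 1.406\,N - 0.0192\,E - 0.0293\,P + 0.787\,s + 0.133\,K + h_1$$
$$\mathrm{ME2} = 18.804 + 2.341\,N - 0.0375\,E - 0.0307\,P + 0.043\,s + h_2$$
$$\mathrm{ME3} = 24.308 - 0.0218\,E - 0.0288\,P + 0.186\,K + h_3$$

(full-precision coefficients ship in
`src/magee_triage/data/coefficients.yaml`). Scores are clamped at 0 and
reported to one decimal.

The decision algorithm bands each score (L: <18, M: 18–25, S: >25 to <31,
H: ≥31, on the reported one-decimal values) and labels the case:

* **do not send — expect low** (RS expected ≤25): all scores <18, or all
  ≤25 with mitotic activity score 1;
* **do not send — expect high** (RS expected >25): all scores ≥31;
* **send**: any score in the 25–31 window, or a mid-band score with
  mitosis >1.

Single-equation and average-score variants of the rule are provided for
sensitivity comparison.

## Worked example

A 2.0 cm grade II tumor (Nottingham score 6, mitosis score 1), ER H-score
300, PR H-score 0, HER2-negative, Ki-67 15%:

```python
from magee_triage import PathologyInput, compute_magee_scores, triage

case = PathologyInput(tumor_size=2.0, nottingham_score=6, mitosis_score=1,
                      er_h_score=300, pr_h_score=0, her2_status="negative",
                      ki67_index=15)
scores = compute_magee_scores(case)
print(scores.me1, scores.me2, scores.me3)   # 21.5 21.7 20.6
result = triage(scores, mitosis_score=1)
print(result.label.value)                   # do_not_send_expect_low
```

All three scores fall in the 18–25 band and the mitosis score is 1, so the
algorithm expects an actual recurrence score of 25 or less and testing can
be forgone.

The same analysis runs end-to-end on a synthetic cohort from the command
line:

```bash
magee-triage report --simulate --n 2196 --seed 0 --output report.json
```

In the resulting report the seeded default cohort triages 72.6% of cases
as do-not-send with an overall do-not-send accuracy of 95.2%, and the cost
block estimates ~$290,528 avoided per 100 test requests at $4,000 per
assay — i.e. roughly 70% of routine test requests could be skipped at
~95% accuracy, the operating point the rule is designed around. Other
subcommands: `score`, `triage`, `validate`, `survival`, `simulate`.

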