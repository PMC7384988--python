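# Default Magee Equation coefficient set (2013 revision of the published
# linear models).  Each score is
#     intercept + sum(coefficient * variable) + her2 offset,
# on the Oncotype recurrence-score scale.  ME2 omits Ki-67; ME3 uses only
# the four biomarker variables (no size, no Nottingham score).
# The HER2 offset for a negative tumor is 0 by construction.
me1:
  intercept: 15.31385
  nottingham_score: 1.4055
  er_h_score: -0.01924
  pr_h_score: -0.02925
  tumor_size: 0.78677
  ki67_index: 0.13269
  her2:
    negative: 0.0
    equivocal: 0.77681
    positive: 11.58134
me2:
  intercept: 18.8042
  nottingham_score: 2.34123
  er_h_score: -0.03749
  pr_h_score: -0.03065
  tumor_size: 0.04267
  her2:
    negative: 0.0
    equivocal: 1.82921
    positive: 11.51378
me3:
  intercept: 24.30812
  er_h_score: -0.02177
  pr_h_score: -0.02884
  ki67_index: 0.18649
  her2:
    negative: 0.0
    equivocal: 1.46495
    positive: 12.34498
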