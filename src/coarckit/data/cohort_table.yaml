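# Published three-group summary of the coarctation cohort (n = 95):
# per-group (mean, sem) for the clinical and CT-morphometric variables,
# categorical counts, and the printed test-statistic column.
# The +/- column is the standard error of the mean (SEM); within-group
# SD = sem * sqrt(n).
groups:
  gothic:
    n: 27
    variables:
      age_months: {mean: 14.3444, sem: 5.64625}
      weight_kg: {mean: 6.996, sem: 0.9809}
      pspg_mmhg: {mean: 38.585, sem: 3.5754}
      D1_AOA: {mean: 0.6304, sem: 0.02607}
      D2_AOA: {mean: 0.5344, sem: 0.02710}
      D3_AOA: {mean: 0.2896, sem: 0.02266}
      D4_AOA: {mean: 0.7098, sem: 0.02982}
      D5_AOA: {mean: 0.6414, sem: 0.02788}
      AAO_DAO: {mean: 26.74, sem: 1.578}
      TAO_DAO: {mean: 109.81, sem: 1.716}
      A_T: {mean: 0.70148, sem: 0.014898}
    counts:
      male: 12
      pda: 19
  crenel:
    n: 25
    variables:
      age_months: {mean: 5.0307, sem: 1.93247}
      weight_kg: {mean: 4.808, sem: 0.5305}
      pspg_mmhg: {mean: 43.076, sem: 3.4719}
      D1_AOA: {mean: 0.6923, sem: 0.03201}
      D2_AOA: {mean: 0.5614, sem: 0.02282}
      D3_AOA: {mean: 0.3078, sem: 0.02511}
      D4_AOA: {mean: 0.8404, sem: 0.04272}
      D5_AOA: {mean: 0.7731, sem: 0.04082}
      AAO_DAO: {mean: 34.56, sem: 1.791}
      TAO_DAO: {mean: 112.40, sem: 2.106}
      A_T: {mean: 0.49028, sem: 0.013728}
    counts:
      male: 17
      pda: 18
  romanesque:
    n: 43
    variables:
      age_months: {mean: 6.7548, sem: 1.78188}
      weight_kg: {mean: 5.451, sem: 0.4003}
      pspg_mmhg: {mean: 38.557, sem: 2.4324}
      D1_AOA: {mean: 0.6646, sem: 0.02213}
      D2_AOA: {mean: 0.5634, sem: 0.02092}
      D3_AOA: {mean: 0.3764, sem: 0.01492}
      D4_AOA: {mean: 0.7729, sem: 0.02893}
      D5_AOA: {mean: 0.7292, sem: 0.02083}
      AAO_DAO: {mean: 31.88, sem: 0.941}
      TAO_DAO: {mean: 108.57, sem: 0.936}
      A_T: {mean: 0.58212, sem: 0.012791}
    counts:
      male: 25
      pda: 35

# printed chi2/t statistic column (reference only); rows whose printed value
# does not reproduce under summary-statistics one-way ANOVA are marked
printed_statistics:
  age_months: {value: 2.096, reproduces: false}
  weight_kg: {value: 2.754, reproduces: true}
  pspg_mmhg: {value: 0.742, reproduces: false}
  pda: {value: 0.670, reproduces: false}
  D1_AOA: {value: 1.168, reproduces: true}
  D2_AOA: {value: 0.440, reproduces: true}
  D3_AOA: {value: 3.692, reproduces: false}
  D4_AOA: {value: 3.155, reproduces: true}
  D5_AOA: {value: 4.725, reproduces: true}
  AAO_DAO: {value: 7.321, reproduces: true}
  TAO_DAO: {value: 1.724, reproduces: false}
  A_T: {value: 47.107, reproduces: false}
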