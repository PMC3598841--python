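# Classical-phenotype synthetic preset: the base preset without the
# attenuated (atypical) cases, i.e. uniformly faster disease progression.
metadata: {preset: classical, description: 'classical-phenotype progression (attenuated cases excluded):
    faster entry into and out of the symptomatic stage'}
transitions:
  asymptomatic->acroparesthesia:
    male: {p: 0.08625, lcl: 0.057787, ucl: 0.114712}
    female: {p: 0.07475, lcl: 0.050082, ucl: 0.099417}
  asymptomatic->symptoms:
    male: {p: 0.023, lcl: 0.01541, ucl: 0.03059}
    female: {p: 0.01725, lcl: 0.011557, ucl: 0.022942}
  acroparesthesia->symptoms:
    male: {p: 0.264, lcl: 0.17688, ucl: 0.35112}
    female: {p: 0.216, lcl: 0.14472, ucl: 0.28728}
  symptoms->esrd:
    male: {p: 0.0042, lcl: 0.002814, ucl: 0.005586}
    female: {p: 0.0021, lcl: 0.001407, ucl: 0.002793}
  symptoms->cardiac:
    male: {p: 0.0077, lcl: 0.005159, ucl: 0.010241}
    female: {p: 0.0056, lcl: 0.003752, ucl: 0.007448}
  symptoms->cva:
    male: {p: 0.0035, lcl: 0.002345, ucl: 0.004655}
    female: {p: 0.0028, lcl: 0.001876, ucl: 0.003724}
  esrd->symptoms:
    male: {p: 0.05, lcl: 0.0335, ucl: 0.0665}
    female: {p: 0.05, lcl: 0.0335, ucl: 0.0665}
  esrd->esrd_cardiac:
    male: {p: 0.075, lcl: 0.05025, ucl: 0.09975}
    female: {p: 0.06, lcl: 0.0402, ucl: 0.0798}
  esrd->esrd_cva:
    male: {p: 0.045, lcl: 0.03015, ucl: 0.05985}
    female: {p: 0.0375, lcl: 0.025125, ucl: 0.049875}
  cardiac->esrd_cardiac:
    male: {p: 0.0525, lcl: 0.035175, ucl: 0.069825}
    female: {p: 0.045, lcl: 0.03015, ucl: 0.05985}
  cardiac->cardiac_cva:
    male: {p: 0.0675, lcl: 0.045225, ucl: 0.089775}
    female: {p: 0.06, lcl: 0.0402, ucl: 0.0798}
  cva->esrd_cva:
    male: {p: 0.045, lcl: 0.03015, ucl: 0.05985}
    female: {p: 0.0375, lcl: 0.025125, ucl: 0.049875}
  cva->cardiac_cva:
    male: {p: 0.075, lcl: 0.05025, ucl: 0.09975}
    female: {p: 0.0675, lcl: 0.045225, ucl: 0.089775}
  esrd_cardiac->esrd_cardiac_cva:
    male: {p: 0.1, lcl: 0.067, ucl: 0.133}
    female: {p: 0.09, lcl: 0.0603, ucl: 0.1197}
  esrd_cva->esrd_cardiac_cva:
    male: {p: 0.1, lcl: 0.067, ucl: 0.133}
    female: {p: 0.09, lcl: 0.0603, ucl: 0.1197}
  cardiac_cva->esrd_cardiac_cva:
    male: {p: 0.1, lcl: 0.067, ucl: 0.133}
    female: {p: 0.09, lcl: 0.0603, ucl: 0.1197}
  death:
    any:
      male: {p: 0.0, lcl: 0.0, ucl: 0.0}
      female: {p: 0.0, lcl: 0.0, ucl: 0.0}
    symptoms:
      male: {p: 0.002, lcl: 0.00134, ucl: 0.00266}
      female: {p: 0.002, lcl: 0.00134, ucl: 0.00266}
    esrd:
      male: {p: 0.05, lcl: 0.0335, ucl: 0.0665}
      female: {p: 0.045, lcl: 0.03015, ucl: 0.05985}
    cardiac:
      male: {p: 0.03, lcl: 0.0201, ucl: 0.0399}
      female: {p: 0.025, lcl: 0.01675, ucl: 0.03325}
    cva:
      male: {p: 0.04, lcl: 0.0268, ucl: 0.0532}
      female: {p: 0.035, lcl: 0.02345, ucl: 0.04655}
    esrd_cardiac:
      male: {p: 0.09, lcl: 0.0603, ucl: 0.1197}
      female: {p: 0.08, lcl: 0.0536, ucl: 0.1064}
    esrd_cva:
      male: {p: 0.1, lcl: 0.067, ucl: 0.133}
      female: {p: 0.09, lcl: 0.0603, ucl: 0.1197}
    cardiac_cva:
      male: {p: 0.09, lcl: 0.0603, ucl: 0.1197}
      female: {p: 0.08, lcl: 0.0536, ucl: 0.1064}
    esrd_cardiac_cva:
      male: {p: 0.18, lcl: 0.1206, ucl: 0.2394}
      female: {p: 0.16, lcl: 0.1072, ucl: 0.2128}
utilities:
  asymptomatic: {mean: 0.874, lcl: 0.804, ucl: 0.934}
  acro_or_symptoms: {mean: 0.762, lcl: 0.699, ucl: 0.822}
  single_complication: {mean: 0.744, lcl: 0.658, ucl: 0.821}
  multiple_complications: {mean: 0.584, lcl: 0.378, ucl: 0.79}
costs:
  ert_per_year: 200000
  unit_cost_hour: 30
  state: {asymptomatic: 600, acro_or_symptoms: 3200, single_complication: 8000, multiple_complications: 18000}
  state_overrides: {esrd: 55000, esrd_cardiac: 60000, esrd_cva: 60000, esrd_cardiac_cva: 64000}
  production_loss: {asymptomatic: 500, acro_or_symptoms: 4000, single_complication: 8000, multiple_complications: 12000}
treatment_effect:
  or_first: {value: 0.82, lcl: 0.68, ucl: 0.96}
  or_second: {value: 0.52, lcl: 0.31, ucl: 0.88}
  median_duration_symptoms: 1.0
  median_duration_single_complication: 1.0
discounting: {effects: 0.015, costs: 0.04, mode: none}
simulation: {horizon: 70, cycle_length: 1, sex_mix: 0.5, ert_start_rule: at-symptoms, wtp_min: 20000,
  wtp_max: 10000000, wtp_points: 25}
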