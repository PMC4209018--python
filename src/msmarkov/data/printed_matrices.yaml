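# Annual transition probabilities (%) between the 7 metabolic states,
# as printed in the source study's tables, one matrix per sex x age stratum.
# Row/column order: no_component, iso_overweight, iso_hypertension,
# iso_dyslipidemia, iso_hyperglycemia, two_component, ms.
# Rows sum to 100.00 up to printed rounding; they are renormalized on load.
men_18-40:
  sex: M
  age_group: "18-40"
  source: study table 2
  matrix_percent:
    - [72.07, 9.48, 4.55, 7.68, 0.58, 4.55, 1.09]
    - [13.51, 52.25, 1.03, 3.35, 0.51, 24.07, 5.28]
    - [0.0, 0.0, 61.21, 0.0, 0.0, 26.67, 12.12]
    - [23.21, 3.27, 1.79, 42.86, 0.30, 22.32, 6.25]
    - [0.0, 0.0, 0.0, 0.0, 48.57, 31.43, 20.00]
    - [3.33, 9.07, 9.44, 2.50, 0.83, 54.17, 20.65]
    - [0.0, 0.0, 3.78, 0.0, 0.0, 23.92, 72.30]
women_18-40:
  sex: F
  age_group: "18-40"
  source: study table 3
  matrix_percent:
    - [86.38, 3.71, 2.15, 3.76, 0.80, 2.30, 0.90]
    - [37.81, 44.27, 0.50, 4.98, 0.50, 9.45, 2.49]
    - [0.0, 0.0, 83.82, 0.0, 0.0, 13.24, 2.94]
    - [47.57, 5.83, 2.91, 25.24, 0.97, 10.68, 6.80]
    - [0.0, 0.0, 0.0, 0.0, 88.64, 9.09, 2.27]
    - [7.69, 6.51, 20.71, 2.37, 3.55, 46.74, 12.43]
    - [0.0, 0.0, 25.00, 0.0, 0.0, 42.31, 32.69]
men_40-49:
  sex: M
  age_group: "40-49"
  source: study table 4
  matrix_percent:
    - [68.15, 8.30, 4.26, 10.54, 1.57, 5.72, 1.46]
    - [13.17, 52.23, 0.0, 3.13, 0.22, 25.45, 5.80]
    - [0.0, 0.0, 64.71, 0.0, 0.0, 27.01, 8.29]
    - [24.82, 4.61, 3.19, 37.59, 1.06, 23.05, 5.67]
    - [0.0, 0.0, 0.0, 0.0, 56.90, 31.03, 12.07]
    - [1.28, 4.81, 8.49, 3.13, 1.44, 57.69, 23.16]
    - [0.0, 0.0, 2.60, 0.0, 0.21, 22.56, 74.64]
women_40-49:
  sex: F
  age_group: "40-49"
  source: study table 5
  matrix_percent:
    - [82.05, 5.45, 3.70, 4.61, 0.84, 2.65, 0.70]
    - [27.50, 54.16, 1.25, 4.17, 0.42, 11.25, 1.25]
    - [0.0, 0.0, 86.80, 0.0, 0.0, 11.46, 1.74]
    - [38.25, 3.48, 3.48, 42.61, 0.0, 9.57, 2.61]
    - [0.0, 0.0, 0.0, 0.0, 73.81, 19.05, 7.14]
    - [3.16, 3.95, 21.34, 3.16, 3.95, 49.02, 15.42]
    - [0.0, 0.0, 4.88, 0.0, 2.44, 36.59, 56.09]
men_50-59:
  sex: M
  age_group: "50-59"
  source: study table 6
  matrix_percent:
    - [62.71, 9.90, 5.94, 7.92, 3.96, 7.59, 1.98]
    - [18.62, 46.28, 2.66, 4.79, 0.53, 20.21, 6.91]
    - [0.0, 0.0, 66.40, 0.0, 0.0, 29.25, 4.35]
    - [22.97, 1.35, 1.35, 36.49, 2.70, 29.73, 5.41]
    - [0.0, 0.0, 0.0, 0.0, 53.57, 30.36, 16.07]
    - [0.53, 2.79, 7.85, 1.60, 1.33, 60.24, 25.66]
    - [0.0, 0.0, 2.13, 0.0, 0.15, 21.46, 76.26]
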