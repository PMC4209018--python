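# SYNTHETIC stand-in transition matrices for the three strata whose study
# tables appear only in an unavailable supplement (women 50-59, men >=60,
# women >=60).  These are NOT study estimates: each is constructed from the
# printed matrices of adjacent strata (a blend, plus one extra cycle of
# progression for the >=60 groups) so that the full 8-stratum pipeline can
# run end to end.  Same row/column order as printed_matrices.yaml.
women_50-59:
  sex: F
  age_group: "50-59"
  source: synthetic stand-in (blend of printed women 40-49 and men 50-59)
  matrix_percent:
    - [72.38, 7.68, 4.82, 6.26, 2.40, 5.12, 1.34]
    - [23.06, 50.22, 1.96, 4.48, 0.48, 15.73, 4.08]
    - [0.00, 0.00, 76.60, 0.00, 0.00, 20.36, 3.04]
    - [30.61, 2.41, 2.41, 39.55, 1.35, 19.65, 4.01]
    - [0.00, 0.00, 0.00, 0.00, 63.69, 24.70, 11.60]
    - [1.85, 3.37, 14.60, 2.38, 2.64, 54.63, 20.54]
    - [0.00, 0.00, 3.50, 0.00, 1.30, 29.02, 66.18]
men_60+:
  sex: M
  age_group: "60+"
  source: synthetic stand-in (printed men 50-59 advanced one extra cycle)
  matrix_percent:
    - [54.84, 10.38, 7.03, 8.13, 4.37, 11.37, 3.87]
    - [19.77, 37.32, 3.96, 5.18, 0.99, 22.84, 9.94]
    - [0.06, 0.33, 58.43, 0.19, 0.16, 32.74, 8.09]
    - [23.06, 2.50, 2.91, 28.16, 3.12, 31.10, 9.15]
    - [0.06, 0.34, 1.09, 0.19, 43.79, 33.42, 21.10]
    - [0.93, 2.89, 8.96, 1.65, 1.45, 54.37, 29.74]
    - [0.05, 0.24, 3.17, 0.14, 0.28, 24.86, 71.27]
women_60+:
  sex: F
  age_group: "60+"
  source: synthetic stand-in (stand-in women 50-59 advanced one extra cycle)
  matrix_percent:
    - [65.90, 8.50, 6.20, 6.75, 2.86, 7.43, 2.36]
    - [25.81, 41.18, 3.63, 5.02, 0.93, 17.54, 5.88]
    - [0.15, 0.27, 70.66, 0.19, 0.23, 23.25, 5.24]
    - [32.44, 3.52, 4.38, 30.98, 1.89, 20.77, 6.01]
    - [0.18, 0.33, 1.60, 0.24, 54.76, 27.86, 15.02]
    - [2.65, 3.52, 16.79, 2.43, 2.98, 48.99, 22.65]
    - [0.21, 0.39, 5.80, 0.28, 1.76, 31.85, 59.71]
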