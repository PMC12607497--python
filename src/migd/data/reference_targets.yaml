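# Published cohort summaries used to calibrate the synthetic-cohort generator
# and to drive group-level (median-based) index computations.
#
# toxin_summaries: median, Q1, Q3 in umol analyte per mmol creatinine,
# per (group x Bristol-stool category) stratum.  Control strata by stool
# category are not published; the generator falls back to the all-control
# values for every control stratum.
#
# demographics: stratum size, number of boys, and age model
# (mean, SD, min, max in years).
version: 1
analyte_units: umol_per_mmol_creatinine
analytes: [ADMA, SDMA, TMAO, IS, PCS]

toxin_summaries:
  control:
    ADMA: [12.70, 9.73, 18.74]
    SDMA: [31.32, 23.01, 38.09]
    TMAO: [3.09, 1.48, 5.19]
    IS:   [63.80, 39.77, 103.18]
    PCS:  [37.74, 20.02, 80.02]
  asd_all:
    ADMA: [14.76, 10.50, 17.03]
    SDMA: [29.06, 20.10, 39.77]
    TMAO: [2.64, 1.64, 5.01]
    IS:   [56.77, 28.22, 89.25]
    PCS:  [51.84, 17.07, 86.81]
  asd_hard:
    ADMA: [14.79, 10.69, 16.95]
    SDMA: [29.09, 20.17, 36.91]
    TMAO: [2.38, 1.69, 3.52]
    IS:   [52.26, 41.88, 79.10]
    PCS:  [46.65, 29.01, 86.73]
  asd_loose:
    ADMA: [8.02, 7.57, 15.15]
    SDMA: [19.73, 14.64, 50.79]
    TMAO: [2.60, 0.04, 3.81]
    IS:   [89.25, 23.98, 108.77]
    PCS:  [31.85, 9.09, 140.45]
  asd_normal:
    ADMA: [15.09, 11.32, 19.54]
    SDMA: [29.08, 23.16, 44.29]
    TMAO: [3.19, 1.67, 5.53]
    IS:   [61.52, 27.95, 89.20]
    PCS:  [52.65, 15.80, 84.76]

demographics:
  control:    {n: 71, boys: 37, age_mean: 8.93, age_sd: 3.82, age_min: 2.40, age_max: 16.70}
  asd_all:    {n: 97, boys: 76, age_mean: 9.44, age_sd: 3.77, age_min: 2.50, age_max: 17.00}
  asd_hard:   {n: 28, boys: 17, age_mean: 9.76, age_sd: 4.21, age_min: 3.50, age_max: 17.00}
  asd_loose:  {n: 8,  boys: 5,  age_mean: 9.88, age_sd: 3.15, age_min: 4.60, age_max: 13.20}
  asd_normal: {n: 61, boys: 54, age_mean: 9.24, age_sd: 3.68, age_min: 2.50, age_max: 16.70}

# Published group-level component ratios for the control row; the underlying
# control BSC 3-5 toxin medians are not printed, so only the ratio -> index
# step is reproducible for controls.
published_group_ratios:
  control: {pcs_tmao: 12.4, is_adma: 5.2}
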