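# A-priori candidate model sets for the breeding-response analyses.
#
# Terms are columns of the season covariate table:
#   mean_tfc / se_tfc      dry-season mean / SE of individual abundance
#   mean_fi  / se_fi       dry-season mean / SE of the foraging index
#   mean_ratio / se_ratio  dry-season mean / SE of the flocking ratio
#   <mon>_tfc, <mon>_fi    monthly means of abundance and FI
#   <mon>_delta            monthly mean day-over-day change in abundance
#
# Effort sets draw on the early dry season (January-March) and carry a
# Decade random intercept; success sets draw on the late dry season
# (February-April) and are fixed-effects only. 27 models per set.

effort:
  random_intercept: decade
  models:
    - []
    - [mean_tfc]
    - [mean_fi]
    - [mean_ratio]
    - [se_tfc]
    - [se_fi]
    - [se_ratio]
    - [jan_delta]
    - [feb_delta]
    - [mar_delta]
    - [jan_tfc]
    - [feb_tfc]
    - [mar_tfc]
    - [jan_fi]
    - [feb_fi]
    - [mar_fi]
    - [mean_tfc, mar_delta]
    - [mar_tfc, mar_delta]
    - [mean_fi, mar_delta]
    - [se_ratio, mar_delta]
    - [se_ratio, mar_delta, se_fi]
    - [se_ratio, mar_tfc, se_fi]
    - [se_ratio, se_fi]
    - [mean_tfc, feb_delta]
    - [mar_fi, feb_fi]
    - [mean_tfc, mean_ratio]
    - [mar_fi, mar_delta]

success:
  random_intercept: null
  models:
    - []
    - [mean_tfc]
    - [mean_fi]
    - [mean_ratio]
    - [se_tfc]
    - [se_fi]
    - [se_ratio]
    - [feb_delta]
    - [mar_delta]
    - [apr_delta]
    - [feb_tfc]
    - [mar_tfc]
    - [apr_tfc]
    - [feb_fi]
    - [mar_fi]
    - [apr_fi]
    - [apr_tfc, mar_delta]
    - [se_ratio, apr_tfc]
    - [se_ratio, apr_tfc, se_fi]
    - [se_ratio, mean_tfc, se_fi]
    - [se_ratio, se_fi]
    - [apr_fi, mar_delta]
    - [mean_fi, apr_tfc]
    - [apr_tfc, apr_fi]
    - [mar_delta, apr_delta]
    - [se_ratio, mar_tfc]
    - [apr_fi, mar_fi]
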