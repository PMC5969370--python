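# Civilian-trauma-audit-like cohort preset.
#
# Emulates the national civilian trauma-audit population: Priority One
# prevalence 19.5% (published study characteristics: 24 791 P1 of 127 233
# cases).  Physiology parameters fitted once as for the military-like preset
# (least squares against the analytic enumeration); the MPTT's analytic
# operating point under this
# model — 57.9% / 69.8% — sits within 5 percentage points of the published
# 57.8% / 71.5%.  Software oracles, not registry replications.
#
# Analytic operating points of this preset (sens, spec):
#   rr22 0.472/0.766  rr24 0.364/0.881  mptt 0.579/0.698
#   mptt24 0.560/0.812  uk_military_sieve 0.270/0.972
p1_prevalence: 0.195
p1:
  rr_mean: 21.0
  rr_sd: 7.2
  hr_mean: 80.0
  hr_sd: 12.0
  alert_prob: 0.90
  cathaem_prob: 0.13
  apnoea_prob: 0.08
  walking_prob: 0.0
not_p1:
  rr_mean: 18.3
  rr_sd: 4.4
  hr_mean: 70.0
  hr_sd: 8.0
  alert_prob: 0.99
  cathaem_prob: 0.0
  apnoea_prob: 0.0
  walking_prob: 0.0
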