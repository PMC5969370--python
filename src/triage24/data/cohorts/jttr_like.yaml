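# Military-registry-like cohort preset.
#
# Emulates the deployed military trauma-registry population used to evaluate
# the triage tools: Priority One prevalence 47.6% (published study
# characteristics: 1738 P1 of 3654 cases).  The registry publishes no
# physiology distributions, so the per-class parameters below were FITTED once
# by least squares against the analytic operating points, so that the MPTT's
# analytic sensitivity/specificity under this model
# — 70.1% / 63.9% — sits within 5 percentage points of the published
# 69.9% / 65.3%, under clinically plausible bounds.  These are software
# oracles, not registry replications.
#
# Analytic operating points of this preset (sens, spec):
#   rr22 0.462/0.716  rr24 0.388/0.836  mptt 0.701/0.639
#   mptt24 0.685/0.758  uk_military_sieve 0.426/0.956
p1_prevalence: 0.476
p1:                     # casualties who received >= 1 life-saving intervention
  rr_mean: 20.5         # breaths/min, discretised normal
  rr_sd: 10.5
  hr_mean: 80.0         # beats/min
  hr_sd: 12.0
  alert_prob: 0.90      # P(AVPU = Alert), equivalently P(GCS >= 14)
  cathaem_prob: 0.13    # catastrophic external haemorrhage (blast/GSW cohort)
  apnoea_prob: 0.01     # not breathing after airway opened
  walking_prob: 0.0     # non-ambulant registry assumption
not_p1:
  rr_mean: 18.7
  rr_sd: 4.9
  hr_mean: 70.0
  hr_sd: 8.0
  alert_prob: 0.99
  cathaem_prob: 0.0
  apnoea_prob: 0.0
  walking_prob: 0.0
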