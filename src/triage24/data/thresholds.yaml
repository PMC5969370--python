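# Tool threshold configuration.  Thresholds are data, not code: each block maps
# directly onto TriageTreeClassifier hyper-parameters, and each entry carries
# the provenance of the boundary convention.
mptt:
  rr_low: 12                    # P1 if RR < 12 (tool derivation study)
  rr_high: 22                   # P1 if RR >= 22 (published operating-point row "RR>=22")
  rr_high_inclusive: true
  hr_high: 100                  # P1 if HR >= 100 (tool derivation study)
  hr_high_inclusive: true
  conscious_rule: gcs_lt_14     # P1 if GCS < 14
  use_catastrophic_haemorrhage: false
mptt24:
  rr_low: 12
  rr_high: 24                   # raised upper threshold: P1 if RR >= 24 (15-s count x 4)
  rr_high_inclusive: true
  hr_high: 100
  hr_high_inclusive: true
  conscious_rule: not_alert     # AVPU replaces GCS: P1 unless Alert
  use_catastrophic_haemorrhage: true
uk_military_sieve:
  rr_low: 10                    # doctrine band: RR 10-29 inclusive passes
  rr_high: 29                   # P1 if RR > 29 (strict; band is inclusive)
  rr_high_inclusive: false
  hr_high: 120                  # P1 if HR > 120 (strict, per doctrine transcription;
  hr_high_inclusive: false      #   capillary-refill alternative omitted — HR was evaluated)
  conscious_rule: none
  use_catastrophic_haemorrhage: true
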