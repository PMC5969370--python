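# triage24

Primary major-incident triage tools — the Modified Physiological Triage Tool
(MPTT), its faster MPTT-24 variant, and the UK Military Sieve — together with
the diagnostic-accuracy machinery used to compare them against the
life-saving-intervention (LSI) definition of a Priority One casualty.

## The problem

In a mass-casualty incident, primary triage sorts casualties at the scene into
priority categories (P1/P2/P3/DEAD) using only rapid physiological checks:
can the casualty walk, do they breathe once the airway is opened, respiratory
rate (RR), heart rate (HR) and conscious level. A tool is judged by how well
its "P1" call predicts the true need for a life-saving intervention:

* **sensitivity** — fraction of genuine P1 casualties called P1
  (its complement is **undertriage** = 1 − sensitivity);
* **specificity**, and **PPV** via the Bayes identity
  PPV = sens·prev / (sens·prev + (1−spec)(1−prev))
  (its complement is **overtriage** = 1 − PPV);
* the prevalence-free **diagnostic odds ratio**
  DOR = [sens/(1−sens)]·[spec/(1−spec)] = (TP·TN)/(FP·FN).

Ground truth is auditably simple: a casualty is Priority One iff they received
at least one intervention from a consensus-derived LSI vocabulary (shipped as
an editable YAML registry).

## The tools

All three are fixed decision trees over a casualty record, short-circuiting at
the first decisive step
(haemorrhage → walking → airway/breathing → consciousness → RR → HR):

| step | MPTT | MPTT-24 | UK Military Sieve |
|---|---|---|---|
| catastrophic external haemorrhage → P1 | — | yes | yes |
| can walk → P3 | yes | yes | yes |
| not breathing after airway opened → DEAD | yes | yes | yes |
| conscious level → P1 | GCS < 14 | not Alert (AVPU) | — |
| respiratory rate → P1 | < 12 or ≥ 22 | < 12 or ≥ 24 | < 10 or > 29 |
| heart rate → P1 | ≥ 100 | ≥ 100 | > 120 |

The MPTT-24's raised RR threshold (≥ 24) lets a provider count breaths for
15 s and multiply by four, and its AVPU conscious-level check (instead of GCS)
needs no scoring — the alert / responds-to-voice division corresponds to
GCS < 14.

Tools are scikit-learn-style classifiers (`MPTTClassifier`,
`MPTT24Classifier`, `MilitarySieveClassifier`, plus the bare-threshold
`RespiratoryRateClassifier`); all thresholds are hyper-parameters of the
generic `TriageTreeClassifier`, so a tool is configuration, not code.

## Worked example

```python
from triage24 import (CasualtyRecord, classify_mptt, classify_mptt24,
                      load_preset, generate, report)

rec = CasualtyRecord(id="c1", can_walk=False, catastrophic_haemorrhage=False,
                     breathing_after_airway_opened=True,
                     rr_bpm=23, hr_bpm=88, avpu="A")
print(classify_mptt(rec).value, classify_mptt24(rec).value)
# P1 P2   <- RR 23 triggers the MPTT (>=22) but not the MPTT-24 (>=24)

params = load_preset("jttr-like", n=20_000, seed=1)   # military-registry-like
records, truth = generate(params)
table, pvals = report(records, truth, ["mptt", "mptt24", "uk_military_sieve"])
print(table[["sensitivity", "specificity", "ppv"]].round(3))
```

prints

```
                   sensitivity  specificity    ppv
tool
mptt                     0.697        0.645  0.644
mptt24                   0.680        0.760  0.724
uk_military_sieve        0.419        0.954  0.893
```

— on this synthetic military-like cohort (Priority One prevalence 47.6%) the
MPTT-24 trades ~2 points of sensitivity against the MPTT for a sizeable
specificity gain, and both identify far more genuine P1 casualties than the
Sieve (higher sensitivity, at the cost of more overtriage).
`pvals` holds the pairwise McNemar p-values for those trade-offs.

The same pipeline is available from a shell:

```sh
triage24 simulate --preset jttr-like --n 10000 --seed 7 --out cohort.csv
triage24 classify --tool mptt24 --in cohort.csv --out categories.csv --assume-non-ambulant
triage24 evaluate --in cohort.csv --tools mptt,mptt24,uk_military_sieve --out table.csv
triage24 compare  --preset tarn-like --n 10000 --seed 7 --out-dir run/
```

## Layout

* `triage24.records` — casualty records, LSI registry and P1 ground truth,
  GCS/AVPU bridge, RR count arithmetic
* `triage24.tools` — the triage-tree classifiers and cohort classification
* `triage24.metrics` — confusion tables, Wilson/Woolf intervals, DOR/PPV
  identities, under/overtriage, McNemar, the per-tool report
* `triage24.simulate` — registry-like synthetic cohorts with exactly
  enumerable operating points (`jttr-like`, `tarn-like` presets)
* `triage24.io` / `triage24.cli` — CSV/YAML I/O and the `triage24` command

See `docs/methods.md` for the model, its assumptions and its limitations.
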