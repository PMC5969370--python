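# Methods

## Ground truth: the Priority One casualty

A casualty is **Priority One (P1)** iff they received at least one
life-saving intervention (LSI) from a configured vocabulary. The packaged
default vocabulary (`triage24/data/lsi_registry.yaml`) is a reconstruction of
the published consensus-derived list (airway, breathing and haemorrhage-control
interventions, transfusion, emergency surgery, ACLS); it is deliberately
editable because trauma registries encode interventions under local coding
schemes. Matching is by exact code string, which keeps the ground-truth
pathway auditable: change the file, not the code. The synthetic generator
injects a sentinel code (`lsi_sentinel`) into generated true-P1 records so
that even simulated evaluations flow through the intervention-set
intersection rather than bypassing it.

## The decision trees

All tools share one tree shape, short-circuiting at the first decisive step:
catastrophic haemorrhage → walking → airway/breathing → conscious level →
respiratory rate → heart rate. The step order matters only where an early
exit (P3 for walkers, DEAD for apnoeic casualties) would otherwise mask a
later P1 trigger; the catastrophic-haemorrhage step deliberately precedes the
walking step, so a walking casualty with controlled-but-catastrophic bleeding
is still P1 under the MPTT-24 and the Sieve.

Boundary conventions, fixed as data in `triage24/data/thresholds.yaml`:

* MPTT family: lower RR bound is strict (`RR < 12`), upper bound inclusive
  (`RR >= 22` for the MPTT, `RR >= 24` for the MPTT-24), HR inclusive
  (`HR >= 100`).
* UK Military Sieve: the doctrinal band "RR 10–29" passes inclusively, so P1
  requires `RR < 10` or `RR > 29`; the pulse check is strict (`HR > 120`).
  The capillary-refill alternative to the pulse check is not implemented:
  the registry evaluations used heart rate.

### Conscious level and the GCS/AVPU bridge

The MPTT's conscious-level check is `GCS < 14`; the MPTT-24 replaces it with
"not Alert" on the AVPU scale, using the empirical correspondence that the
alert / responds-to-voice division sits at a median GCS of 13 (so Alert
⇔ GCS ≥ 14). Records may carry either or both fields. When both are present
and inconsistent with that equivalence, AVPU wins and a data-quality warning
is emitted — the MPTT-24 is defined on AVPU, GCS is the legacy input. Each
conscious rule prefers its native field and falls back to the other through
the binary bridge only; no V/P/U sub-level is ever invented from a GCS.

### Missing data

A field is consulted only if the tree actually reaches its step. When a
needed field is absent, the policy decides:

* `exclude` (default): the record is excluded from evaluation and counted,
  mirroring registry analyses restricted to records with usable first-recorded
  hospital physiology;
* `treat-missing-as-normal`: the missing predicate resolves to its
  non-triggering side (breathing, alert, RR in band, HR below threshold, no
  catastrophic haemorrhage);
* `treat-missing-as-abnormal`: it resolves to the P1-triggering side.

Missing ambulation never routes a casualty to P3 under either lenient policy;
evaluation additionally supports `assume_non_ambulant` (default in `report`
and the `compare` command), which forces `can_walk = False` for every record —
the standing assumption when emulating hospital trauma-registry populations
whose inclusion criteria preclude walking wounded.

## Diagnostic accuracy

Predictions are collapsed to binary (P1 vs P2/P3/DEAD) and cross-tabulated
against LSI truth. Point estimates: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN); undertriage = 1 − sensitivity;
overtriage = 1 − PPV; number-needed-to-assess = 1/Δsensitivity (genuine P1
casualties assessed per additional missed casualty when switching tools).

Interval methods are not dictated by the quantities themselves, so the
package makes and labels its own choices: **Wilson score** for proportions
(well-behaved near 0 and 1, unlike Wald) and the **Woolf log method** for the
diagnostic odds ratio. Rate-only identities are provided for working from
published operating points without cell counts:
DOR = [sens/(1−sens)]·[spec/(1−spec)] and
PPV = sens·prev/(sens·prev + (1−spec)(1−prev)); on any complete 2×2 table
these coincide with the count-based definitions (property-tested).

**McNemar's test** compares two tools on the same records, pairing
correct/incorrect calls (correct = binary collapse matches LSI truth). With
b + c ≥ 25 discordant pairs the χ² statistic (b−c)²/(b+c) on 1 df is used,
uncorrected by default — at registry scale the continuity correction is
immaterial; below 25 the exact two-sided binomial is used. The continuity
correction is available as a flag, and the test suite checks the corrected χ²
against the exact binomial (agreement within 0.02 across moderate
discordance) — the uncorrected statistic is anti-conservative at small b + c,
which is precisely why the implementation switches to the exact test there.

Degenerate margins (e.g. specificity of an all-P1 cohort) raise an
`UndefinedMetricError` rather than returning a silent NaN; the per-tool DOR
column in `report` is the one exception, shown as NaN when a cell is zero so
one degenerate tool does not abort a multi-tool table.

## Synthetic cohorts

The generative model per casualty: true P1 status ~ Bernoulli(prevalence);
given the class, RR and HR are independent discretised normals (normal
rounded to the nearest integer, negative mass collected at 0 — clinical
measurements are integers and the tools' thresholds have exact integer
semantics), and alertness, catastrophic haemorrhage, apnoea and ambulation
are independent Bernoullis. Generated conscious level is emitted as a
consistent (AVPU, GCS) pair. Per-field missingness is optional and off by
default. All randomness flows from one seed; identical parameters reproduce
identical cohorts.

Because every field is discrete, each tool's sensitivity and specificity
under the model are exactly computable by summation
(`analytic_operating_point`), giving an oracle independent of the sampling
path: Monte-Carlo evaluation on generated cohorts must converge to it (tested
within 3 SE at n = 10⁵, a size chosen to keep the binomial standard error
near 0.002 while the whole suite runs in seconds).

Two presets emulate the published evaluation populations' coarse structure:
`jttr-like` (military: P1 prevalence 47.6%) and `tarn-like` (civilian: 19.5%).
The registries publish no physiology distributions, so the per-class
parameters were fitted once, by least squares against the analytic operating
points under clinically plausible bounds, such that the MPTT's analytic
operating point lies within 5 percentage points of the published registry
values (achieved: 70.1%/63.9% vs 69.9%/65.3% military-like; 57.9%/69.8% vs
57.8%/71.5% civilian-like); the fitted values are frozen in the preset YAMLs.
The presets are software oracles, not registry replications.

What the simulator does **not** model — and what passing tests therefore do
not show about real data: correlation between RR, HR and conscious level
given class (real shocked casualties are jointly tachypnoeic, tachycardic and
obtunded; class-conditional independence understates that clustering),
mechanism of injury, injury severity, age structure, mortality, and
informative missingness. Agreement between the pipeline and the analytic
oracle validates the software, not any clinical claim.

## Numerical and design notes

* RR/HR discretisation support runs to mean + 10 SD; truncation error is
  below 10⁻²³ and irrelevant at the thresholds.
* The discretised-normal point-mass limit (SD → 0) is exercised in tests with
  SD = 10⁻⁶; SD = 0 is rejected.
* Ratios are reported at full precision; display rounding (percentages to
  0.1, ratios to 0.01) happens only at the output layer.
* The tools are stateless rule classifiers; `fit` validates hyper-parameters
  and exists for scikit-learn composability (`get_params`/`set_params`,
  pipelines), not learning.
* Record order never affects `report` (property-tested), and the `compare`
  command's manifest (config hash, seed, version) makes any run exactly
  reproducible.

## Known limitations

* Exact-code LSI matching pushes all registry-vocabulary mapping onto
  configuration; there is no fuzzy or hierarchical code matching.
* The GCS→AVPU bridge is binary by construction; analyses needing V/P/U
  granularity from GCS records are out of scope.
* No secondary triage, paediatric tools, or civilian ambulance-service sieve
  variants; the tools target adult primary triage only.
* Synthetic operating points for tools other than the MPTT track the
  published values only loosely (within ~7 percentage points); the presets
  were calibrated on the MPTT alone.
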