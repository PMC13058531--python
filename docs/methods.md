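# Methods

This note documents the models, conventions and design decisions behind
`sepsiseval`, in the order data flows through the package.

## Sepsis-3 onset labeling

Suspicion of infection (SI) is inferred from antibiotic exposure alone
(microbiology-free EHR setting): a *course* is a maximal run of doses with
inter-dose gaps ≤ 24 h and a first-to-last span ≥ 72 h ("at least 3 days" is
read as a strict span of ≥ 72 h); the SI time is the course start. Each course
spawns one SI window [SI − 48 h, SI + 24 h], clipped at admission. Onset is
the earliest time, across windows, at which a SOFA value exceeds the window's
reference by ≥ 2 points.

The SOFA reference is not pinned down by the consensus definition. The default
is the **running minimum** of the SOFA values observed earlier within the same
window — the least restrictive common reading — with `baseline="window_first"`
available as the stricter alternative. Antibiotic events are pooled over all
drugs (any-antibiotic union); whether a course must be a single agent is
unspecified in routine EHR data and a per-drug analysis can be obtained by
filtering the event stream before labeling.

Eligibility filters: ICU admission origin, age ≥ 18 y, onset not strictly
before 4 h (an onset at exactly 4.0 h is retained), measurement span ≥ 6 h,
no inter-measurement gap ≥ 12 h (gaps are evaluated on the union of all
time-varying measurements, between consecutive measurements within the 7-day
window), and truncation of every stay at 168 h. An onset beyond the truncation
demotes the stay to a control rather than excluding it, which is why the
filter returns updated labels alongside the reports.

## Preprocessing

Bin convention: 0-based, left-closed — bin *t* covers [t, t+1) hours since
admission; a score "at bin t" may use data through bin t inclusive. Values
outside the supplied per-feature plausibility ranges are removed (bounds
inclusive); survivors are aggregated per hour by the median (even counts →
midpoint); missing bins are forward-filled within the stay, with a per-channel
fallback mean for leading gaps; binary missingness indicators (one per
time-varying and static channel, 52 for the default 48 + 4 layout) record the
observed mask. Temporal features are trailing-window statistics (min, max,
mean, median, variance) over the last 4, 8 and 16 h, truncated at the stay
start, giving c·(1 + 5·3) + 4 columns — 772 for 48 channels. Variance uses the
population convention (ddof 0), so single-value windows give exactly 0. The
logistic baseline is an L2-penalized regression with class weights inversely
proportional to class frequencies, fitted in 5-fold cross-validation split at
the stay level; scores are emitted only for held-out stays. Fallback means are
caller-supplied (in practice they come from a training cohort; the package does
not presume which one).

## Evaluation strategies

All strategies consume the same per-stay trajectories and differ only in
labeling and selection. Cases carry `onset_bin = floor(t_onset)`; the
prediction at the onset bin itself is excluded everywhere (explicitly defined
for continuous evaluation and extended to peak score for consistency).

* *Fixed horizon*: one record per stay at bin `onset_bin − h`; stays with
  `onset_bin < h` are excluded and counted.
* *Peak score*: max over bins [0, onset_bin), or [onset_bin − h, onset_bin)
  for the horizon variant (same exclusion rule as fixed horizon).
* *Continuous*: records for all bins [0, onset_bin); case bins within h of
  onset are positive; per-record weight 1/n_i, so total weight = stay count.
  The horizon labels, it never excludes stays.

Onset matching draws, for each control, uniformly **with replacement** among
cases whose onset does not exceed the control's data end ("does not exceed"
read as ≤ last_bin + 1). With-replacement matching cannot fail when controls
outnumber cases; controls with no eligible case fall back to their data end
and are flagged rather than dropped (exclusion would silently change
prevalence). Prevalence harmonization removes controls uniformly at random to
hit the target stay-level prevalence (cases are never removed; a cohort
already above the target is an error) and happens before onset assignment and
before any horizon filtering, so all strategies see the same patient set.

A consequence worth knowing: when control stays are *not* much longer than
case onsets, the matching eligibility constraint truncates the upper tail of
the matched window lengths, so matched peak-score samples are not exactly
exchangeable even for label-independent scores — matched "null" AUROC sits
slightly above 0.5. Null calibration checks therefore use unmatched arms with
control length-of-stay distributed as the case onsets, where exchangeability
is exact by construction.

## Metrics

The alarm rule is strictly `score > threshold` everywhere. AUROC is computed
in the weighted tied-rank form (ties credited 1/2), which matches the
brute-force pairwise probability to machine precision and is invariant to
prevalence reweighting. The PR curve is the weighted step-wise curve over the
achievable operating points; AUPRC is its step-wise area (equal to weighted
average precision), and linear interpolation is used only for
precision-at-recall queries. Lifted variants divide PPV and AUPRC by the
sample prevalence (≈ 1 for an uninformative model, so they remain comparable
when the horizon shifts the positive fraction); `recall_at_2prev` scans
achievable operating points for the maximum recall with precision ≥ 2 ×
prevalence and returns 0 with a flag when no point qualifies, since a
threshold where precision *equals* twice the prevalence need not exist.

Calibration: the weighted Brier score, plus 5-fold cross-validated isotonic
regression split at the stay level; the monotone map leaves rankings (hence
AUROC) unchanged up to ties. Decision curves use
NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t) with treat-all/treat-none references on a
default grid 0.01–0.50 in steps of 0.01 (the grid is a reporting choice, not a
model property). The operating threshold for alerting is the largest threshold
whose weighted sensitivity reaches the target (default 80%), returned as the
largest qualifying score nudged just below itself so that score still fires.
Alarm rates are alarms per pre-onset patient-hour per group; the 4-hour
silencing rule suppresses bins t+1..t+4 after an unsilenced alarm at t, and
suppressed alarms do not extend the suppression. Whether post-onset hours
should enter the denominator is a reporting decision; the default restricts to
pre-onset hours, matching the bins the strategies evaluate.

## Inference

The resampling unit is the ICU stay (no patient-level clustering: readmissions
are not modeled). Matching and harmonization are frozen before bootstrapping —
replicates resample the observed assignments rather than redrawing the design,
so the reported uncertainty is conditional on the realized design, which is
the quantity the percentile CI of a single published analysis refers to.
Because all builders are deterministic per stay, resampled samples are
materialized by gathering the observed records by stay (vectorized), which is
identical to rebuilding and keeps 200-cohort × 200-replicate studies in
seconds. The paired Wald test feeds one shared stay resample to both arms per
replicate; z = Δ_observed / SD(Δ_replicates) with the observed (not
bootstrap-mean) difference in the numerator — the conventional Wald form.
Two-sided p-values come from the standard normal; families of related
contrasts (the three pairwise strategy comparisons per condition; the single
matching contrast per strategy) are Holm-adjusted.

## Synthetic cohort generator

The generator defines the study conditions for all self-contained experiments.
Score level: stays are Bernoulli(prevalence = 0.10) cases; control
length-of-stay is log-normal (median 24 h, σ = 0.8) and case onset times
log-normal (median 30 h, σ = 0.7), truncated to [5, 168] h and [6, 168] h
respectively, which reproduces the ordering seen in large ICU cohorts (septic
stays longer than controls) without claiming any specific cohort's values.
The latent case risk is `baseline + signal_gain · max(0, 1 − (t_onset −
t)/signal_lead) + AR(1)` (defaults: baseline −1 logit, gain 2, lead 12 h,
noise ρ = 0.7, σ = 0.5), squashed by a sigmoid; controls omit the ramp and can
receive a pre-discharge decline (`discharge_recovery`) over the final
`signal_lead` hours. Scores are correlated with risk but deliberately not
calibrated — calibration is tested separately. Case trajectories end at the
onset bin because every strategy discards post-onset predictions.

Raw EHR level: cases get an antibiotic course (doses every 8–20 h spanning
72–120 h) starting 0–24 h before a planted onset, and a SOFA step of 2–4
points exactly at the onset, with the pre-onset SOFA held at its baseline so
the planted step is always the first qualifying rise; onsets are capped at
90 h so a full 3-day course fits inside the 7-day window. Controls receive
short (< 3-day) antibiotic courses and SOFA steps outside any SI window at
configurable rates (defaults 0.25/0.25) to exercise labeler specificity —
these confuser rates are free parameters of the simulation, not estimates of
real exposure patterns. Measurements are per-feature Poisson streams (vitals
at least hourly, labs ≈ every 4 h) from a 48-feature panel with Gaussian
in-range values clipped inside the plausibility bounds, and a configurable
fraction (default 1%) replaced by values strictly outside the bounds, with
exact bookkeeping so the plausibility filter's recovery can be asserted.

What the generator does **not** emulate: real marginal feature distributions,
demographic structure, correlated organ-system dynamics behind SOFA,
treatment feedback (antibiotics responding to deterioration), readmissions, or
informative missingness. Passing tests therefore demonstrate correctness of
the evaluation machinery and the direction/mechanism of the design biases —
not clinical performance on real data, which additionally depends on domain
shift, label noise and documentation practice.

## Numerical and reproducibility choices

Seeds: a single master seed derives every component seed via
`SeedSequence([seed, crc32(label)])`, keeping components independently
reproducible and all derived seeds below 2^31. The same config + seed is
bit-identical; the experiment runner's CSV outputs are byte-stable across
runs. Degenerate inputs fail loudly: single-class samples raise an
undefined-metric error (and bootstrap replicates hitting them are dropped,
erroring if > 5% of replicates fail), unsorted event times are contract
violations, and configuration errors name the offending field.

Default problem sizes for the self-contained studies (chosen so the whole
suite stays interactive): 500-stay cohorts for labeler recovery, 2000 stays ×
20 seeds for the length-of-stay bias (balanced groups, so the null AUROC's
binomial SE ≈ 0.013 resolves the ±0.03 band), and 200 null cohorts of 300
stays with B = 200 for type-I calibration.
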