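# Methods

## The assay and its endpoints

A spheroid control probability (SCP) experiment follows individual tumour
spheroids after treatment (hyperthermia at 42.5–46.5 °C for 30–60 min,
immediately followed by a single X-ray dose of 0–25 Gy) by imaging each
spheroid every 2–3 days for up to 60 days.  Two endpoints are computed from
the volume trajectories:

* **Growth delay** (non-curative): the time for a spheroid to reach five
  times its pre-treatment volume V₀, divided by the mean time of the
  untreated control population.
* **Control** (curative): a spheroid that never resumes growth within the
  observation window is controlled; the controlled fraction per arm is the
  SCP, and the dose–response of SCP over the radiation dose ladder yields
  the SCD50.

## Relapse rule

Regrowth is operationalised as the first run of `min_consecutive = 3`
consecutive measurement-to-measurement volume increases, each exceeding the
previous measurement by a relative factor > `1 + rel_tol` (`rel_tol = 0` by
default: any increase counts).  The event is dated at the run's first
measurement — the earliest evidence of regrowth — configurable to the run's
last point.  Spheroids without a qualifying run are controlled and censored
at their last observation; trajectories too short to evidence regrowth are
classified controlled with a warning, as are disintegrated spheroids whose
series end early.

The phrase "enlarged over three consecutive time points" admits a second
reading — three *measurements* forming two increases — available via
`rule="points"`.  The default (three increases, i.e. four measurements) is
the stricter reading and the one under which the synthetic ground truth is
recovered exactly in the noise-free limit.

With independent multiplicative measurement noise, a controlled spheroid
sitting at its residual volume plateau performs a random walk in measured
volume, and chance runs of three increases occur; with the default 5%
diameter CV this misclassifies a fraction of controlled spheroids when
`rel_tol = 0`.  For noisy data, `rel_tol` of roughly twice the volume noise
CV suppresses these runs; validation of label recovery is therefore done
noise-free, which is also what isolates the classifier's logic from the
noise model.

## Growth-delay computation

The time to k·V₀ (k = 5) is found by ordinary least squares of ln V on t
over the `window` measurements bracketing the first crossing; `window = 2`
(the default) is exact log-linear interpolation between the bracketing
pair, and wider windows (3–4) average over noise.  If a wide noisy window
produces a non-increasing fit, the bracketing pair is used.  The statistic
is scale-free (depends only on V/V₀) and equivariant under time shifts.
Spheroids never reaching the threshold are excluded from the ratio set and
reported as a censored count.  Population comparisons use the two-sided
Mann–Whitney U test: exact null distribution when n·m ≤ 400 without ties,
otherwise the normal approximation with midranks, tie and continuity
corrections (scipy backend).

## Survival layer

Kaplan–Meier product-limit estimation and the one-degree-of-freedom
log-rank test are delegated to lifelines, with relapse as the event and end
of observation as censoring; degenerate inputs (no events anywhere) return
χ² = 0, p = 1 with a warning rather than NaN.  Tests validate both against
an independent hand-rolled product-limit computation and a 5000-permutation
oracle.

## Dose–response model and fitting

SCP(D) = 1/(1 + e^(−a−bD)) is fitted to per-arm controlled/total counts by
binomial maximum likelihood (hand-written Newton–Raphson with step damping;
convergence at step < 1e-10, max 100 iterations, started from the empirical
logit regression).  SCD50 = −a/b holds exactly for every fit and replicate.

SCP data invite (quasi-)complete separation — the 0 Gy arm is typically all
relapse and the top dose all controlled.  Divergence (non-convergence or
|coefficient| > 50) triggers an automatic refit with the Firth-adjusted
score U*(β) = Xᵀ(y − mπ + h(½ − π)), where h are the leverages of the
weighted hat matrix; the result is flagged `method="firth"`.  A
least-squares-on-proportions mode exists for comparison only.

**Bootstrap.**  Confidence intervals are percentile 2.5/97.5 intervals over
`n_boot = 4000` replicates (the assay's published protocol size).  The
resampling unit is the spheroid, within each dose arm, preserving arm
sizes; since per-spheroid outcomes are Bernoulli flags, this is realised as
a binomial draw of each arm's controlled count — the identical
distribution, vectorised.  Replicates that fail to converge or fit b ≤ 0
are dropped and counted; more than 10% failures raises a warning that the
pipeline escalates into its report.

**TER.**  TER = SCD50(reference)/SCD50(condition).  Its CI is the
percentile interval of ratios of index-paired replicates from the two
independent bootstraps, and the significance of a SCD50 difference is the
two-sided bootstrap p-value 2·min(P(Δ ≤ 0), P(Δ ≥ 0)), which is 1 for
identical fits and 0 when the bootstrap distributions are disjoint (i.e.
below the resolution 1/n_boot).  TER values are reported to one decimal and
SCD50 to 0.1 Gy; full precision is kept internally, and ratios of *rounded*
SCD50s can differ from a TER computed on unrounded fits in the last decimal
for large enhancement factors.

## Synthetic data generator

The generator emulates the study conditions: 400 µm initial diameter,
eleven dose arms 0–25 Gy in 2.5 Gy steps, five thermal conditions, 56
spheroids per arm, a 2/3-day alternating imaging schedule to day 60.  Each
spheroid is assigned *controlled* ~ Bernoulli(SCP(D)) with the arm's
effective parameters; hyperthermia enters as an additive intercept shift
(a left shift of the dose–response).  Defaults: a = −5.55, b = 0.5/Gy
(true RT SCD50 11.1 Gy) with shifts 1.2, 1.9, 1.8, 3.95 for 42.5 °C/30 min,
42.5 °C/60 min, 44.5 °C/30 min, 46.5 °C/30 min — reproducing a published
FaDu-like SCD50 ladder (8.7, 7.3, 7.5, 3.2 Gy).

Volume kinetics are phenomenological, not mechanistic:

* untreated growth is Gompertz, V(t) = V_max·exp(ln(V/V_max)·e^(−αt)),
  with carrying capacity `v_max_fold = 50`×V₀ and α set through the
  early-phase doubling time (3 d), which puts the untreated time to 5×V₀
  at ≈ 9.0 d;
* treated spheroids shrink exponentially (rate 0.08/d) toward a residual
  plateau at 30% of V₀ — controlled spheroids stay there, so the relapse
  rule, not disappearance, is the operative classifier;
* non-controlled spheroids regrow Gompertz-wise from their nadir after a
  lag of 1.2 d/Gy, a linear stand-in for the dose-dependent recovery delay
  seen in such assays;
* measurement noise is multiplicative lognormal on the *diameter*
  (σ = √ln(1+CV²), median-preserving; volume noise is the cube), default
  CV 5%; the baseline V₀ measurement is noisy like any other.

No kinetic constants are published for the assay this emulates, so the
growth defaults are plausibility choices, fixed once.  The generator does
not model cellular mechanism, image formation, plate geometry, feeding
artifacts, or inter-experiment batch effects; passing tests demonstrate
the pipeline's correctness on data of this structure, not the biology of
any particular cell line.

Reproducibility: a single root seed spawns one PCG64 substream per
spheroid keyed by (arm index, spheroid index), so regenerating or
resampling one arm never perturbs another, and identical designs produce
byte-identical CSVs.

## Validation sizes

The test suite and `scripts/acceptance.py` run the stochastic checks at
the study's own design size of 11 dose arms × 56 spheroids: parameter
recovery over 100 replications per true SCD50 ∈ {3.5, 8.0, 11.1, 16.5} Gy
(median absolute error < 0.5 Gy), bootstrap CI coverage over 200
replications at n_boot = 500 (95% ± 4%), grid-oracle equivalence on 20
small datasets, and significance detection over 10 seeds at n_boot = 4000.

## Known limitations

* The percentile bootstrap is first-order accurate; at 56 spheroids/arm
  its coverage sits near 93–95% rather than exactly 95%.
* The log-rank p-value is asymptotic; for very small arms the permutation
  test (used as a test oracle) is preferable.
* Growth-delay censoring (spheroids never reaching 5×V₀) is reported, not
  modelled; heavily controlled arms therefore summarise only the regrowing
  subpopulation.
* The simulator draws control labels directly from the logistic model, so
  dose–response fits on synthetic data validate estimation, not the
  biological adequacy of the logistic form.
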