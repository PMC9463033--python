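# Methods

## The sequential model

Each attempt by a trainee is treated as a Bernoulli trial with an
unobserved failure probability. Competency monitoring is cast as
Wald's sequential probability ratio test between a *competent*
hypothesis H₀: failure rate = p₀ and a *not competent* hypothesis
H₁: failure rate = p₁ > p₀, with design error rates α (declare
unacceptable when H₀ is true) and β (declare competent when H₁ is
true). Writing S_n for the cumulative failure count after n attempts,
the log-likelihood ratio is

    LLR_n = S_n·P − (n − S_n)·Q,   P = ln(p₁/p₀),  Q = ln[(1−p₀)/(1−p₁)],

and the Wald continuation region ln[β/(1−α)] < LLR_n < ln[(1−β)/α]
solved for S_n gives two parallel lines of slope s = Q/(P+Q):
h₀(n) = s·n − b/(P+Q) and h₁(n) = s·n + a/(P+Q), with
a = ln[(1−β)/α], b = ln[(1−α)/β]. The slope always satisfies
p₀ < s < p₁. The test suite verifies the line equations against a
direct solve of the Wald inequalities on a 5×5×3×3 parameter grid to
1e−12.

Note on the upper line's sign: in cumulative-failure form the upper
intercept is **added** (h₁ = s·n + a/(P+Q)). With a subtracted
intercept the two lines would coincide whenever α = β and no chart
could distinguish acceptable from unacceptable performance; the
additive form is the standard SPRT geometry and the one implemented.

## Classification conventions

* The chart is integer-valued against real-valued lines, so an exact
  touch is the natural discrete crossing event: competence uses
  S_n ≤ h₀(n), unacceptable uses S_n ≥ h₁(n).
* Comparisons carry an absolute slack of 1e−12 so that analytically
  exact touches are not lost to floating-point rounding. This matters
  in practice: at (p₀, p₁, α, β) = (0.10, 0.30, 0.10, 0.10) the
  identity a = 2P (ln 9 = 2 ln 3) makes an all-failure path meet the
  upper line *exactly* at n = 2.
* At an attempt where both inequalities hold, the lower line wins —
  a favourable-to-trainee tie-break, stated explicitly because the
  verdict is otherwise ambiguous.
* The verdict is terminal at the first crossing; later recrossings are
  ignored.
* Boundaries are defined only at integer attempts n ≥ 1; all
  logarithms are natural.
* Indeterminate trainees count as non-achievers in cohort 2×2 tables
  and are excluded from attempts-to-competence summaries. The SD of a
  single achiever's crossing attempt is reported as 0 with a
  degenerate-input flag.

## Cohort comparison

Achievement (competent vs not) is compared with the crude odds ratio
of the 2×2 table, a Woolf log-OR 95 % interval
exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) and a two-sided z test on the
log OR. When any single cell is zero, the Haldane–Anscombe 0.5
correction is applied to every cell and flagged in the output (this
includes the degenerate all-achievers cohort, whose corrected OR is
1); the OR is reported as undefined only when an arm contains no
trainees at all. Published interval estimates for such tables are
method-sensitive; this package standardises on Woolf and treats only
point estimates and counts as reproducible.

The logistic regression of achievement on a binary arm indicator is
fitted by Newton scoring (IRLS) implemented in `cohort_stats` itself;
for this saturated one-covariate model exp(slope) equals the crude OR,
and the test suite exploits that identity (to 1e−6) plus an external
statsmodels GLM cross-check. Complete separation (an arm with
all-identical outcomes) raises a `SeparationError` rather than
returning a silently diverged estimate.

Attempts-to-competence are compared with Welch's unequal-variance
t-test (scipy); when both samples have zero variance the p-value is 1
for equal means and 0 otherwise, flagged degenerate. No
multiple-testing correction is applied across sensitivity rows; the
grid is descriptive.

Percentages are rounded half-away-from-zero to integer percent
(13/21 → 62 %).

### Sensitivity grid and monotonicity

The grid re-derives the constants, reclassifies every trainee and
rebuilds the full comparison per (p₀, p₁) setting. Raising p₁ with p₀
fixed raises the lower line pointwise, so the first lower-line
crossing never comes later — but the upper line's intercept also
shrinks, so a trainee's overall status is **not** monotone in p₁: the
unacceptable verdict can pre-empt the now-easier competence crossing.
The property suite asserts the monotone sub-property (lower-crossing
time non-increasing) rather than full status monotonicity.

## Synthetic cohorts

The generator emulates the latent learning process behind the binary
scores: trainee t in an arm with parameters (p_start, p_floor, τ,
heterogeneity σ) fails attempt i with probability

    p(i) = p_floor + (p_start − p_floor)·exp(−(i−1)/τ_t),
    τ_t = τ·exp(ε),  ε ~ N(0, σ²).

Exponential decay is the simplest monotone curve consistent with
learning; it is isolated behind `LearnerModel` and fully
configurable. One global seed expands to per-trainee substreams via
`SeedSequence(seed, spawn_key=(arm, index))`, so enlarging a cohort
never perturbs existing trainees.

Defaults (`default_design`): two arms of 21 trainees over a 60-attempt
rotation (a typical six-month obstetric-anaesthesia caseload), shared
p_start = 0.5, p_floor = 0.04, σ = 0.3, with τ = 3 (study arm,
structured teaching) vs τ = 7 (control). These values were calibrated
once, by Monte-Carlo, to place the arms at the study-scale operating
point the analysis is designed around: ≈ 2/3 vs ≈ 2/5 of trainees
achieving competence at the (0.10, 0.30, 0.10, 0.10) boundary, with
mean attempts-to-competence among achievers in the high teens to low
twenties.

What the simulator does *not* model: patient-level covariates (BMI,
labor stage), instructor effects, drift in case difficulty, or the
separate analgesia-quality component of the score — the binary score
already composes all failure criteria, which is what the analysis
consumes. Passing tests therefore demonstrate correctness of the
charting, classification and comparison machinery under a plausible
learning process, not validity of any particular clinical dataset.

### Operating characteristics

`operating_characteristics` simulates constant-rate trainees and
reports the proportion of each verdict: at rate p₀ the unacceptable
proportion estimates the realised type-I error, at p₁ the competent
proportion the realised type-II error. Truncation at a finite number
of attempts and the discreteness of the failure count keep the
realised rates below, not equal to, the nominal 0.10; the suite allows
0.12. Problem sizes used: 10,000 replicates of 300 attempts for the
operating characteristics; 500 replicate cohorts per arm size for the
effect-detection and power studies.

## Known limitations

* The SPRT lines assume a constant failure rate within each
  hypothesis; a trainee mid-learning violates both hypotheses early
  on, which is why indeterminate verdicts are common in short series.
* No resetting/holding-barrier CUSUM variant, risk adjustment, or
  average-run-length closed forms are provided.
* Confidence-interval methods for small 2×2 tables differ
  non-trivially; only point estimates should be compared across
  implementations.
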