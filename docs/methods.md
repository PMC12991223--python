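# Methods

## The VGC model

Visual grading characteristics (VGC) analysis compares the ordinal
image-quality rating distributions of two protocols the way ROC analysis
compares rating distributions of abnormal and normal cases. For a test
protocol *t* and reference protocol *r* rated on a K-category scale, the
empirical VGC curve is the set of operating points

    ( P(R_r >= k), P(R_t >= k) ),  k = K, K-1, …, 1,

prefixed by (0, 0), i.e. at most K + 1 points joined by straight lines.
Its trapezoidal area equals the tie-corrected two-sample U-statistic

    AUC_VGC = [ #{t > r} + ½ #{t = r} ] / (n_t n_r),

an identity the test suite verifies exhaustively for all multiset pairs
with up to 4 ratings per arm on scales up to 4 categories. Ties carry
weight ½; this is what makes the estimator antisymmetric
(AUC(A,B) + AUC(B,A) = 1) and invariant under strictly increasing
relabelings of the categories. Orientation: higher rating = better
quality, AUC_VGC > 0.5 = test protocol rated better.

In the MRMC design every observer rates every case under every protocol.
Ratings are never pooled across observers: each observer's (case,
criterion) ratings within a criterion class form that observer's test and
reference multisets, one AUC is computed per observer, and the reported
AUC is their arithmetic mean. Criterion classes are analysed by *pooling*
each (case, criterion) rating as one observation, not by averaging
criteria within a case first: averaging ordinal labels would fabricate a
numeric scale, while pooling stays rank-based. The pooling mechanism is a
package design choice (the combination rule is underdetermined in the VGC
literature) and is isolated behind the `criteria` argument, so analysing
single criteria or other groupings needs no code change.

The *effect size* of a comparison is |AUC_VGC − 0.5|, the distance from
the null value; the pipeline reports it rounded to two decimals.

## Bootstrap inference

Inference is fixed-reader and paired-case. The observer panel is treated
as fixed (the study's generalisation target is these readers, not a reader
population), so the only resampled unit is the case: each bootstrap
replicate draws cases with replacement, and a drawn case carries all of
its ratings — every observer, every criterion, both protocols — which
preserves the within-patient pairing of protocols. Per replicate the
per-observer AUCs are recomputed and averaged.

* Confidence interval: percentile interval of the replicate distribution
  at the requested level (default 95 %). Percentile intervals are
  asymmetric by construction; BCa was not used because the percentile
  interval is reproducible without jackknife influence estimates and its
  coverage at the study's size is verified by simulation (see below).
* p-value against AUC_VGC = 0.5: doubled smaller tail fraction,
  p = min(1, 2·min(#{AUC* ≤ 0.5}, #{AUC* ≥ 0.5})/B), replicates exactly
  at 0.5 counted in both tails. The doubled-tail construction is a
  documented convention; one-sided alternatives are deliberately not
  offered.
* Degenerate replicates (an observer whose resampled ratings are constant
  and identical across protocols) yield AUC = 0.5 through the tie rule;
  no replicate is discarded.
* Multiple comparisons: `compare_all` runs one test per (non-reference
  protocol × criterion class) and applies no multiplicity correction;
  the per-observer AUCs, tie counts, seed and replicate count are logged
  so any number is auditable.

Default B = 10 000 replicates; the calibration simulations in the test
suite use B = 2 000, which is ample for p-values near 0.05. All
resampling is vectorised over replicates by reducing each observer's
ratings to per-case category counts, so one replicate costs two
(B × cases) × (cases × K) matrix products per observer.

## Binormal model

The smooth alternative assumes latent normal quality: reference ~ N(0, 1),
test ~ N(μ, σ²), both discretised through the same K − 1 strictly
increasing thresholds. On probit-transformed VGC axes the curve is the
line y = Φ(a + b Φ⁻¹(x)) with a = μ/σ, b = 1/σ, and
AUC = Φ(a/√(1 + b²)). The multinomial likelihood is maximised jointly
over (a, log b, t₁, log Δ₂, …, log Δ_{K−1}) — the log-increment
parameterisation enforces monotone thresholds — with Nelder–Mead at a
10⁻⁸ absolute tolerance on the log-likelihood, initialised from the
pooled empirical cumulative proportions (thresholds) and a least-squares
probit line through the operating points (a, b). Category probabilities
are floored at 10⁻³⁰⁰ so empty cells cannot produce −∞. If either arm
occupies a single category the model is not identifiable and the fit
raises instead of returning noise.

The empirical (trapezoidal) AUC is the headline estimator fed to the
bootstrap; the binormal AUC is reported as the smooth alternative. The
package favours the assumption-free estimator because the curve/U-statistic
identity makes it exactly reproducible, while the binormal value depends
on fitting choices.

## Dose model

Effective dose E (mSv) = DAP (Gy·cm²) × c, with c = 0.26 mSv/(Gy·cm²),
the Monte-Carlo-derived coefficient for chest tomosynthesis of a
standard-sized adult; the linearity is exact by construction. The
acquisition *dose ratio* multiplies the scout image's tube load, so the
designed exposure fraction of ratio ρ against reference ρ₀ is ρ/ρ₀
(7/10 = 0.7, 5/10 = 0.5). Cohort summaries stratify by BMI — below 25,
25–30 inclusive on both ends, above 30 — and report per-ratio group
means/SDs plus each reduced ratio's group-mean dose as an integer
percentage of the reference group mean. Percentages are
**ratio-of-group-means** with half-up rounding, not means of per-patient
ratios: only this reading reproduces published BMI-stratified tables of
this kind from their printed group means, and it is the natural summary
when per-patient pairing is incomplete. Published tables of this form can
carry internal rounding inconsistencies (a printed group-mean DAP times c
need not equal the printed group-mean dose, since the per-patient
averaging order is unrecoverable); the package always computes
per-patient doses exactly and summarises those.

## Synthetic generator

The generator stands in for access-restricted patient rating data. Latent
quality is

    q(case, protocol, criterion) = δ_protocol + γ_case + ε,

γ_case ~ N(0, σ_c²) shared by all protocols of a case — this is what
makes the paired bootstrap informative — and ε ~ N(0, σ_e²) independent
per (case, protocol, criterion). Each observer perceives q plus
independent N(0, σ_e²) reading noise and discretises it through
observer-specific thresholds. Under this model the probability that one
perceived draw of a shifted arm exceeds one of the reference arm has the
closed form Φ(δ/(σ√2)) with per-arm SD σ = √(σ_c² + 2 σ_e²), which is the
ground truth for recovery and coverage checks.

Defaults emulate the target study: 4 observers, 50 cases, 14 criteria,
K = 5, three protocols with latent shifts 0 / −0.05 / −0.13 (chosen so the
reduced protocols' true AUCs sit near 0.49 and 0.47, the magnitude of
effect such studies report), σ_c = 1, σ_e = 0.5. The unit case effect
dominating the rating noise makes null bootstrap intervals at the study's
size visibly asymmetric, as in real paired panels.

Observer heterogeneity enters only through thresholds — differences in
scale interpretation, not in perceived quality. Base thresholds are
equally spaced and symmetric with the outer pair at ±1.2 σ; observer
jitter is a shared leniency shift (SD = `observer_threshold_jitter`,
default 0.3) plus small independent spacing noise (SD = jitter/4). The
shift-dominant decomposition matters: exact computation shows that for
*any* symmetric equally spaced thresholds on a 5-category scale the
tie-corrected AUC of the discretised ratings is attenuated toward 0.5 by
about 0.004 / 0.008 / 0.013 / 0.020 at shifts of 0.3 / 0.6 / 1.0 / 1.5
latent SDs, and random spacing perturbations only add to that floor. The
generator's recovery property is therefore calibrated by its own
repeat-simulation harness: the averaged empirical AUC at 500 cases stays
within 0.02 of the latent closed form for shifts up to 1.0 (AUC up to
≈ 0.72, comfortably covering the effect sizes such studies report) and
within 0.025 at 1.5; the tests assert exactly those bands.

What the generator does *not* emulate: BMI-dependent image quality,
criterion-specific difficulty (all criteria share one shift per protocol),
correlated criteria within a case beyond the shared case effect, and
reader drift over the session. Passing calibration tests on these panels
therefore shows the estimator chain is correct and calibrated under a
faithful paired MRMC null, not that any particular clinical dataset meets
the model's assumptions.

The dose cohort generator draws per-patient reference DAPs log-normally
around per-BMI-group means (defaults matching a chest-tomosynthesis
cohort: 2.53 / 4.11 / 4.78 Gy·cm², CV 0.25) and scales them by per-ratio
factors, exact (0.7, 0.5) by default or per-group to emulate measured
ratios.

## Simulation sizes and verified properties

All sizes below are the package's own calibration choices, run by the
default test suite:

* Null calibration: 500 replicate null studies at study size, B = 2 000;
  grand mean AUC within 3 Monte-Carlo SEs of 0.5 and rejection rate at
  α = 0.05 within the binomial 95 % margin of 0.05 (measured ≈ 0.04).
* Interval coverage: 400 null studies at study size; 95 % percentile
  intervals cover the true AUC 0.5 in 95 % ± 2.5 points (measured 0.950).
  Coverage is checked at zero shift because there the latent closed form
  and the discretised estimand coincide exactly; at non-zero shifts the
  interval is centred on the discretised AUC, which sits below the latent
  value by the attenuation listed above, so "coverage of the latent
  value" would conflate that known offset with interval calibration.
* Parameter recovery: shift grid {0, 0.3, 0.6, 1.0} at 500 cases,
  8 replicate panels per point; monotone in the shift and within 0.02 of
  Φ(δ/(σ√2)). Binormal recovery: a = 1, b = 1, 5 000 ratings per arm;
  â within 0.1, AUC within 0.02 of Φ(1/√2).
* Exhaustive identity: trapezoidal area = U-statistic and antisymmetry
  for every multiset pair with ≤ 4 ratings per arm, K ≤ 4.

`scripts/acceptance.py` recomputes the null grand mean (500 studies) from
scratch at any seed.

## Known limitations

* Fixed-reader only: no Obuchowski–Rockette / DBM random-reader variance
  components; conclusions generalise to the observer panel, not the
  reader population.
* The rating scale length K must be declared; the package never infers it
  from data, so a mis-declared K silently changes the operating points.
* The binormal fit can be fragile for sparse tables (few cases, extreme
  categories empty); it raises on non-convergence rather than falling
  back.
* Percentile (not BCa) intervals; for very small case counts (< ~20) the
  percentile interval's coverage has not been characterised here.
* The 5-category discretisation attenuates large AUCs (see above);
  comparisons with true AUC beyond ≈ 0.8 are reported conservatively.
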