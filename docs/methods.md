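# Methods

## The phase model

Clock-gene transcription in peripheral tissues oscillates with a ~24-h
period, and the phase relations between clock-gene transcripts are nearly
constant across tissues and individuals. `circascreen` exploits this by
fitting all measured genes jointly to fixed-period cosines that share a
single phase θ:

    obs_g(t_i) = A_g cos(ω t_i + θ + Δθ_g) + C_g + ε_g(t_i),  ω = 2π/24,

with Δθ = 0 for the anchor gene (*Per3*) and Δθ_g = 2πΔτ_g/24 for the
others, where the peak-time offset Δτ_g is constrained to a narrow window
(default [1.5, 2.5] h: the Rev-erb genes *Nr1d1*/*Nr1d2* peak about 2 h
before *Per3*). Sharing θ is what makes three samples per gene sufficient:
each gene alone would be exactly interpolable, but the joint fit pools
information across genes.

Assumptions: the period is exactly 24 h (no free-running drift over the
sampling day); one harmonic suffices at three points; noise is additive
and roughly homoscedastic on the standardized scale; the inter-gene offset
lies inside the configured window. Each gene's series is standardized
(zero mean, unit sample SD) before fitting; phase estimates are invariant
to per-gene affine scaling, so this is equivalent to any "unit amplitude"
normalization while keeping amplitudes free in the cost.

## Optimization

For fixed θ and Δθ_g the per-gene amplitude and offset have an exact
linear least-squares solution, so the cost can be profiled over θ alone —
and the Δτ_g selection separates per gene given θ. The three-point profile
is multimodal in θ, so the global minimum is found on a dense
deterministic grid (1440 points = 1-minute resolution; ties resolve to the
smaller θ) followed by bounded golden-section refinement within one grid
cell (cost tolerance 1e-10). Δτ_g moves on its own grid (step 0.1 h,
comfortably finer than the ~0.5-1 h phase estimation error at realistic
noise). Amplitudes are canonicalized to A_anchor ≥ 0 via a joint θ → θ+π
flip; a negative non-anchor amplitude after canonicalization sets an
antiphase warning flag. A nonlinear conjugate-gradient backend over the
full parameter vector (`backend="cg"`) exists as a cross-check and is
tested to agree with the grid.

Two conventions convert θ to the anchor peak time: `"paper-formula"`
evaluates 24(0.5π − θ)/(2π) mod 24, the peak of sin(ωt + θ); and
`"curve-argmax"` evaluates (−24θ/2π) mod 24, the argmax of the fitted
cosine. They differ by exactly 6 h. The library default is
`"paper-formula"`; synthetic-recovery work uses `"curve-argmax"` because
ground truth is defined as the expression peak. Every screening quantity
that is referenced to a control band is unaffected by the choice, since
the constant offset cancels between subject and band.

Goodness of fit is CD = 1 − SSE/SST pooled across genes, SST about
per-gene means of the standardized data. The constant model is nested in
the cosine model, so CD ∈ [0, 1] by construction; constant data defines
CD = 0 with a degenerate flag, and an all-constant subject raises a
degenerate-fit error that the cohort pipeline converts into an
"arrhythmic" screening flag.

## Confidence intervals

The 95% CI of the peak time is a parametric bootstrap: synthetic datasets
are drawn around the fitted curves, refitted on a θ grid (720 points; the
1-2 min grid resolution is negligible against bootstrap spread), and the
circular 2.5/97.5 percentiles of the peaks around the point estimate form
the interval.

The noise model matters. With two genes at three times the model has
nearly as many effective parameters (θ, per-gene A and C, Δτ) as
observations (6), so fit residuals are interpolation artifacts and any
residual-based noise estimate is badly anti-conservative — measured CI
coverage collapses to ~30-50% even with sqrt(n/dof) inflation. The
recommended path therefore estimates the noise SD from *replicate
scatter*: when several independent samples exist per time point,
`estimate_noise_sd` pools the within-time variance of the per-time mean
(pure error, on the gene's standardized scale) and the bootstrap draws
Gaussian noise with that SD. With this design the empirical coverage of
the nominal 95% interval measures 93-95%. Residual resampling (inflated by
sqrt(n_obs/dof)) remains available for unreplicated data and must be read
as approximate there; degenerate fits report the full circle [0, 24).

## Replicate-combination validation

With r samples per time point, one phase is estimated for each of the r³
combinations of one sample per time (lexicographic enumeration; a sample
supplies all genes simultaneously). The "real" phase of a subject is the
*circular* mean (resultant vector) of the ensemble — arithmetic averaging
fails when phases straddle midnight — and errors are signed circular
deviations in (−12, +12], with the antipode mapped to +12 for determinism.
The circular SD sqrt(−2 ln R) summarizes spread. Stratifying pooled
|error| by CD shows CD acting as a reliability filter: in the packaged
simulations mean |error| falls monotonically as the CD threshold rises
through 0.8 → 0.99 (~0.5 h at CD ≥ 0.95 under mixed noise of 0.1-0.7 on
the standardized scale).

## Sleep parameters and the screen

Sleep times are extended decimal local-time hours: onsets after midnight
are recorded > 24 (01:47 → 25.78), get-up times as morning clock times.
All interval parameters are then plain subtractions with P3PT in [0, 24)
— no modular reduction — which keeps typical values in interpretable
ranges (GUw − P3PT ≈ 1.6 h, SOw − P3PT ≈ 18-19 h). Mid-sleep is
(onset + next-morning get-up)/2 and social jetlag is mid-sleep(free) −
mid-sleep(work); social jetlag is reported for context but is not a screen
criterion.

The control reference band is the per-parameter sample mean ± SD (n−1)
over control subjects (PSQI ≤ 5 by default). The screen classifies a
subject as a latent-CRSWD candidate iff

    (A ∧ B) ∨ (A ∧ exception), where
    A: GUf − GUw ≥ 3 h,
    B: GUw − P3PT < control mean − SD (or a fixed preset cutoff,
       0.15 h / 0.16 h for the two-/three-gene estimator),
    exception: CD < 0.95, CI width > 4 h, or arrhythmic expression.

The low-CD and wide-CI thresholds are conservative defaults (the band
itself fixes criterion B; the exception path exists because severe
circadian dysfunction can defeat the phase estimate itself) and every
threshold is echoed into the result record for auditability. Subjects in
the advanced tail (GUw − P3PT above mean + SD) get an informational flag
but are never classified as candidates: an advanced-looking phase is more
plausibly the *result* of independently delayed sleep than of advanced
circadian sleepiness. Follow-up comparisons report per-criterion deltas,
band re-entry and PSQI change, with a coarse improved / unchanged /
deteriorated status.

## Synthetic cohorts

The generator draws a circadian phase per subject (controls
N(6.4, 1.0²) h; cases delayed by 4 h by default), builds cosine expression
(baseline 2, amplitude 1, Rev-erb genes peaking 2 h before *Per3*) sampled
at wake + {0, 8, 16} h with additive Gaussian noise on the standardized
scale, and couples sleep to phase: work-day wake is socially fixed
(8:00 ± 0.4 h) while free-day wake follows the phase (phase + 2.76 h ±
0.4 h); sleep durations are 7.5/8.1 ± 0.3 h; PSQI totals are drawn ≤ 5
for controls and > 5 for cases so group labels hold by construction.
Everything is deterministic for a fixed seed.

What the generator does *not* emulate: the heavy-tailed, possibly
multiplicative noise of real hair-follicle qPCR; inter-individual
variation in the inter-gene offset; day-to-day instability of sleep
timing; questionnaire measurement error; and any correlation between
noise level and pathology. Passing end-to-end tests therefore demonstrate
the *pipeline's* correctness and its behavior under the stated model, not
field performance on real cohorts.

## Problem sizes and numerical choices

The packaged test and acceptance runs use deliberately modest sizes chosen
to exercise each claim with stable statistics: 100 random instances for
the brute-force θ-grid oracle (10⁵ grid points), 200 two-replicate
ensembles for the error-vs-CD monotonicity, 500 simulations × 200
bootstrap replicates for CI coverage, and 50 cohorts of 12 controls + 10
cases for the screen's sensitivity/specificity. Degenerate inputs
(constant series, singular cosine designs, zero-variance bands, antipodal
circular means) are flagged or raised explicitly rather than silently
propagated; all tie-breaks (θ grid, Youden cutoff) resolve to the first
candidate for determinism.

## Known limitations

- The 6-h ambiguity between the two peak-time conventions cannot be
  resolved internally; absolute P3PT values must state their convention.
  Band-referenced screening quantities are convention-free.
- With unreplicated three-point data the CI is approximate (see above) and
  the Δτ window is an assumption, not an estimate.
- The screen's exception thresholds (CD < 0.95, CI width > 4 h) are
  design defaults, not fitted quantities.
- Statistical helpers assume independent subjects; repeated screens of
  the same subject are compared descriptively, not tested formally.
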