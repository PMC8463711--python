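# Methods

## Problem and approach

Opportunistic occurrence platforms record a species only when someone
notices it, can photograph it, and bothers to submit it; checklist
platforms with effort metadata come much closer to a census of what a
birder detected. Contrasting the two therefore isolates the *recording*
bias of the opportunistic stream. The pipeline quantifies that bias per
species and asks whether it is predicted by four detectability-related
traits: body size, gregariousness (flock size), colorfulness, and
commonness (IUCN status as a proxy).

The procedure has four stages, each behind its own module:

1. **Quality filtering** (`io_filtering`). Checklists are retained when
   complete, with a protocol other than incidental/historical, distance
   ≤ 5 km and duration in [5, 240] minutes. The boundaries are inclusive:
   the exclusions are of checklists that travelled *more than* 5 km or
   lasted *less than* 5 / *more than* 240 minutes, so exact boundary
   values pass. Missing distance is treated as 0 km only for stationary
   checklists (stationary implies no travel); missing duration always
   fails the duration filter. A filter report counts removals per
   criterion (a checklist failing several criteria counts once per
   criterion, is removed once) and must reconcile exactly with the input.

   Species are then trimmed per state to the core avifauna: a species on
   strictly fewer than `cutoff` (default 1%) of the state's retained
   checklists is removed there, so a species can survive in one state and
   not another. Prevalence uses the *retained* checklists as denominator.
   The cutoff is swept over {0, 0.5, 1, 1.5}% in every pipeline run;
   survivor sets are nested by construction and the run manifest records
   the check. No record-level filter is applied to the unstructured
   platform (its research-grade vetting is assumed of the input).

2. **Representation residual** (`representation`). Per state, OLS of
   log10(unstructured count) on log10(checklist-platform count) across
   species; the residual is the over/under-representation score. Fitting
   per state absorbs state-level differences in observer base, effort and
   avifauna. Zero counts cannot enter a log-log fit; the default policy
   drops the pair from that state's fit and counts it in the fit
   metadata, and an `add-one` (log10(n+1)) variant exists for sensitivity.
   Dropping matches a literal log transform of observation counts and
   keeps the impact auditable. States with fewer than 3 usable species
   (or a degenerate predictor) are skipped with a warning, never merged.

3. **Traits** (`traits`).
   - *Body mass*: log10 grams.
   - *Flock size*: mean reported count over all checklists reporting the
     species, pooled across states; "X" (present, uncounted) records are
     excluded from numerator and denominator and species with only "X"
     records get a missing trait, not zero. The mean is ≥ 1 whenever
     defined, so its log10 is ≥ 0.
   - *Color index*: two components over six plumage patches (upper/lower
     breast, crown, forehead, nape, throat) for both sexes — the maximum
     Euclidean RGB distance from brown and the maximum relative luminance
     0.2126R + 0.7152G + 0.0722B. Each component is min–max scaled over
     the species set, averaged with equal weight (configurable), and
     rescaled to [0, 1]. The brown reference defaults to
     (R, G, B) = (102, 68, 0); the transposed variant (102, 0, 68) and a
     CIE Lab (D65, via scikit-image) distance are available by config for
     sensitivity. A constant component makes min–max scaling undefined
     and raises with instructions rather than emitting NaN.
   - *IUCN score*: ordinal commonness proxy with Least Concern highest:
     LC = 2, VU = 1, NT = 0, equally spaced so a single linear
     coefficient is interpretable per level. Endangered and rarer
     categories are excluded (too few species for that level to carry
     signal); exclusion is a missing value that the per-model
     completeness rule then drops.

4. **Mixed models** (`trait_models`). The residual (one row per
   state × species) is modelled with fixed trait effects and a random
   intercept per state, which accounts for species replicated across
   states. One global model uses all four traits; four single-trait
   models each use one, admitting more rows when trait missingness is
   uneven (per-model completeness: rows are dropped only for predictors
   that model uses, with drop counts reported). Estimation is REML
   (ML available). Confidence intervals are Wald (estimate ± z·SE) and
   p-values use the normal approximation to the Wald statistic; the
   method string is recorded in every result. With one state the random
   intercept is unidentifiable and the fit is OLS (recorded). When the
   estimated random-intercept variance hits the 0 boundary — which is the
   expected outcome here, because per-state OLS residuals have exactly
   zero state means — the GLS fit coincides with OLS but the mixed-model
   covariance is singular, so fixed effects and their standard errors are
   reported from OLS, again recorded in the method string.

## Synthetic data and what it does (not) emulate

The generator exists so that every stage is testable without the real
multi-hundred-GB platform extracts. It emulates, with defaults chosen
once from the real platforms' published scale:

- **Effort heterogeneity**: per-state checklist totals 10^U(4.7, 5.7),
  reproducing per-(state, species) record totals of order 10^4 on the
  checklist platform and, under the 1:200 volume ratio below, order 10^2
  on the unstructured platform — the scale implied by ~2.6×10^8 checklist
  records and ~1.1×10^6 unstructured records spread over ~4×10^3
  state × species combinations.
- **Positively skewed counts**: a per-species baseline rate
  10^N(−1.1, 0.35) per checklist, jittered per state by 10^N(0, 0.2),
  times state effort, truncated below at 1 — log-normal on the count
  scale, matching the strong right skew of real per-species counts.
- **The planted relation**: log10(unstructured count) = state intercept
  + slope·log10(count) + Σ γ·trait (traits centred) + N(0, noise_sd),
  rounded to a nonnegative integer. Intercepts default to N(−2.3, 0.25)
  (the ~1:200 volume ratio) with slope 1. Centring traits in the
  generative model makes state intercepts and trait effects orthogonal by
  construction, which keeps recovery tests interpretable. Zero rounded
  counts are flagged, never silently dropped, so the zero policy is
  testable. The pre-rounding latent value is retained as generator truth
  for rounding-perturbation bounds.
- **Traits**: body mass log-normal around 50 g (0.65 dex spread), flock
  size 1 + log-normal, IUCN drawn from (0.88, 0.07, 0.05) over
  (LC, NT, VU) with optional Endangered mass, and plumage patches placed
  along the brown→white axis at per-patch fractions of a Beta(2, 2)
  target, making both color components affine in the target so the
  derived color index reproduces the target's min–max ranks exactly.
  Trait dimensions are drawn independently by default (an explicit
  simplification; real body mass and flock size are not independent, but
  no joint distribution is credibly known, and independence makes the
  recovery design orthogonal).
- **Event-level bundles** additionally materialise checklists with
  labelled quality-filter violations (each contaminated checklist
  violates exactly its labelled criterion; a configurable fraction of
  clean checklists sit exactly on the 5 km / 5 min / 240 min boundary)
  and checklist-linked records with occasional "X" counts. These bundles
  are desk-scale (hundreds of checklists per state), so their planted
  intercepts default to N(0.3, 0.25): at the real 1:200 ratio every
  unstructured count would round to zero at this scale. The volume ratio
  is therefore only emulated by the aggregated direct path.

Not emulated: spatial structure within states, observer-level behaviour,
seasonal/weekly effort cycles, taxonomic misidentification, and any
correlation between traits and *true* abundance. Passing recovery tests
therefore show that the estimator is calibrated when its structural
assumptions hold at realistic scale — they do not show that the real
platforms satisfy those assumptions.

## Validation design

The primary validation is parameter recovery: 200 replicates of 40
states × 150 species with planted effects γ_body = 0.05,
γ_flock = 0.05, γ_color = 0, γ_iucn = 0.03 and noise 0.05 (log10 scale),
checking |mean bias| < 0.01 per trait, 95% CI coverage within
[0.90, 0.98], and a null-effect rejection rate inside the binomial 95%
band around 0.05. Replicates use seeds 1..200; each replicate redraws
states, effort, intercepts and traits from its own stream. The residual
regression stage makes exact calibration impossible in principle — the
per-state OLS projection attenuates trait effects by a factor of order
1 − 2/n_species and adds projection noise the second-stage model cannot
see — but at 150 species per state both effects are an order of
magnitude below the acceptance tolerances.

Supporting checks: OLS residual-sum and orthogonality identities
(< 1e−8) and closed-form normal-equations agreement (< 1e−10) on random
fixtures; exact agreement of the quality filter with generator labels on
a 10,000-checklist bundle including boundary retention; brute-force
prevalence recounts and nested trim survivor sets; the printed color
formula anchors (distance 0 at the brown reference, luminance 255 at
white and 54.213 at pure red); single-state mixed = OLS within 1e−6;
zero-noise residuals bounded by the OLS image of the integer-rounding
perturbation (bound |δ|∞ + √h_max·‖δ‖₂ computed from the design); and
bit-identical pipeline artifacts across repeated runs at fixed seed
(manifest timestamps excluded).

## Numerical choices and degenerate inputs

- Tie-break at the trim boundary: prevalence exactly equal to the cutoff
  survives (removal is strict `<`).
- R² of a constant-response state fit is defined as 1 when the fit is
  exact (0/0 case), 0 otherwise.
- Seeds: one master seed per generator call; sub-streams per table are
  derived via `SeedSequence` spawning so tables are independently
  reproducible.
- CSV artifacts are written with `%.10g` floats and stable row ordering;
  JSON with sorted keys — determinism is a test, not an aspiration.
- Empty inputs, missing columns, unknown config keys, out-of-range
  cutoffs and unrecognized IUCN labels all fail fast with messages naming
  the offending field; nonconvergent mixed fits return
  `converged=False` with diagnostics instead of raising.

## Known limitations

- p-values use the normal approximation rather than Satterthwaite
  degrees of freedom; with dozens of states and thousands of rows the
  difference is negligible, but small-state designs will be slightly
  anti-conservative.
- The two-stage design (residuals as response) slightly attenuates trait
  effects and understates uncertainty for small per-state species pools;
  see the validation section for magnitudes.
- The flock-size proxy conflates gregariousness with local density, and
  the color index reduces plumage to two scalar components.
- `zero_policy="drop"` makes the estimand conditional on presence in
  both datasets; the `add-one` variant changes the estimand rather than
  fixing this.
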