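# Methods

## Scope and design

`numerosym` models a two-interval forced-choice (2IFC) numerosity comparison
between a standard dot array (random, vertically symmetric, or doubly
symmetric) and an asymmetric test, across standard numerosities spanning the
estimation and density regimes. The package separates four layers:

1. **geometry** (`stimgen`) — the physical stimulus;
2. **generative observer** (`observer`, `cohort`) — what a participant does;
3. **measurement** (`staircase`, trial simulation) — how the experiment
   samples behaviour;
4. **analysis** (`psychofit`, `regimefit`, `inferstats`, `aq`) — the fitting
   and inference chain applied to trial tables.

Because layers 2–3 are explicit, every analysis-layer estimator is validated
by parameter recovery: simulate with known parameters, analyse, compare.

## Stimulus geometry

Dots (default 0.3° diameter) are placed in a 10°-diameter virtual circle by
rejection sampling. The minimum separation is **centre-to-centre** and
defaults to 0.6° (a 0.3° edge gap for 0.3° dots); it is a parameter because
the constraint is geometrically infeasible for the densest arrays — a
hexagonal-packing bound (⌊area/(√3/2·s²)⌋) is checked up front and dense
conditions (e.g. 400 dots) require lowering `min_separation` explicitly
rather than looping forever. Symmetric arrays sample one half (or quadrant)
and copy reflected coordinates, so mirror invariance is exact; sampled points
keep `min_separation/2` clear of each reflection axis, which guarantees
separation between a dot and its own mirror image and between any
cross-axis pair. Odd counts under vertical symmetry (or counts not divisible
by 4 under double symmetry) are rejected rather than placing dots on the
axis; all design numerosities are even. `check_symmetry` classifies an array
by optimal assignment (Hungarian matching) between the centre multiset and
its reflections, returning the maximal invariant class.

Note that trial simulation carries numerosities only; per-trial images are
never generated. The geometry module exists so that the stimulus class
definitions are concrete, exportable (CSV + JSON sidecar, optional PNG) and
testable.

## Generative observer

A participant is an `ObserverParams` record:

- **Two-regime Weber curve** `Wf(N) = Wf0` for `N ≤ N′`, else
  `Wf0 (N/N′)^(−α)`. Defaults Wf0 = 0.25, N′ = 100, α = 0.5: Weber's law in
  the estimation regime switching to a square-root law in the density
  regime, with the plateau level and switch location characteristic of this
  task.
- **Condition bias**: a multiplicative shift of the perceived standard.
  The probability of answering "test more" is
  `Φ((n_test − PSE)/σ)` with `PSE = N(1 + bias/100)` and
  `σ = Wf(N)·N / Φ⁻¹(0.75)` (Φ⁻¹(0.75) ≈ 0.6745 converts a 50→75% JND to a
  Gaussian sd). All decision noise is placed on the test axis — the model
  the analysis fits — rather than combining two interval noises as
  √(σ_t²+σ_s²); the single-σ description is what the data constrain, and a
  two-interval variant is an extension hook, not the default.
- **No lapse rate** by default; a symmetric lapse is available for
  robustness refits.
- **Control-task accuracy**: per-N probability of identifying the symmetric
  interval (defaults 0.95–1.00, highest at sparse arrays).
- **AQ score** (0–50).

## Synthetic cohorts

`CohortSpec` draws per-participant parameters. Defaults encode the study
conditions the analysis is meant to recover:

| parameter | default | rationale |
|---|---|---|
| vertical bias, estimation regime | −7 % ± 2.5 | ~7% underestimation at moderate numerosities |
| vertical bias, density regime | −3 % ± 2.5 | effect largely vanishes when dense |
| Exp-2 profile (vertical/double) | −8/−14 (N12), −7/−9 (N48), −4/−7 (N200) | double symmetry deepens the bias |
| random-condition bias | 0 % ± 1 | veridical baseline |
| Wf0, N′, α | 0.25 ± 0.03, 100, 0.5 | group Weber curve |
| AQ | 17 ± 6 | synthetic default for a neurotypical sample (not a published value) |
| AQ–bias correlation | r = 0.51 | target coupling, estimation-regime symmetry bias |

Within a participant all symmetric-condition biases share one
"susceptibility" latent z; AQ is built as
`aq_mean + aq_sd·(r·z + √(1−r²)·z')`, which yields the target correlation in
expectation (verified by Monte Carlo to ±0.03 over 200 cohorts). Integer
clamping of AQ to 0–50 attenuates it negligibly at these settings. Seeds
form a `SeedSequence` spawn hierarchy (master → participant → staircase), so
enlarging a cohort never perturbs existing participants' data.

The generator emulates the *statistical* structure the analysis assumes —
per-participant Weber noise, regime-dependent bias, AQ coupling. It does not
emulate sequential effects, learning/fatigue, lapses, finite display effects,
or image-level stimulus confounds; passing recovery tests therefore
validates the analysis chain under the stated model, not the model itself
against real behaviour.

## Staircase and trial sampling

QUEST maintains a discretised posterior over the threshold on
`x = log10(n_test/N)` (grid ±0.7, step 0.02), assuming a cumulative-Gaussian
kernel with sd β = log10(1.25)/Φ⁻¹(0.75) ≈ 0.144 (the slope implied by
Wf = 0.25), guess rate γ = 0 (a comparative judgment has no chance floor)
and lapse δ = 0.01. Placement uses the posterior mean (mode and quantile are
config options). Each participant × condition × standard runs two
independent 50-trial sessions, pooled for fitting (100 trials per
psychometric function).

The simulator jitters the shown intensity around the QUEST recommendation
with Gaussian sd equal to the kernel width β. This is deliberate: placing
every trial exactly at the tracked 50% point leaves the psychometric *slope*
(hence JND and Wf) nearly unidentified — in development we measured a ~20%
downward bias in fitted σ from unjittered staircases — and spreading
placements by about one kernel width samples the ±1 JND flanks where slope
information is maximal, a standard adaptive-design consideration when the
threshold spread is itself an outcome. The jitter sd is exposed
(`placement_jitter_sd`, set 0 to disable).

Recommended intensities convert to integer test numerosities (half-up,
floor 1); the *shown* intensity `log10(n_test/N)` is what updates the
posterior.

## Psychometric fitting

`PsychometricGaussian` maximises the Bernoulli likelihood of the unbinned
trials over (PSE, σ) with L-BFGS-B from three σ starts, bounded to
PSE ∈ [0.25N, 2.5N] and σ/N ∈ [10⁻³, 2]. Cells with all-identical responses,
σ pinned at its lower bound (step-separated data) or failed optimisation are
flagged `converged_ = False` and excluded downstream with a logged count;
batch fitting also flags cells that fail the ≥20-trials / ≥5-levels
preconditions instead of aborting a whole cohort. There is no lapse
parameter by default (fits are to 100 clean simulated trials); a fixed-lapse
refit is available. Derived indices satisfy `jnd = 0.6745·σ`, `wf = jnd/N`,
`bias = (pse/N − 1)·100` by construction.

Sign convention: an underestimated (symmetric) standard needs fewer test
dots to match, pulling the PSE below N — so underestimation is a *negative*
bias.

## Two-limb Weber fit

`TwoLimbWeber` minimises RSS in log10 Wf with the continuity constraint
built into the parameterisation `y = c − α·max(0, x − log10 N′)`. For each
candidate N′ on a 200-point log grid (8→400), (c, α) solve 2×2 normal
equations in closed form; the profile over N′ takes the global minimum with
ties broken toward smaller N′, α clamped at 0 (the curve never rises), and
all-flat data reported as α = 0 with N′ flagged at the grid's upper edge.
The default target is the group-mean Wf per numerosity (per-participant fits
are available). The profile estimator is exact least squares — verified
against brute-force joint grid search — and its precision is
information-limited by the 8-point design: median relative error in N̂′ is
≈8% at log10 noise sd 0.02 (the group-mean scale for ~19 observers) and
≈21% at sd 0.05.

## Inferential statistics

- `rm_anova2`: two-way fully-within ANOVA from the explicit sums-of-squares
  decomposition, subject×effect interaction error terms. Per-effect
  Greenhouse–Geisser ε from the orthonormal-contrast form
  ε = tr(E)²/(df·tr(E²)), E = MΣM′ — for main effects this equals the
  classic ε of the collapsed subject×factor table. Reports classical
  η² = SS/SS_total (matching small printed effect sizes) alongside partial
  η². Missing cells raise; nothing is imputed. Note the GG-corrected p is
  guaranteed ≥ the uncorrected p only when F is clearly above 1; near F ≈ 1
  the two df reductions can cancel.
- `log10_bf_correlation`: exact default Bayes factor for a correlation from
  summary statistics (r, n), integrating the ρ-dependent part of the
  sampling density of r against a stretched beta(1/κ, 1/κ) prior on
  (−1, 1); κ = 1 (uniform) is the default, matching the convention of
  standard Bayesian-statistics software. The prior width is exposed because
  conventions differ by ~0.05 log units.
- `jarque_bera`: scipy's moment form with an explicit constant-input error
  and a small-sample (n < 30) warning for the asymptotic χ²₂ reference.
- t-tests/post-hocs: scipy, with Cohen's d = (x̄−μ)/s and Bonferroni
  `p_adj = min(1, m·p)`.

## AQ scoring

Binary collapse of the 4-point scale onto the item's autistic-characteristic
pole; total = Σ of five 10-item subscales by construction. The item key and
subscale map ship as an editable JSON data file (they belong to the
published instrument). Threshold semantics: totals *below* 32 are unflagged,
so 32 itself raises the clinical-assessment flag.

## Pipeline

`simulate → fit → regime → stats → report`, each stage resumable from plain
CSV/JSON intermediates; one master seed drives everything and is recorded in
the report. The AQ correlation uses each participant's vertical-condition
bias averaged over the estimation-regime standards (the random condition is
unbiased by construction, so the symmetric-condition bias *is* the symmetry
effect). `reproduce --zenodo-dir` applies the regime fit and the AQ
normality test to a locally supplied copy of the deposited dataset through a
column-mapping config; the package never downloads anything.

## Problem sizes and numerical choices

Recovery tests run 19-participant cohorts through the full Exp-1 design
(30,400 trials) over three master seeds, and 16-participant Exp-2 cohorts
over two; group-mean biases are averaged across seeds before comparison, as
the recovery claims concern expectations over cohorts. Integer rounding of
test numerosities is half-up with floor 1; staircase updates clamp shown
intensities to the grid hull; all optimisers use bounded parameterisations
with explicit degeneracy flags rather than silent clipping.

## Known limitations

- The switching point N̂′ from 8 sampled numerosities is coarse (see above);
  no confidence interval is attached.
- Recovered AQ–bias correlations are attenuated relative to the generative
  target by psychometric measurement noise (reliability ≈ 0.6–0.8 under
  defaults) and are further dispersed by small-cohort sampling error — a
  faithful property of the measurement chain, illustrated in the README's
  worked example.
- The observer has no lapse, sequential dependence, or interval bias;
  `standard_first` is recorded but does not influence simulated behaviour.
- The staircase assumes a fixed kernel slope; gross observer/kernel slope
  mismatch degrades placement efficiency, though fits remain unbiased.
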