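# numerosym

Simulation and analysis of **symmetry-induced numerosity underestimation**
experiments.

When people judge how many dots are in a briefly flashed array, mirror-
symmetric arrangements look *less* numerous than random ones — but only at
moderate numerosities, where items are individually resolvable (the
*estimation* regime). For very dense arrays (the *density* regime) the
illusion largely disappears, and its strength across individuals covaries
with autistic-like personality traits (AQ), consistent with a perceptual-
grouping account. `numerosym` implements the complete measurement chain for
this phenomenon as a tested Python package: stimulus geometry, a generative
observer, the adaptive staircase, psychometric and Weber-curve fitting, the
inferential statistics, AQ scoring, and a synthetic-cohort simulator that
lets every stage be validated by parameter recovery.

## The model

A trial is a two-interval forced choice (2IFC): a *standard* array of N dots
(random or symmetric) against an asymmetric *test* whose numerosity is driven
by a QUEST Bayesian staircase. The proportion of "test more numerous"
responses vs test numerosity is fit with a cumulative Gaussian, giving

- **PSE** — the 50% point (test numerosity that matches the standard's
  apparent numerosity),
- **JND** — the 50%→75% distance, and the **Weber fraction** `Wf = JND / N`,
- **bias** `= (PSE/N − 1) × 100` — negative when the standard is
  underestimated.

Across numerosity, Weber fractions follow a two-regime law,

```
Wf(N) = Wf0                    for N ≤ N′
Wf(N) = Wf0 · (N/N′)^(−α)      for N > N′
```

fit on double-logarithmic coordinates by profiled least squares over the
switching point N′ (Weber's law below N′, approximately a square-root law
with α ≈ 0.5 above). The statistics layer provides the two-way
repeated-measures ANOVA with Greenhouse–Geisser correction,
Bonferroni-corrected post-hoc t-tests, Cohen's d, Pearson correlations, the
Jarque–Bera normality test, and the log10 default Bayes factor for a
correlation (exact integral with a stretched-beta prior on ρ).

## Worked example

Simulate a 19-participant cohort through the full eight-numerosity,
two-condition design (1600 trials per participant) and run the analysis
chain:

```bash
numerosym run --seed 42 --out demo
```

which prints (abridged):

```
Two-limb Weber curve per condition:
condition      wf0  n_switch    alpha
   random 0.243527       105 0.577527
 vertical 0.245214       101 0.532968

Group bias (percent) by condition x regime:
condition     regime      mean
   random    density  0.343103
   random estimation -0.267937
 vertical    density -3.918127
 vertical estimation -6.860033

AQ vs symmetry bias (estimation): r = 0.17, p = 0.477, LBF = -0.44 (n = 19)
```

Reading this: both conditions recover the generative Weber plateau
(Wf0 ≈ 0.25) switching near N′ = 100 into a declining limb (α ≈ 0.5);
random standards are judged veridically while vertically symmetric standards
are underestimated by ≈7% in the estimation regime and ≈4% in the density
regime. The AQ correlation illustrates attenuation: a generative r = 0.51 is
diluted by psychometric measurement noise and n = 19 sampling error (see
`docs/methods.md`).

The same stages are available individually (`numerosym simulate|fit|regime|
stats|report`), resume from cached CSVs, and are thin wrappers over library
functions — `PsychometricGaussian` and `TwoLimbWeber` are scikit-learn style
estimators usable directly:

```python
from numerosym import TwoLimbWeber
fit = TwoLimbWeber().fit([8, 12, 24, 50, 100, 200, 300, 400],
                         [.25, .25, .25, .25, .25, .177, .144, .125])
fit.n_switch_, fit.alpha_   # (101.0, 0.50)
```

`numerosym stimgen --n 48 --symmetry double --out stim.csv` generates the
dot-array geometry itself (exact mirror construction, minimum-separation and
packing-feasibility checks), and `numerosym reproduce --zenodo-dir PATH`
runs the regime fit and AQ normality test on a locally supplied copy of the
deposited study data (nothing is downloaded).

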