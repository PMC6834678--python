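# Methods

## The trafficking model

Exogenous IgG is exchanged between three well-mixed spaces: a central
extracellular compartment (serum; relative volume fixed at `V_c = 1`), a
peripheral extracellular compartment (relative volume `V_p`) and an
endosomal compartment (relative volume `V_e`). Writing the concentration
vector `c = (C_c, C_p, C_e)` in μg/mL, the model is the linear system
`dc/dt = M c` with

    dC_c/dt        = Q (C_p − C_c)
    V_p · dC_p/dt  = Q C_c − Q C_p − Q_u C_p + Q_u C_e f_sort f_release
    V_e · dC_e/dt  = Q_u [ C_p + C_e ((1 − f_release) f_sort − 1) ]

`Q` is the central↔peripheral exchange rate and `Q_u` the cellular uptake
rate, both in central-compartment volumes per hour. Inside the endosome
FcRn binds IgG at acidic pH and sorts a fraction `f_sort` to recycling;
the complement `1 − f_sort` is degraded in the lysosome — the model's
only elimination route. Of the recycled IgG presented at the cell
surface, a fraction `f_release` dissociates at extracellular pH and
returns to circulation; the remainder, the **surface recapture fraction
`1 − f_release`**, is still receptor-bound at neutral pH and is
endocytosed again. Variants that show no measurable receptor binding at
pH 7.4 are therefore modelled with `f_release = 1`.

Assumptions: all rates are linear (no binding saturation, no
target-mediated clearance), parameters do not depend on the IgG
concentration, and the sorting/release fractions are the only
variant-specific parameters — volumes and flows are shared across
variants within a strain. An i.v. bolus puts the whole dose in the
central compartment: `c(0) = (dose/V_c, 0, 0)`.

Useful identities used as test oracles:

* total mass `m = C_c + V_p C_p + V_e C_e` obeys
  `dm/dt = Q_u C_e (f_sort − 1) ≤ 0`, so the system is closed exactly
  when `f_sort = f_release = 1`;
* `M` is a Metzler matrix (non-negative off-diagonal), so trajectories
  started non-negative stay non-negative and the slow mode is a Perron
  mode;
* scaling `Q` and `Q_u` jointly by `c > 0` rescales time by `1/c`, so
  every half-life definition scales by `1/c` (the `Q` and `Q_u`
  elasticities sum to −1).

Propagation uses `scipy.linalg.expm` (scaling-and-squaring/Padé); an
adaptive high-order integrator (DOP853 at `rtol 1e-12`) serves as the
independent oracle in the tests, with agreement required at `1e-8`
relative over 100 random parameter draws and horizons up to 1000 h.

## Two half-life definitions

The package computes both, and keeps them strictly apart:

* **`terminal`** — `ln 2 / |λ_slow|`, with `λ_slow` the rate-matrix
  eigenvalue of smallest magnitude: the asymptotic (β-phase) slope of
  every compartment. Infinite for a closed system.
* **`newton`** — the first time at which `C_c(t)` falls to half its
  bolus value, found by root finding on the matrix-exponential solution
  (Newton with derivative `M e^{tM} c(0)` and a bisection fallback in
  the scalar routine; a bracketed bisection on the eigen-expansion in
  the vectorized likelihood path, with the two paths cross-checked to
  `1e-7` in the tests). This value includes the early distribution
  phase, so it can be much shorter than the terminal value when the
  peripheral space is large.

The likelihood's default is `newton`. The observable being fitted is a
serum half-life obtained by root finding on the model solution, and the
choice is consequential: with the packaged half-life tables the
`terminal` likelihood drives the posterior recapture of the YTE and LS
variants to ≈75–80%, while the `newton` likelihood yields the ≈40–65%
range consistent with the headline recapture estimates this package
reproduces (see `half_life_def` to switch). A system with no
elimination pathway reports an infinite half-life under either
definition and is rejected by the likelihood rather than raising.

Newton settings (scalar routine): relative tolerance `1e-10`, at most
100 iterations, bisection fallback on a bracket found by doubling.

## Priors and inference

Data enter as per-variant half-life summaries (mean, SD, n); each
variant's model half-life is scored against a normal distribution with
the observed mean and standard error `SD/√n` (an SD option exists).

Priors:

| parameter | prior | notes |
|---|---|---|
| `V_p`, `V_e`, `Q` | log-normal, log-location 0, log-scale 1 | volumes relative to `V_c = 1`; rates in `V_c`/h |
| `Q_u` | log-normal, log-location 0.1, log-scale 0.5 | written as mean `e^0.1` on the log scale |
| `f_sort` per variant | flat on [0, 1], totally ordered | order: ascending endosomal (pH 5.8) K_D — the strongest binder gets `U(0,1)`, the next `U(0, f_sort_prev)`, … |
| `f_release` per variant | fixed at 1, or flat-ordered | fixed for variants with no detectable pH-7.4 binding; the free ones ordered by descending pH-7.4 K_D (stronger neutral-pH binder ⇒ smaller release) |

The "log-location 0/1" reading of the volume/flow priors, and reading
the uptake prior's mean as an exponent, are interpretations of a
configuration that could also be parameterized on the natural scale;
both readings were implemented and compared, and the log-scale reading
is the default. One prior label in the source configuration is
ambiguous about whether it refers to the endosomal volume; it is taken
as `V_e`, which then follows the `V_p`/`Q` family by symmetry.

Sampling works in an unconstrained space: logs for the positive
parameters and a logistic stick-breaking chain for each ordered
fraction family (`f_top = σ(u₁)`, `f_next = f_top σ(u₂)`, …). The
stick-breaking Jacobian exactly cancels the conditional-uniform
normalizers, leaving one logistic derivative per stick in the log
prior, so every draw satisfies the box and ordering constraints by
construction (asserted on every draw in the tests). The sampler is the
affine-invariant stretch-move ensemble (`emcee`), run as `n_chains`
independent ensembles; draws are flattened walker-within-move so each
chain keeps temporal order. Runs are bit-reproducible given the seed.

This posterior is a curved ridge (4 observations constrain 10
parameters), and ensemble autocorrelation times reach several hundred
moves. Two measures keep runs inside practical budgets:

* chains start in a Gaussian ball (scale 0.5) around a posterior mode
  located independently per chain by L-BFGS from prior starts
  (`init="map"`), removing most of the burn-in transient; prior-start
  initialization remains available and is the default for prior-only
  runs, which then start at stationarity;
* the default production size is 4 chains × 64 walkers × (8,000
  discarded + 4,000 retained) moves — 256,000 post-warmup draws per
  chain, ≈4 min per strain on one CPU. These sizes were chosen to agree
  with much longer reference runs (20,000+ moves, stretch and
  differential-evolution moves cross-checked) to within ~2 percentage
  points on the recapture summaries.

Convergence reporting: per chain and parameter, an integrated
autocorrelation time (FFT autocorrelation with Sokal windowing, c = 5)
of the walker-averaged trace, and a Geweke z comparing the first 10% to
the last 50% of the retained run with autocorrelation-corrected
variances; |z| < 2 is flagged as passing. On a ridge this sharp the
Geweke flags remain informative rather than universally green at the
production sizes; the recapture summaries are stable at the ~1–2
percentage-point level across seeds and samplers, which is an order of
magnitude below the ±15-point tolerance used for them.

## Sensitivity analysis

At a parameter point the package reports elasticities of the half-life:
`∂ln T½ / ∂ln θ` by central differences for `V_p`, `V_e`, `Q`, `Q_u`,
and the derivative `∂ln T½ / ∂f` for the fractions (one-sided at a
boundary, flagged). Rows are ranked by magnitude.

A structural caveat: fitted sorting fractions sit close to 1 for
long-lived variants, and `∂ln T½ / ∂f_sort` grows like `1/(1 − f_sort)`
there, so on this metric `f_sort` outranks everything near that
boundary. The release fraction is nevertheless the top-ranked parameter
*that differs between the engineered variants and the fully-released
ones* — it is the knob that separates variants with identical sorting
behaviour — which is the sense in which surface recapture limits
persistence. The table reports the raw elasticities and leaves that
reading to the caller; fixed parameters (a pinned `f_release`) are
excluded on request.

## Noncompartmental analysis

Standard linear-up/log-down rules: per interval, the logarithmic
trapezoid `(C₁−C₂)Δt / ln(C₁/C₂)` when concentration strictly decreases
with positive endpoints, the linear trapezoid otherwise; AUMC uses the
exact first-moment integral of the same per-interval model. Censored
(below-LLOQ) samples are excluded from areas and fits. The terminal
window is the last `n ≥ 6` measurable points with `n` chosen to
maximize adjusted R² (smallest window on ties); `λ_z` is the OLS slope
of `ln C` on time, and `AUC_∞ = AUC_last + C_last/λ_z`,
`AUMC_∞ = AUMC_last + t_last C_last/λ_z + C_last/λ_z²`. Clearance is
`Dose/AUC_∞` and `V_ss = Dose·AUMC_∞/AUC_∞²`; `C_max` is the observed
maximum. Times are hours internally; areas and rates are per day
(1 day = 24 h, converted explicitly). Doses are stored per kg, so
clearances are mL/day/kg; cross-variant **ratios**, which are
unit-free, are the quantities validated against the packaged summary
tables.

The two-phase fit `C(t) = A e^{−αt} + B e^{−βt}` (α > β enforced) is
nonlinear least squares on log-concentration, initialized by curve
stripping; a fit is declared degenerate when the rates are within 20%
of each other or one amplitude collapses below `1e-6` of the other.

## Binding and spectral assays

* **Steady-state SPR**: `R(C) = R_max C/(K_D + C)` fit by unweighted
  least squares on untransformed responses; 95% CIs from the linearized
  covariance with a t quantile on `n − 2` degrees of freedom. The CI is
  calibrated under the fit's own error model (homoscedastic additive
  noise — verified by a coverage simulation); under strongly
  multiplicative noise it undercovers, a documented limitation of the
  unweighted convention. All-zero responses are reported as
  non-detectable rather than fitted; a `K_D` more than 100× outside the
  concentration range is flagged.
* **1:1 binding kinetics**: association
  `R(t) = R_eq (1 − e^{−(k_a C + k_d)t})` with
  `R_eq = R_max C/(K_D + C)`, dissociation `e^{−k_d t}`; `K_D = k_d/k_a`
  consistent with the equilibrium model by construction. True
  mass-transport-limited models are out of scope.
* **pH-normalized binding**: response at a given pH over the maximal
  response at pH 6.0, clipped below at zero.
* **Percent lysis**: `100 (E − S)/(M − S)`; invariant under common
  shifts of all three fluorescence readings; rejected when `M = S`.
* **Plasmon wavelength**: least-squares quadratic over the window of 20
  points on each side of the absorbance argmax (ties broken toward the
  lower wavelength, window truncated at spectrum edges), peak at the
  vertex `−b/2a`; non-concave fits are rejected. The vertex is
  invariant under affine transforms of the absorbance scale.

## Synthetic data

`StudyDesign` emulates a bolus PK study: 2 mg/kg i.v. dose (converted
to an initial serum concentration with a nominal 50 mL/kg plasma
volume, i.e. C₀ = 40 μg/mL), sampling at 1 h, 6 h and days 1, 2, 4, 7,
10, 14, 21, 28 (chosen so that at least six measurable terminal points
exist; configurable), per-animal multiplicative log-normal noise with
`σ = ln(1 + CV²)^½` so the simulated CV equals the design CV, and
censoring flags set exactly when a value falls below the LLOQ. Truths
can be biexponential curves or trafficking-model parameter sets.
Isotherm and spectrum simulators produce 1:1 Langmuir responses on the
two-fold 1000→40 nM ladder and Gaussian absorbance bands on the
450–650 nm, 1 nm grid.

What the generator does **not** emulate: between-animal parameter
variability, correlated within-animal assay errors, assay
standard-curve nonlinearity, FcγR-mediated clearance and endogenous-IgG
competition (these appear only implicitly through strain-specific
fitted parameters). Passing recovery tests therefore demonstrate
estimator correctness under the stated noise model, not robustness to
those real-data features.

Packaged fixtures (half-life, affinity and PK summary tables) are small
CSVs carrying a `study` column naming the source study/strain.

## Known limitations

* With four observed half-lives and ten parameters the posterior is
  strongly prior-influenced; the recapture marginals are the robust
  summaries, the volume/flow marginals are not individually
  identified.
* The ordering constraints force the model's YTE half-life to be at
  least the LS one; one packaged table trends the other way, so the fit
  compresses the two variants' parameters together there, and the
  posterior-mean recapture for that strain (≈40%) sits well above the
  ≈20% headline figure. The bound is structural: with a half-life
  ratio `T_DHS/T_YTE = r` the YTE loss probability per endosomal pass
  must exceed the DHS one by ≈`r`, which forces recapture
  ≳ `(1 − 1/r)/f_sort` — about 38% for that table — under every
  definition and prior reading tried. An unordered-release option is
  provided for exploring this.
* The CLI's `fit-trafficking` posterior CSV at production sizes is
  ~100 MB; use `--samples` to thin when only summaries are needed.
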