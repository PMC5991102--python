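# Methods

## The model

`allokit` implements the thermodynamic description of the simple repression
motif with an allosteric (MWC) repressor. The promoter can be empty, bound by
RNA polymerase, or occluded by a repressor; the repressor itself fluctuates
between an active conformation that binds its operator with energy
Δε_RA (relative to the non-specific genomic background of N_NS = 4.6×10⁶
sites) and an inactive conformation that binds negligibly. Inducer at
concentration *c* binds the two conformations with dissociation constants K_A
and K_I; the zero-inducer conformational equilibrium is set by
Δε_AI = ε_I − ε_A. The active fraction is

    p_A(c) = (1 + c/K_A)^n / [ (1 + c/K_A)^n + e^(−Δε_AI) (1 + c/K_I)^n ]

and, under the weak-promoter approximation, the fold-change in expression is

    fold-change = [ 1 + p_A(c) (R/N_NS) e^(−Δε_RA) ]^(−1).

All energies are dimensionless multiples of k_BT (β = 1 internally);
concentrations are molar everywhere inside the library, with unit-suffixed
strings (`"500 uM"`) accepted at the CLI/file boundary. R counts repressor
**dimers** (twice the tetramer count for a dimer-of-dimers protein), and this
convention is stated at every I/O boundary.

The five phenotypic properties — leakiness, saturation, dynamic range, EC50,
effective Hill coefficient — have closed forms. The EC50 closed form is the
primary implementation and is verified against a bisection root of the
midpoint equation to relative 1e−8. The effective Hill coefficient is twice
the log-log slope of the normalized response at the EC50, computed by central
finite difference with relative step 1e−6 in ln c and verified against
symbolic differentiation. Both are undefined (raising a diagnostic
`FlatResponseError`) when the dynamic range is below 1e−4, mirroring the
weak-operator/low-copy pathology where the midpoint is unidentifiable.

The dynamic-range peak over repressor number was re-derived here because the
radical signs did not survive the source text extraction: the peak sits at
repression strength ρ* = 1/sqrt(p_A(0)·p_A(∞)) with magnitude
(sqrt(p_A(0)) − sqrt(p_A(∞)))² / (p_A(0) − p_A(∞)), which is manifestly
independent of Δε_RA (the operator only shifts the peak location). The
implementation reproduces the printed independence property to 1e−12 and the
brute-force grid argmax.

The free energy (Bohr parameter)
F(c) = Δε_RA − log p_A-term − log(R/N_NS) satisfies
fold-change = 1/(1+e^(−F)) to machine precision; this identity is what makes
all 216 design points collapse onto one master curve.

### Numerical fine print

- "Saturating" concentration for numeric limit checks is c = 10⁴·K_A. The
  saturation asymptote is approached like ~n·(K_A/K_I)/10⁴ in relative
  terms (≈1e−4 at the fitted parameters), so numeric limit tests use a
  relative tolerance of 1e−3; the closed forms remain primary.
- c = 0 is a valid input on every code path (no log-of-zero).
- The four-state `fold_change_exact` (RNAP term P·e^(−Δε_P)/N_NS and
  inactive-repressor binding Δε_RI included) converges to the weak-promoter
  form when P·e^(−Δε_P)/N_NS ≪ 1 and Δε_RI is large; since Δε_P is only
  known to lie in roughly −2 to −5 k_BT, the approximation tests exercise the
  stated magnitude P·e^(−Δε_P)/N_NS ≈ 10⁻² rather than a point value.

## Multi-promoter (fugacity) model

With N identical specific sites competing for R_tot repressors, the fugacity
λ_r = e^μ distributes the **active** pool over specific and non-specific
sites: p_A(0)·R_tot = N·w/(1+w) + N_NS·λ_r/(1+λ_r) with w = λ_r e^(−Δε_RA),
and fold-change = 1/(1+λ_r e^(−Δε_RA)). As printed in the source material the
conservation relation carries the factor 1/(1+e^(−βΔε_AI)) on both sides
(which would cancel); we solve the physical reading in which only the active
fraction partitions, which is also the reading the downstream inference
requires. The root is found by bisection on ln λ_r over [1e−15, 1e6]
(monotone conservation gap ⇒ unique root; scalar path uses Brent to relative
1e−12, the vectorized path 100 bisections).

Historical binding energies fitted under the all-active assumption are
convoluted values Δε̃_RA with βΔε_RA = βΔε̃_RA + log p_A(0); the conversion
round-trips to 1e−12.

Fitting Δε_AI to repression-versus-copy-number curves uses the same Gaussian
likelihood as the induction fits, with a uniform prior on Δε_AI over
[−2, 12] k_BT and a Jeffreys prior on the noise scale. Above ≈5 k_BT
essentially all repressors are active and the data can only bound Δε_AI from
below; results whose mode or upper credible bound reaches that regime are
flagged `lower_bound_only`. Note the identifiability is intrinsically
asymmetric even at 4.5 k_BT: with 1% noise the likelihood falls off sharply
below the truth but is nearly flat above ~5, so recovery tests assert the
mode within 0.5 k_BT and coverage of the credible interval rather than a
tighter symmetric bound.

## Bayesian inference

The measurement model is iid Gaussian noise of unknown scale σ on
fold-change (deliberately not truncated to [0, 1]; negative observations are
retained). Dissociation constants are sampled as k̃ = −log₁₀(K/1 M) with
uniform priors on [−7, 7] — base 10, since the printed prior range contains
the fitted −log₁₀ values but not the natural-log ones. σ carries a Jeffreys
prior, implemented by sampling log₁₀σ uniformly on [−5, 0].

Sampling uses an in-package seeded affine-invariant ensemble sampler
(Goodman–Weare stretch moves, a = 2) with vectorized batch evaluation of the
log posterior over half-ensembles. Contract: recorded seed, walker ensemble,
split-R̂ < 1.1 and bulk ESS ≥ 400 per parameter (computed with arviz,
treating walkers as chains) before any summary; a `ConvergenceWarning` is
emitted if the contract is not met. Defaults per model (walkers ×
burn-in/kept steps): single-strain 64×600/800, global 4·ndim×3000/1500,
Hill 64×1500/2500, Hill-thermo 64×2000/3000, Δε_AI 24×400/700 — all give
≥10⁴ post-warmup draws and pass the contract on the synthetic reference
data. Walker ensembles are initialized in a tight ball around a multi-start
Nelder–Mead point estimate; without this, isolated walkers occasionally
strand in a far-off flat-likelihood region (e.g. "midpoint far above the
measured concentration window") and stall R̂.

Two deliberate prior restrictions stabilize the phenomenological fits: the
Hill midpoint K (and Hill-thermo K_D) is restricted to the measured
concentration window ± one decade (a midpoint outside the data cannot be
identified and only feeds a junk mode), and the Hill-thermo saturating
active fraction p_A_min = p_A_max − p_A_range is sampled as log₁₀ p_A_min
because it spans decades.

Point estimates: the **reported** per-parameter estimate is the maximizer of
a Gaussian KDE on each marginal, with equal-tailed 2.5/97.5 percentile
bounds (equal-tailed was chosen where the source left the interval type
unstated). **Predictions**, however, use the single highest-posterior draw
(`map_params`): marginal modes of a correlated posterior need not be jointly
coherent, and using them for prediction produced visibly wrong transfers in
the Hill-thermo model during development.

Degeneracy: a single strain cannot identify (K_A, K_I, Δε_AI) jointly. The
`degeneracy_scan` fixes Δε_AI on a grid, corrects the convoluted binding
energy accordingly, and shows the conditional best fits are equally good
(residuals within twice the generating noise). For data generated with
K_A = K_I (a flat response) the posterior admits the whole flat-response
ridge — K_A ≈ K_I at any magnitude, or both constants outside the measured
window with arbitrary ratio — so the individual constants span essentially
the full prior. Tests assert that structure rather than the idealized claim
that the ratio alone concentrates at 1, which does not hold under bounded
uniform priors.

Property propagation pushes every posterior draw through the closed-form
properties; draws on which a property is undefined (flat response) are
excluded and counted. For a nearly-flat strain this yields the expected
wide, strongly right-skewed EC50 interval.

## Gating

Cytometry-like event tables (fsc, ssc, fl) are gated by fitting a bivariate
Gaussian to (log₁₀ fsc, log₁₀ ssc) by sample moments and keeping events with
Mahalanobis squared distance ≤ χ²₂(α) = −2 ln(1−α), default α = 0.4. Events
with non-positive scatter are dropped (counted) before the log transform;
fewer than 100 gateable events or a singular covariance is an error naming
the offending channel. Moments (not EM / robust estimators) follow the
single-Gaussian description; contamination is assumed to be a minority.

One property worth knowing: gating is *not* idempotent under moment
refitting. Conditioning on the ellipse truncates the distribution, the
refitted covariance shrinks by k = E[d²|d²≤t]/2 ≈ 0.234 at α = 0.4, and a
second pass retains (1−e^(−tk/2))/α ≈ 0.281 < α. The test suite asserts this
derived value.

Fold-change from events gates the sample, the no-repressor control and the
autofluorescence control independently, subtracts the autofluorescence gated
mean from both signal means, and returns the ratio
(`subtract_autofluorescence=False` restores the literal uncorrected ratio,
since the source describes measuring the autofluorescent strain but not the
correction formula). A constitutive signal at or below background is an
error, not a silent negative.

## Synthetic data

The generator states the measurement design it emulates: R ∈ {22, 60, 124,
260, 1220, 1740} dimers/cell × operators O1 (−15.3), O2 (−13.9), O3 (−9.7
k_BT) × 12 IPTG concentrations (0 plus 11 log-spaced points from 10⁻⁷ M to
5×10⁻³ M — the exact printed concentrations are not available, so the grid
is an artifact decision covering the stated 0–5 mM range with the zero point
plotted-below-10⁻⁷ convention), one replicate by default, iid Gaussian noise
σ = 0.02 on fold-change (chosen once to match the plotted SEM scale of the
reference data). That yields the 216 (strain, concentration) points of the
full design. Noise is not truncated, matching the inference likelihood.

Event tables come from a 2-D log-normal scatter model plus an optional
uniform contamination cloud; fluorescence is background plus
fold-change × expression scale × a unit-mean log-normal factor (cv = 0.25).
What a green test establishes: the pipeline recovers what this model
generates; it does not establish robustness to instrument artifacts (PMT
saturation, drift, doublets beyond the ellipse), which the generator does
not emulate.

Multi-promoter titrations use N ∈ {10, 52, 64} (plasmid-like copy numbers)
with a log-spaced R_tot grid straddling the p_A(0)·R_tot = N transition —
the transition is the entire information content for Δε_AI, and a grid dense
around it (40 points per curve in the tests) is what makes the 1%-noise
recovery meaningful.

Same seed ⇒ byte-identical outputs, everywhere.

## Known limitations

- The weak-promoter approximation is the working model; the exact four-state
  form is provided for checking it, not fitted.
- Activation, DNA looping, multi-operator architectures and expression-noise
  modeling are out of scope; corepression (K_I > K_A) works through the same
  formulas but has no dedicated property operations (no interior
  dynamic-range peak exists there).
- The grand-canonical model treats plasmid copy number as fixed; copy-number
  variability across the population is not modeled.
- Binary cytometry formats are not parsed; convert to CSV (fsc, ssc, fl)
  with external tools first.
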