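# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each analysis stage, and what the synthetic-data
generators do and do not emulate.

## Interfacial (surface-dilution) kinetics

**Model.**  A phosphatase acting on vesicle-embedded substrate binds the
membrane (dissociation constant `Ks`, µM bulk) and then engages substrate
within the interface (interfacial Michaelis constant `iKm`, mol%):

    V0 = Vmax·Xs·S0 / (iKm·Ks + iKm·S0 + Xs·S0),  Vmax = kcat·[E]T.

Holding `Xs` fixed and titrating `S0` (bulk dilution, BD) or vice versa
(surface dilution, SD) produces rectangular hyperbolas with closed-form
apparent parameters:

| design | Vmax_app | Km_app |
|---|---|---|
| BD (Xs fixed) | `Vmax·Xs/(iKm+Xs)` | `iKm·Ks/(iKm+Xs)` (µM) |
| SD (S0 fixed) | `Vmax` | `iKm·(Ks+S0)/S0` (mol%) |

The combining equations invert this: `iKm = (Vmax_SD/Vmax_BD − 1)·Xs`,
`Ks = Km_BD·(Xs/iKm + 1)`, `kcat = Vmax_SD/[E]T`.  The last is division by
the enzyme concentration on dimensional grounds (µM/min divided by µM gives
min⁻¹); sources sometimes print it as a multiplication, which cannot be
dimensionally correct.

**Units.**  `Xs` is mol% (0–100) everywhere internally; the CSV loader
accepts mole fraction (0–1) via an `Xs_unit` column and converts on ingest.

**Substrate inhibition.**  SD curves commonly bend down at high mol%.  No
inhibition term is fitted; instead the analysis keeps the `n_keep` lowest
distinct surface concentrations (default 4, configurable) and fits the
hyperbola to that limb.  Decreasing data passed to the apparent fit raise an
error that points at the truncation step.

**Fitting.**  Unweighted nonlinear least squares (optional 1/V² weighting),
initial guesses from the Hanes linearization `x/V = x/Vmax + Km/Vmax`,
gradient tolerance 1e-12, parameters bounded positive.  Velocities that are
negative after blank subtraction are clipped to zero with a logged warning
rather than dropped.

**Uncertainty.**  Combined parameters carry first-order delta-method SEs
using both apparent fits' standard errors and each fit's internal
Vmax/Km covariance (BD and SD fits are independent experiments).  A
replicate-resampling bootstrap (`bootstrap_interfacial`, seeded) is the
alternative when the fits are strongly nonlinear; single-dataset combined
estimates — especially `iKm`, a difference of two fitted plateaus — scatter
at the tens-of-percent level at 5% assay noise, which is why recovery is
assessed as a mean over many seeded repeats.

## Soluble-substrate kinetics

`V = kcat·[E]T·S/(Km+S)` fitted with bounded least squares.  When the Km
estimate exceeds 5× the largest assayed substrate concentration the fit is
rejected as saturation-free and the caller is directed to the
linear-efficiency estimator: the slope of V vs S through the origin with
1/S² weighting (equivalently the mean of V/S), divided by `[E]T`.  That
weighting matches the multiplicative error structure of the assays and
minimizes the low-substrate truncation bias; it equals `kcat/Km` in the
S ≪ Km limit.  Applicability is guarded by an F-test (α = 0.05) of the
one-parameter line against the two-parameter hyperbola; significant
curvature raises an error instructing a full fit.  Efficiencies are
reported to 2 significant figures in summary tables, with delta-method SEs
that include the kcat/Km covariance.

**IC50.**  `activity = bottom + (top−bottom)/(1 + [I]/IC50)`, Hill fixed at
1 unless freed; `top` anchored to the mean uninhibited activity unless
freed; `bottom ≥ 0`.  Designs require ≥ 5 concentrations spanning ≥ 2 log
units including a zero control.  A response whose logistic fit does not
significantly beat a flat mean (F-test, α = 0.05) is returned as a
"no inhibition" result (IC50 = ∞), since inactive control peptides are an
expected outcome, not an error.

## Protection kinetics and conformational equilibrium

Dephosphorylation of the tail phospho-cluster by a probe phosphatase follows
`F(t) = F0·exp(−k·t)`; `F0` is fitted within [0.8, 1.2] to absorb
blot-loading variation (intensities are assumed background-subtracted and
normalized to the t = 0 band upstream).  Fits with less than ~5% decay over
the observed window are flagged `no_decay` with `k` pinned at its lower
bound; windows shorter than half a fitted half-life warn about wide
confidence intervals.

Pseudo-first-order linearity in the probe justifies
`k_norm = k·ref_conc/CIP_conc`.  With a fully exposed reference (denatured
protein), the rate ratio `r = k_open/k_native` gives the protection factor.
Two conventions are always reported: the headline rate-ratio convention
closed:open = r:1, and the exact occupancy model `k_native = f_open·k_open`,
which gives closed:open = (r−1):1 and `f_open = 1/r`.  They agree for
r ≫ 1; the summary table carries both.  A ratio below 1 (state more exposed
than the reference, as for destabilizing mutants) sets a `destabilized`
flag rather than raising.

## Vesicle co-sedimentation

`fraction_bound = pellet/(pellet+supernatant)`, scale-invariant by
construction.  Replicates are combined as the mean of per-replicate
fractions.  Each titration of anionic lipid content is fitted with a
descriptive saturable hyperbola `f = fmax·c/(c50+c)` — interpolation
plumbing that smooths blot noise, not a mechanistic isotherm — and
matched-binding compositions are read off by inverse interpolation
(`c = c50·f/(fmax−f)`).  Flat or decreasing series return a `poor_fit`
result instead of raising; pellet-wash protein loss is assumed negligible
(no recovery correction).

## SAXS shape descriptors

**Guinier.**  Weighted fit of ln I vs q² (weights I/σ, since
d ln I = dI/I) over the largest low-q window with qmax·Rg ≤ `qRg_limit`
(default 1.3, the standard validity bound for globular particles), iterated
to self-consistency.  On low-noise data the q⁴ deviation from the pure
Guinier law biases Rg upward by ~2% at qRg = 1.3; when that curvature is
statistically significant (|c₂| > 2 SE) a q⁴ nuisance term is included and
Rg taken from the q² coefficient, which removes the bias on analytic test
bodies while leaving noisy fits untouched (flagged `curvature_corrected`).
Positive slopes (aggregation-like upturns) raise; flat profiles return
Rg = 0 with a `point_like` flag.

**P(r).**  The Debye integral `I(q) = 4π∫₀^Dmax P(r)·sinc(qr) dr` is
discretized on a uniform 201-point r-grid (trapezoid quadrature) with
P(0) = P(Dmax) = 0 imposed exactly, and solved by least squares with a
second-difference roughness penalty.  The penalty weight α is dimensionless:
it is scaled internally by the ratio of the data-matrix and penalty-matrix
norms, so α = 1 is a sensible default and halving/doubling it moves the
real-space Rg by < 1% on test bodies.  Negative P values are suppressed by
an iterative soft penalty of weight 10α (not a hard constraint).  An
L-curve corner scan (`choose_alpha`) is available when a data-driven α is
preferred over the reproducible fixed default.  `Rg_real² = ∫r²P/(2∫P)`;
`I0 = 4π∫P` is checked against the Guinier intercept.

**Dmax.**  Candidate dimensions are scanned; each regularized solution is
scored by log-scaled normalized χ², a roughness penalty, and a small
parsimony term proportional to the candidate (weight 0.05).  χ² spans
orders of magnitude below the true dimension and plateaus above it, so the
log keeps the knee sharp while the parsimony term selects the smallest
adequate dimension; without it the argmin on the plateau is ill-posed.
Scores minimized at the scan boundary or monotone across it trigger a
range warning.  On the analytic sphere (Dmax = 2R) the estimate lands
within ~2%; on a two-sphere dumbbell, whose P(r) tail carries ~0.1% of the
mass near Dmax, regularization trades that tail away and the estimate runs
~5–7% low — an inherent softness of regularized indirect transforms for
shallow-tailed shapes, tested at a 10% tolerance.

## Synthetic data

Generators are pure functions of (parameters, seed); seeds are mandatory
and there is no global random state.  Zero-noise outputs lie exactly on the
forward models.  Defaults emulate the assay designs the analyses expect:
three experiments in duplicate; multiplicative Gaussian noise with 5% CV (a
typical precision for these assay types; true per-assay CVs are not
published); BD at fixed 1 mol%, SD at fixed 50 µM; an optional
surface-dilution inhibition artifact `1/(1+((Xs−x₀)/x₀)²)` beyond the
fourth-lowest level; Poisson-like scattering noise with σ ∝ √I (a nominal
1%-scale σ is attached to zero-noise curves so χ² weighting stays defined).
Scattering bodies are the uniform sphere and a two-sphere dumbbell, chosen
because they have closed-form intensities and known Rg/Dmax.

What the generators do **not** emulate: systematic densitometry
nonlinearity, baseline drift and blank-subtraction artifacts, vesicle size
and lamellarity heterogeneity, inter-day batch effects, and instrument
smearing of scattering curves.  Passing recovery tests therefore
demonstrates estimator correctness and calibration under the stated noise
model, not robustness to those real-data systematics.

## Problem sizes

Recovery statistics average 500 seeded simulations per quantity (200 for
in-suite variants of the same checks); scattering analyses use 240-point
curves, a 201-point r-grid (151 during Dmax scans) and 25-candidate scans.
These sizes give sub-percent Monte-Carlo error on the reported means while
keeping the full suite and the acceptance script fast on one CPU.

## Known limitations

- The interfacial model treats membrane binding through the single constant
  `Ks`; vesicle geometry, size distributions and binding isotherms beyond
  `Ks` are out of scope, as is the mechanism of anionic-lipid stimulation
  (available only as a synthetic scenario).
- Inhibition mode (competitive vs mixed) is not discriminated; the IC50 is
  descriptive.
- Protection fits are single-exponential; site-resolved dephosphorylation
  among the four tail phosphosites is not modeled.
- P(r) inversion assumes an isotropic, monodisperse particle and no
  instrumental smearing.
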