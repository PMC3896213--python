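# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package, in the package's own words.

## Model structure

The afferent is modelled as a chain of three stages sharing one 1-kHz
time grid: skin mechanics (probe displacement → strain energy density,
SED), cluster-level mechanotransduction (SED → receptor current per
spike initiation zone), and a coupled array of leaky integrate-and-fire
(LIF) zones with antidromic resetting (currents → merged spike train).
SED is treated as spatially uniform across the end organ: the 3-mm probe
is some thirty times wider than a mouse touch dome, so every cluster
sees the same mechanical drive and arbors differ only in how many
transduction units converge on each zone.

## Skin surrogate

The full finite-element treatment of layered skin is deliberately
replaced by a uniaxial two-column surrogate, because the downstream
model consumes only a single uniform SED signal.  Commanded depth is
split by force balance between an incompressible Mooney–Rivlin tissue
column (C10 = 14 847 Pa, C01 = 41 410 Pa, thickness 342 µm = 17 µm
epidermis + 224 µm dermis + 101 µm subcutis) and a linear-elastic
substrate column (E = 906 098 Pa, default thickness 2000 µm).  The
nominal Mooney–Rivlin stress `2(λ − λ⁻²)(C10 + C01/λ)` is matched to the
substrate stress by Brent root finding; the tissue
column's strain energy density `W = C10(I₁−3) + C01(I₂−3)` is the
elastic SED.  Substrate thickness is not a measured quantity; 2000 µm
keeps the surrogate physical at depths (up to 0.36 mm) that exceed the
tissue stack, and it is exposed in configuration.  Probe friction (0.3)
and diameter (3 mm) are recorded for provenance but play no role in a
uniaxial model.

Viscoelasticity follows the quasi-linear form: the elastic SED history
is convolved with the reduced relaxation function
`G(t) = g∞ + g₁e^(−t/τ₁) + g₂e^(−t/τ₂)` (g₁ = 0.391, τ₁ = 0.25 s,
g₂ = 0.226, τ₂ = 9.371 s, hence g∞ = 0.383).  The Prony time constants
are interpreted in seconds: 0.25 s and 9.37 s bracket the rapid
adaptation and slow relaxation seen over a 5-s hold.  Each Prony branch
is advanced by the standard recursive exponential update (cost linear in
samples); tests verify agreement with direct quadrature of the
hereditary integral to 0.1%.

Known gap: the surrogate's SED at the end organ is smaller than what a
2-D axisymmetric finite-element model concentrates beneath the probe
(plateau SED here is ~6 kPa at 0.36 mm).  Fitted gains absorb most of
the scale change, but relative static-phase effects of grouping changes
come out smaller than with a full FEM skin stage (see Limitations).
Users with FEM output can import SED traces via `read_sed_trace` and
bypass the surrogate entirely.

## Transduction and noise

`I(t) = β + M(αε + λ·dε/dt) + ω(t)` per cluster.  The derivative is a
per-sample backward difference in Pa/ms, so λ's units (mA·ms/Pa) need no
conversion on the 1-ms grid.  ω is drawn independently per cluster
(matching the position of ω outside the M-parenthesis) and is not scaled
by M; a configuration switch shares one series across clusters instead.
Gaussian deviates come from a hand-rolled Box–Muller transform (the
method is part of the model definition), smoothed by a centered 7-point
moving average with shrinking windows at the edges; the average reduces
interior variance by exactly 1/7, and traces are ≥5000 samples long so
edge effects are negligible.

σ (the pre-averaging standard deviation) is not a measured quantity; it
exists to reproduce the irregular static-phase inter-spike intervals of
SAI afferents.  It was calibrated once, before any acceptance
measurement, by fitting the {8,5,3,1} model at each σ in
{2, 5, 8, 12}·10⁻⁹ mA and checking the pooled normalized-ISI
coefficient of variation; every candidate landed in the admissible
0.3–0.8 band (CV 0.70–0.79), so the pre-registered default of
**8·10⁻⁹ mA** was kept.  σ is held fixed during fitting and never
co-fitted.

## Spike initiation

Each zone integrates `RC du/dt = −u + RI(t)` by RK4 with the current
held constant over each sample; with τ = 5 ms and C = 10⁻⁸ mF,
R = τ/C = 5·10⁸ Ω, so mA-scale currents map to tens of mV against the
30-mV threshold.  A threshold crossing at any zone records a spike at
the end of the integration step, resets all zones to 0 mV (antidromic
invasion) and suspends integration for the shared 1-ms absolute
refractory period (a flag switches to integrate-through-refractoriness
instead).  Simultaneous crossings are resolved by largest overshoot,
ties by lowest zone index — deterministic and seed-independent.  Spike
times live on the integration grid: there is no sub-step interpolation,
so ISI resolution equals the step.  At the default 1-ms step the ISI of
a constant-drive zone is accurate to one sample; accuracy tests
subdivide the step (`substeps = 10–20`), where RK4 matches the closed
form `ISI = t_ref + τ ln(RI/(RI − v̄))` to better than 2%.  Conduction
delays between zones are zero; the cable module's report shows branch
travel times are two orders of magnitude below the refractory period.

## Fitting

The combined fractional sum of squares scores static (hold) and ramp
phases separately against the prototypical target, each normalized by
the target's sum of squares about zero, so a perfect model scores 2.
Repetitions are averaged before the score: each of the 15 unique
stimulations is simulated five times and the mean rate stands in for its
five indexed entries (their target values are identical).  Noise stays
on during fitting — with the fixed LIF constants a noise-free model
cannot fire at the prototypical static rates of 2–12 Hz at all, because
the deterministic LIF rate falls off a cliff below rheobase — and noise
series are drawn once per (stimulus, repetition, zone) and reused across
parameter evaluations (common random numbers), which makes the
stochastic objective a fixed deterministic function during the search.

The search is gradient-free response-surface methodology over
(β linear; α, λ in log₁₀).  Implementation choices beyond the named
structure, made once and recorded here:

* **Operating-point reparametrization.**  β and α trade off along a
  near-flat ridge (both shift the static drive's distance to threshold),
  so the search runs over `c = β + αK` with `K` = primary cluster size ×
  mean static-window SED; β is recovered as `c − αK`, clipped to its
  bounds.  This aligns the ridge with a coordinate axis.
* **Profiled domain design.**  The 50-point domain stage samples (α, λ)
  by Latin hypercube and bisects `c` (11 steps) so the mean simulated
  static rate matches the mean static target — the admissible operating
  points occupy a thin slab that plain 3-D space filling rarely hits.
* **Multi-start refinement.**  The five best domain points each seed a
  track of iterated 20-point Latin-hypercube designs with region shrink
  0.65 per iteration (the first region is narrow along `c`, half-domain
  along the gains), up to 20 iterations, stopping after 3 consecutive
  stagnant designs (improvement < 10⁻⁴).  The global incumbent is never
  discarded.  Default bounds: β ∈ [10⁻⁸, 6·10⁻⁸] mA (capped below
  threshold/R so the offset alone can never fire), α ∈ [10⁻¹⁶, 10⁻¹²]
  mA/Pa, λ ∈ [10⁻¹³, 10⁻⁹] mA·ms/Pa.

With this schedule the fit is reproducible across seeds (combined score
1.94–1.95, spread < 0.01 over six seeds for the {8,5,3,1} reference
model) and noise-free parameter-recovery experiments return the
generating (β, α, λ) to within ~7%.

## Synthetic study inputs

The prototypical target response is built from linear regressions of
rate vs displacement: one ramp regression per acceleration
(slope/intercept 150/5, 300/10, 700/20 Hz·mm⁻¹/Hz for 20, 81,
1143 mm·s⁻²) and one pooled static regression (30 Hz/mm, 1 Hz),
evaluated at the 5 × 3 × 5 protocol and clipped at zero.  These
coefficients are synthetic configuration values chosen to be
qualitatively consistent with published mouse SAI displacement–response
data (static rates of a few to ~12 Hz across 0.04–0.36 mm; ramp rates
rising steeply with acceleration); they are not measurements, and every
quantitative result downstream of them is conditional on this synthetic
target.  The five fitting depths {0.04, 0.12, 0.20, 0.28, 0.36} mm are
evenly spaced across the published stimulus range.

Synthetic arbors are drawn by rejection sampling: zone count uniform in
3–5, total units uniform in 13–20, units partitioned uniformly at
random, accepted when the skew magnitude (|OLS slope| of cluster size vs
rank) falls in 0.6–4.5 (cap 10⁴ attempts).  The pooled cluster-size
median of the sampled population lands inside the anatomically observed
1.2–4.4 interquartile envelope; the generator emulates ranges and
summary statistics, not the exact histograms, chains of Merkel cells
along single neurites, or any 3-D geometry.

## Response statistics

Ramp rate = spikes in [0, t_ramp)/t_ramp; static rate = spikes in the
final 2.5 s of the 5-s hold / 2.5 s (placing the window at the end of
the hold maximally excludes rapid adaptation).  Displacement–response
relations are fitted with `rate = Y0·e^(κD)` by nonlinear least squares
(Y0 ≥ 0; log-linear initialisation), and pairs of fits are compared with
extra-sum-of-squares F tests for a shared κ or shared Y0 (full model 4
parameters, nested model 3).  Percent firing-rate change between two
configurations is the difference of summed static-phase rates divided by
the smaller sum (always ≥ 0; a signed variant reports direction); the
static phase is used because the structural comparisons concern
sustained firing.  "Suprathreshold depths" are those with positive mean
static rate in the reference configuration.  Normalized ISIs divide each
static-phase interval by the mean interval of its stimulus; the pooled
sample has mean 1 by construction.

## Problem sizes

Default runs use the full 75-stimulation protocol at 1 kHz (5-s holds,
≈5000–5200 samples per trace).  A model fit costs ≈700 objective
evaluations of 75 simulations each (the LIF kernel is numba-compiled);
the complete acceptance run — four fits plus all surveys — takes about
two minutes on one CPU.  Tests use a reduced protocol (three depths, one
acceleration, 2.5-s hold) wherever full resolution is not the point.

## Limitations

* The skin surrogate reproduces the viscoelastic time course but not the
  absolute SED scale of a contact-mechanics FEM; static-phase grouping
  effects (percent change when units move between clusters) come out
  roughly 2–3× smaller than with the original skin stage, though every
  sign and ordering prediction (driver effect, secondary-fill advantage,
  skewed-arbor sensitivity) holds.  The SED-trace import path exists
  precisely so a user with FEM output can remove this gap.
* Transduction is phenomenological — no channel kinetics, no per-complex
  heterogeneity; zones are points — no cable dynamics beyond the
  closed-form justification checks.
* Spike times are quantized to the integration grid (1 ms by default).
* The synthetic prototypical response stands in for regression
  coefficients that are not recoverable from published material; passing
  tests demonstrate internal consistency of the pipeline and the
  structural predictions, not agreement with any particular biological
  recording.
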