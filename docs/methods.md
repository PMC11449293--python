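# Methods

## Model

### Agonist field

The uncaging flash (~200 ms) is treated as instantaneous at t = 0: it is
short compared with every diffusion timescale in the problem, so no source
term persists during the flash. The released ADP profile is the free 2-D
diffusion of a Gaussian peak,

    C(r, t) = ADP0 · t0/(t + t0) · exp(−r² / (4 D (t + t0))),

radially symmetric about the spot center. The characteristic time
t0 = (d/2)²/(4D) maps the beam size onto the initial profile width; the
"beam diameter" d is read as the 1/e-intensity diameter (a convention —
the observable spot size does not distinguish diameter, FWHM or 1/e
width). Defaults: ADP0 = 1.5·10⁻⁵ M, D = 257 μm²/s, d = 80 μm
(t0 ≈ 1.556 s). The plane integral 4π·D·t0·ADP0 is conserved exactly; the
test suite verifies it by quadrature to 10⁻⁶ relative.

At fixed radius r the concentration is unimodal in time: monotone
decreasing for r² ≤ 4·D·t0, otherwise rising to the peak
ADP0·t0·4D/(e·r²) at t* = r²/(4D) − t0 and decaying afterwards. The peak
bound decides "never activates" exactly, without time stepping.

### Threshold crossing

A cell activates at the smallest t ≥ 0 with C(r, t) ≥ TR. Cells already
above threshold at t = 0 get TA = 0; crossings are otherwise searched
only on the rising branch (the first crossing cannot lie beyond the
peak). Two equivalent solvers are provided and cross-checked: a
bracketing bisection (`crossing_time`, absolute tolerance 10⁻⁶ s, the
definitional route) and a closed form for whole populations
(`crossing_times`): substituting v = a/(t+t0) with a = r²/(4D) turns the
crossing condition into v·e⁻ᵛ = threshold·a/(ADP0·t0), whose rising-branch
root is −W₋₁(−c), the secondary real branch of the Lambert W function.
The vectorized form evaluates ~10⁵ cells in milliseconds, which is what
makes the simulation-based least-squares fit affordable.

### Population and observables

Cells are immobile points, uniformly scattered; positions, thresholds,
delays and noise use separate named RNG streams spawned from one seed, so
re-running any component alone is reproducible. Never-activated cells
carry NaN times; aggregations keep them in denominators (activated
fractions plateau below 1) and report them separately from histograms.
Annulus bins are half-open [r_in, r_out); cells beyond the last ring stay
unassigned rather than being lumped into the outer ring. The default
field of view is the square just covering all six annuli (side 468 μm).
Whether a simulated node is one platelet or a small ensemble is purely a
matter of interpretation of `n_cells` — the mathematics is identical, and
the fluorescence pathway (below) explicitly treats nodes as ensembles.

### Fluorescence synthesis

The per-annulus mean intensity is

    I_a(t) = baseline + (1/N_a) · Σ_{i∈a, TA_i ≤ t} f(t − TA_i),

where f is the *basic response curve*: a least-squares polynomial fit of
the baseline-subtracted nearest-annulus mean trace, zero before
activation, clamped at ≥ 0, holding its end value beyond its support.
Defaults are degree 5 on [0, 120 s], but both are free parameters and
**should be chosen so the fit residual is small against the response
amplitude**: a stiff polynomial that cannot follow the transient biases
the downstream threshold fit (see below). The curve is indexed by
activation time TA, not spike time TS — the delay smearing is inherited
from the nearest-annulus data the curve is fit to, which keeps the
forward model consistent with observed signals in expectation.

Synthesis has two numerical routes: exact per-cell polynomial evaluation
(default), and a fast variant that deposits activation times with linear
weights onto a 4× oversampled frame grid and convolves with the sampled
curve — equal to the exact sum with f replaced by its piecewise-linear
interpolant (error O(step²), measured < 0.5% of signal). The fast route
backs the least-squares objective, where the forward model runs hundreds
of times.

### Spike detection

First spikes are located with standard peak detection: the first local
maximum after the flash whose prominence exceeds `min_prominence` (default
8) times the robust pre-flash noise scale (1.4826 × median absolute
deviation). The detector reports the *peak* time; for a transient with
rise time τ_r and decay τ_d (defaults 0.5 s / 5 s) the peak lags spike
onset by ln(τ_d/τ_r)/(1/τ_r − 1/τ_d) ≈ 1.28 s, an offset that delay fits
on detected times absorb into μ_D. Timing precision is limited by the
flat template top: at the generator's default noise (SNR 100) detection
is frame-accurate (≥ 95% within one frame), but at SNR 10 the sampled
argmax wanders ± a few frames (≥ 99% within 2 s), and at SNR 5 a raw peak
detector can neither localize to one frame nor reliably clear an
8-noise-unit prominence bar. Sub-frame timing claims should not be made
from peak detection at 3 frames/s.

## Inverse problems

### Delay law

In the nearest annulus the diffusion delay is negligible, so spike times
are approximately pure delays. `fit_delay` uses the closed-form log-space
MLE (mean and population SD of ln TS) rather than fitting the histogram —
statistically preferable and asymptotically equivalent. Inside
r ≤ √(4·D·t0) ≈ 40 μm the approximation is exact in this model:
concentration only decays there, so activation is instantaneous or never.

### Threshold law

`fit_threshold` minimizes Σ_areas Σ_frames (I_sim − I_obs)² over (μ, σ).
Common random numbers make the objective deterministic and continuous:
one fixed standard-normal array z is mapped through exp(μ + σ·z) at every
candidate, so the same virtual population deforms smoothly instead of
being re-sampled. The search is a coarse grid (μ ∈ [−18, −10] step 0.5,
σ ∈ [0.5, 4] step 0.25 — bracketing physiological threshold laws) followed
by Nelder–Mead refinement to 10⁻³ in both parameters; a minimum on the
grid boundary is flagged, not fatal. Weighting is uniform over all
post-flash frames and annuli.

Two corrections matter for unbiased recovery, both verified by the
parameter-recovery tests:

1. **Nearest-area rescaling** (`ForwardSetup.rescale_nearest`, default
   on). The basic curve is fit from the *observed* nearest-annulus mean,
   which already includes that annulus's never-activated cells; the
   forward model's 1/N_a average would multiply by an activated fraction
   a second time, deflating every simulated curve by the nearest area's
   activated fraction (~8% under the defaults) and biasing σ by ≈ −0.19
   with near-zero variance. Dividing the simulated response by the
   model's own nearest-area activated fraction at each candidate removes
   the double count.
2. **Adequate curve representation.** With a degree-5 polynomial on
   [0, 120 s] the synthetic world's fast transient is fit with RMS ≈ 0.46
   against an amplitude ≈ 2.5, which alone biased σ by ≈ −0.4. The
   recovery pipeline uses degree 11 on [0, 30 s] (RMS ≈ 0.13); the
   residual-RMS diagnostic, not the recovered parameters, guided that
   choice.

With both in place, recovery at the default world (μ = −14.5, σ = 1.7,
50 000 observed cells, n_sim = 50 000) over ten seeds gives a μ bias of
+0.01 (seed-to-seed SD 0.03) and σ bias of −0.03 (SD 0.03).

## Synthetic experiments

The generator emulates: uniform cell scatter; log-normal thresholds and
delays; a difference-of-exponentials spike transient (rise 0.5 s, decay
5 s, amplitude 5× baseline — the single-cell transient shape is not
constrained by the modeled experiment, these are plausible
calcium-probe kinetics) inserted at flash + TS; i.i.d. Gaussian frame
noise (σ = 0.05 of baseline) at 3 frames/s; a 60 s pre-flash baseline in
a 180 s recording; and spontaneous pre-flash activations as a Poisson
process at 10⁻⁴ events/cell/s (~0.6% of cells in 60 s, "occasional").
Spontaneous activation does not deplete the cell's later ADP response — a
deliberate simplification. The delay defaults μ_D = 0.7, σ_D = 0.3
(median 2 s) are package choices for a seconds-scale, moderately
dispersed lag; they are config values, not measured constants.

Not emulated: photobleaching (beyond an optional linear drift), shot
noise, optics/segmentation artifacts, cell motion, agonist consumption,
secondary agonist release by activated cells, and platelet subtypes. A
green recovery test therefore establishes internal consistency of the
estimation machinery under the model's own assumptions — not robustness
to these real-data effects.

## Numerical choices

- Bisection tolerance 10⁻⁶ s; Lambert-W route clipped at the peak
  boundary c = 1/e to absorb rounding.
- Annulus boundaries half-open; a cell exactly on a ring boundary belongs
  to the outer of the two areas.
- Binned synthesis oversamples the frame grid 4×; linear weight
  deposition keeps the least-squares objective continuous in (μ, σ).
- Traces must be on uniform time grids; the binned route additionally
  requires the grid to start at 0 and falls back to exact evaluation
  otherwise.
- Normalization divides each series by its own pre-flash mean; a zero
  pre-flash mean is an error, not a silent skip.

## Known limitations

- The concentration field ignores the finite sample depth; ADP0 is
  treated as the released surface concentration scale, and absolute
  concentrations inherit that convention.
- The least-squares fit assumes the annulus scheme and diffusion
  constants are known exactly; errors in D or beam width propagate into
  (μ, σ) unquantified.
- Delay fits on *detected* spike times include the transient's
  rise-to-peak lag and frame quantization; at 3 frames/s this is a
  ~±0.17 s uniform timing error plus a +1.28 s offset under the default
  template. Recovery of μ_D to ±0.01 is only meaningful for model spike
  times, not detector output.
- Nelder–Mead refinement on a stochastic-but-frozen objective can stall
  on sub-grid plateaus if the oversampling factor is lowered.
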