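# Methods

`fnirspect` decomposes continuous-wave fNIRS recordings into the spectral
components that physiology imprints on them — cardiac pulsation,
respiration, myogenic vasomotion and very-low-frequency (VLF)
oscillations — and quantifies how those components are distributed across
tissue depth (long vs short source–detector separation, SDS), hemisphere
and task condition. This note records the models, the parameter choices
that matter, and the limits of what the synthetic validation shows.

## Signal chain

### Optical model and hemoglobin conversion

Raw intensities `I(t)` at 730 and 850 nm are converted to optical-density
changes relative to a baseline window,

    dOD_λ(t) = log10( I_baseline,λ / I_λ(t) ),

and to chromophore concentration changes by inverting the two-wavelength
modified Beer–Lambert system

    dOD_λ = ε_λ^HbR · d · DPF_λ · dc_HbR  +  ε_λ^HbO · d · DPF_λ · dc_HbO ,

with extinction coefficients ε₇₃₀^HbO = 0.390, ε₇₃₀^HbR = 1.102,
ε₈₅₀^HbO = 1.058, ε₈₅₀^HbR = 0.691 in per-(mM·cm), source–detector
distance `d` in cm (2.5 long, 1.0 short) and a unitless differential
pathlength factor DPF. Concentrations are reported in µM through a fixed
1000× scale (configurable on `MBLLCoefficients`; the extinction table is
also configurable if a different unit convention is preferred). The 2×2
system is solved exactly per sample — no regularisation — and the
forward/inverse round trip on synthetic data is exact to ~1e-14 µM.

DPF is age-corrected with the Scholkmann–Wolf general-purpose polynomial
DPF(λ, age) = 223.3 + 0.05624·age^0.8493 − 5.723e-7·λ³ + 0.001245·λ² −
0.9025·λ, which is monotonically nondecreasing in age and ≈ 5–6 at
730–850 nm for adults; a fixed-DPF override is available everywhere. Ages
outside [18, 90] are clamped with a warning.

**Baseline policy.** The baseline window is not uniquely defined by the
task description, so it is a parameter: `per_condition` (default) uses
the mean intensity over the first 10 s of each scheduled condition;
`record_start` uses the first 10 s of the record; `reference` uses the
generator's stored true baseline (exact, for validation). The choice
shifts per-segment DC only and is immaterial to band energies after
detrending.

### Channel quality control

A channel is rejected iff any raw intensity sample exceeds 4500 counts
(saturation), or its mean dark-current exceeds 200 counts, or the Pearson
correlation between either wavelength's series and the channel's dark
series exceeds r = 0.7 (poor skin coupling). Rejected channels are
dropped from region means, never imputed; a region losing all member
channels is flagged missing and skipped downstream rather than
zero-filled. The default layout averages long channels 3–6 (left) and
11–14 (right) into the middle-frontal long-SDS regions; channels 17/18
are the left/right short-SDS regions.

### Motion-artifact removal

Abrupt spikes are suppressed with a wavelet outlier rule: decompose the
intensity series, fit a Gaussian robustly (median / MAD) to each detail
level, and zero coefficients whose two-sided exceedance probability under
that fit is below the tuning parameter α = 0.1. Two implementation
choices are ours:

* the transform is the **undecimated (stationary) wavelet transform**
  (`sym8`, depth ⌊log₂N⌋−4 capped at 8). With a decimated DWT the detail
  coefficients of an oscillation are shift-variant and heavy-tailed, and
  the α = 0.1 rule removed up to ~20 % of genuine band energy; the
  shift-invariant transform keeps a stationary tone's coefficients
  sinusoid-distributed, entirely below the robust threshold, so clean
  physiology passes at the 1e-13 level while a 10-SD spike is attenuated
  by ≈ 95 %.
* **Known limitation:** when a level contains *intermittent* genuine
  energy — a frequency-wandering oscillator whose spectral skirt drifts
  across a dyadic level boundary, or two comparable tones beating — the
  envelope peaks exceed the robust threshold and are zeroed. We measured
  up to ~20 % loss of respiratory-band energy per 12-min segment under
  strong wander. This attenuation of physiology is intrinsic to the
  α-threshold family of wavelet despiking and is why the end-to-end
  identity check (below) is defined with this stage disabled.

### Shift correction, detrending, filtering

Baseline shifts (sensor slippage) are detected as sample-to-sample jumps
larger than 5× the robust SD of the first difference; detected segments
are repaired by cubic-spline interpolation and the flanking stable
segments re-levelled so 1-s boundary means are continuous. Shift
correction is applied per region to dHbO and dHbR; dHbT is rebuilt as
their sum afterwards so additivity holds exactly after every stage.

Each region series is then detrended by subtracting a least-squares cubic
and bandpass filtered 0.009–2 Hz with a zero-phase (forward–backward)
3rd-order Butterworth in second-order sections. The passband droop of
this filter at 1.1 Hz costs ≈ 2.7 % of cardiac-band energy (squared by
the two passes); the 0.009 Hz corner has an impulse response of order
100 s, so on records much shorter than ~15 min its edge transients leak
VLF-scale energy — one more reason short records get a duration advisory.

## Spectral decomposition

### Morlet transform

The continuous wavelet transform is
`W(s, t₀) = ∫ x(t) s^(-1/2) ψ*((t−t₀)/s) dt` with the admissible Morlet
kernel

    ψ(t) = (2π)^(-1/2) (e^{i2πf₀t} − e^{−(2πf₀)²/2}) e^{−t²/2},

resolution parameter f₀ = 1, and centre frequency f = f₀/s. The grid is
log-spaced at 16 voices per octave over [0.009, 2] Hz (126 frequencies).
The transform is evaluated by frequency-domain convolution using the
kernel's closed-form spectrum, zero-padded to a power of two at least
6·s_max beyond the record so circular wrap-around stays below 1e-7 of the
kernel peak; it matches direct numerical integration of the transform
integral on test tones to ~1e-15 relative (tested at 1e-6). Kernel
spectra are cached per (padding, grid) so cohort runs pay the setup once.

A cone-of-influence mask marks coefficients within one e-folding time
(√2·s) of either record edge per scale; time averages exclude masked
samples by default (configurable), and a frequency row entirely inside
the cone is flagged unreliable rather than dropped.

**Record-duration guard.** Coefficients at f_min need several cycles to
be trustworthy; the advisory threshold is 8 cycles of f_min (≈ 15 min at
0.009 Hz), so a 7-min record warns and a 20-min record does not. Below
2 cycles the transform is refused.

### Band energies

Band energy density over [f₁, f₂] is the time-averaged double integral

    ε(f₁, f₂) = (1/T) ∫∫ |W(s, t)|² / s²  ds dt

over the scales whose centre frequencies lie in the band, evaluated by
the trapezoidal rule with the exact band edges interpolated onto the
grid — so the four bands (VLF [0.009, 0.06], myogenic [0.06, 0.15],
respiratory [0.15, 0.4], cardiac [0.4, 2] Hz; shared endpoints belong to
the upper band) tile the full range to machine precision, and ε scales
exactly quadratically with amplitude. The relative energy density is
relε = ε_band / ε_total_average with ε_total_average the across-band
*mean* of the four ε values: the four relε of a cell then average to
exactly 1 and individual values may exceed 1 (VLF typically ≈ 2–3). A
total-sum normalisation (divisor 1) is configurable but would bound
relε ≤ 1.

For HbT the complex coefficients of HbO and HbR are summed before taking
magnitudes (the transform is linear); cognitive-protocol records are
transformed per 12-min condition segment, hypercapnic records as a whole
(splitting 60-s blocks would forfeit everything below ~0.06 Hz).

## Group statistics

Each (response, biomarker) table is modelled with a subject random
intercept:

* cognitive:  `1 + Band + Band:SDS + Band:SDS:Hemisphere +
  Band:SDS:Condition + (1 | subject)`  (48 fixed parameters with 5
  conditions),
* hypercapnic: `1 + Band + Band:SDS + (1 | subject)` (8 parameters),

fitted by REML for reported estimates (statsmodels `MixedLM`; a
closed-form profiled fitter over the variance ratio is the fallback when
the optimizer fails) and refitted by ML for likelihood-ratio tests of
each term against the model without it (df = parameter-count difference:
3, 4, 8, 32). If residual diagnostics on the initial fit show |skew| > 1
or a variance ratio > 4 across fitted-value quartiles, the response is
refit as log₁₀(y) and contrast estimates and CIs are reported
back-transformed (10^estimate; a difference becomes a ratio).

Planned comparisons are differences of equally weighted marginal cell
means: 3 Band (VLF minus each other band) and 4 Band:SDS per protocol,
plus 8 Band:SDS:Hemisphere (left minus right) and 48 Band:SDS:Condition
pairs (E1–E2, E1–E3, H1–H2, E1–H1, E2–H2, E3–H1 per band × SDS) for the
cognitive protocol — 7 and 63 in total. **Sign convention:** the SDS
contrast is *short minus long*, so a band dominating the long (cerebral)
channels yields a negative estimate and Cohen's d — matching how
long-channel VLF dominance is conventionally reported. Standard errors
come from (X'V⁻¹X)⁻¹ at the REML variance estimates; degrees of freedom
are Satterthwaite-approximated, df = 2·(c'Φc)² / (∇f' A ∇f) with Φ the
fixed-effect covariance, ∇f its gradient in (σ², τ²) (central
differences) and A the inverse negative Hessian of the closed-form
restricted log-likelihood. Estimates, SEs, df and p-values were verified
to agree with R `lme4`/`lmerTest`/`emmeans` to the printed precision on a
shared fixture. p-values are Benjamini–Hochberg adjusted within each
model term's contrast family (a single global family is available);
unadjusted p is always reported alongside. Cohen's d divides the
model-scale estimate by the total SD √(τ² + σ²), with anchors 0.2 / 0.5
/ 0.8 for small / medium / large.

**Calibration.** Under a simulated no-effect null (direct table
simulation, 13 subjects, hypercapnic model) the Band:SDS LRT rejects at
α = 0.05 in ≈ 6–7 % of 500 replicates. The ML-based LRT is visibly
anti-conservative at smaller cohorts (≈ 9 % at 6 subjects, mean χ² 4.8
on 4 df) — ordinary small-sample behaviour of likelihood asymptotics,
worth remembering when the hypercapnic cohort is only 5 subjects.

## Synthetic data: what it emulates and what it does not

The generator produces raw two-wavelength intensities plus dark current
for the 16-long/2-short channel layout at 10 Hz, for two protocols: five
12-min cognitive conditions (E1–E3, a 15-min break, H1–H2, with a 60-s
lead-in) or the 7-min hypercapnic block design (30-s baseline, 3 × 60-s
CO₂/air alternation). Hemoglobin dynamics are sums of four band
oscillators shared within each (SDS class, hemisphere) group — systemic
oscillations are spatially coherent — plus per-channel cubic drift and
white noise; intensities follow from the forward Beer–Lambert chain
`I = I₀ · 10^(−dOD)` using the same coefficient construction the
preprocessing inverts, so the clean round trip is exact. Motion spikes
(≤ 1-s half-sine transients) and baseline shifts (steps persisting to the
record end) are injected into the intensity series at configurable
per-minute Poisson rates with a full event log. A "bad coupling" option
mixes the dark series into one channel's measurements at a target
correlation to exercise the r > 0.7 rejection.

Default study conditions (chosen once; HbO amplitudes in µM as
(long, short) pairs): VLF 0.03 Hz (1.0, 0.4); myogenic 0.10 Hz
(0.5, 0.6); respiratory 0.25 Hz (0.15, 0.35); cardiac 1.10 Hz
(0.3, 0.8). Since a tone's ε is proportional to its squared amplitude
(and essentially frequency-independent for the Morlet family), these
encode VLF-dominant long channels with the long-channel relε order
VLF > myogenic > cardiac > respiratory, and systemic-dominant short
channels — the qualitative structure the pipeline is asked to recover.
Respiratory and myogenic instantaneous frequencies perform a
mean-reverting bounded walk (stationary SD = the configured jitter,
reversion time 120 s, reflected at the band edges); cardiac and VLF are
near-stationary. HbR defaults to −0.3 × the HbO dynamics plus weak
(0.15×) independent oscillators, so systemic peaks are damped in HbR.
Subject heterogeneity is a lognormal global scale (σ = 0.25) plus
per-band lognormal gains (σ = 0.15); drift amplitude 0.5 µM, noise SD
0.05 µM, spikes 0.3/min, shifts 0.05/min, baseline intensities
1200/1500 counts, dark 30 ± 3 counts, age 30 y. A single top-level seed
drives per-subject/per-channel counter-derived substreams, so any subset
of a cohort is bit-reproducible in isolation.

Not emulated: photon transport through layered tissue (amplitudes are
asserted, not derived from optics), task-evoked hemodynamic response
shapes, physiological coupling between bands (e.g. respiratory sinus
arrhythmia), EtCO₂ or other peripheral sensors, and instrument-specific
gain or nonlinearity — baseline intensity and noise levels are free
parameters, not calibrated to hardware. Passing the synthetic checks
therefore demonstrates that the *analysis chain* is correct and
calibrated under its own assumptions, not that those assumptions hold
for any particular instrument or cohort.

## Numerical choices and degenerate inputs

Trapezoid integration on the 16-voice grid agrees with a 4×-denser
Riemann evaluation within 2 % on tones; COI-masked samples are excluded
from time averages with an all-sample fallback (flagged) when a row is
fully masked. Non-positive intensities are flagged NaN in OD (warned,
never silently repaired); an all-zero band-energy vector yields NaN relε
with a warning; a constant response gives a degenerate zero-variance fit
(all effects zero) instead of an optimizer crash; a random-intercept
variance at the boundary (~0) is warned as singular; contrasts touching
an absent factor level are skipped and reported. Pipeline runs write a
manifest with SHA-256 checksums, config echo, seed and library versions —
and no timestamps — so identical configurations are byte-reproducible.

## Problem sizes used in validation

Unit and property tests run on 420-s to 600-s single-subject records.
The pattern-recovery study uses 20 seeded replicates of the full
13-subject cognitive cohort (HbO biomarker; ≈ 20 s per replicate). The
type-I calibration uses 500 direct-table null replicates at 13 subjects.
The determinism and duration-guard checks run 2–3-subject hypercapnic
pipelines end to end.
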