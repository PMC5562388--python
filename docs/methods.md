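# Methods

This note documents the models implemented in `nirstwin`, their assumptions,
the defaults and why they were chosen, and what the synthetic data do and do
not establish about real recordings.

## Instrument scheduling

The scheduling arithmetic is deterministic bookkeeping of the measurement
cycle: a 6.6-ms acquisition window holding five 1.2-ms slots (backlight +
four wavelengths), 1.2 ms of on-board averaging, and 0.6 ms of bus
communication per module read out.  Channel enumeration assumes every module
alternately acts as source while all modules — including the source itself —
read their detector, so N modules yield N² channels (N short-separation
self-pairs at the fixed 7.5-mm on-board distance, N(N−1) long-separation
pairs at the Euclidean inter-module distance; module positions are treated
as planar coordinates, with no geodesic scalp model).  The per-channel rate
formula 100 Hz/[NS(1+0.06·ND)] counts the source module's own detector in
ND.  Because the formula and the sub-10-ms cycle budget are stated as
independent constraints, `effective_sampling_rate` reports both and their
minimum.

## Light transport and the optical-loss scale

Diffuse reflectance R(ρ) uses the steady-state diffusion approximation for a
homogeneous semi-infinite medium with the standard two-source construction:
an isotropic source at depth z₀ = 1/(μa + μs′) and a negative image mirrored
about the extrapolated boundary at z_b = 2AD, with the internal-reflection
parameter A from the Groenhuis polynomial at n = 1.4 (used for both tissue
and phantom).  Optical loss is OL(ρ) = 1/(R(ρ)·A_ap) with A_ap the area of
an 8-mm-diameter circular aperture (the standardized convention specifies
the diameter).  The OL↔separation inversion is a bracketed root find on
log₁₀ OL to 0.01 mm.  On the packaged phantom properties (μa = 0.0099 mm⁻¹,
μs′ = 0.9514 mm⁻¹ at 850 nm) the model places OL 10⁴/10⁶/10⁷ at
25.5/45.7/56.7 mm.  OL targets are anchored at the 850-nm column because the
tabulated properties exist only at 680 and 850 nm and the near-infrared
channels cluster around the latter.

A weighted-packet Monte-Carlo photon random walk (test-only) provides an
independent check of the diffusion solution.  It uses isotropic scattering
at the reduced scattering coefficient — by the similarity relation this is
equivalent in the diffusion regime to anisotropic scattering with matched
μs′ and roughly an order of magnitude cheaper — with fractional absorption,
Russian-roulette termination, Fresnel reflection at the mismatched surface,
and annular scoring.  2×10⁵ packets give ≈5% agreement at 10–30 mm; the test
asserts 20%.  The diffusion approximation itself is least accurate within a
few transport mean free paths of the source (ρ ≲ 3 mm), well below the
instrument's 7.5-mm minimum separation.

## Physiology generators

The generators produce ground-truth chromophore changes (µM) on a uniform
grid, split into an extracerebral layer (seen by all channels) and a
cerebral layer (seen by long channels only, scaled by a partial-pathlength
weight, default 1.0 — an idealization; in tissue the cerebral contribution
to a 40-mm channel is partial).

* **Systemic oscillations** — a sum of seeded, phase- and
  frequency-jittered sinusoids: Mayer waves 0.1 Hz, respiration 0.25 Hz,
  cardiac 1 Hz, with O2Hb amplitudes 0.4/0.2/0.2 µM and HHb at a quarter of
  that, oxCCO flat.  No printed amplitudes exist for these; the defaults
  were chosen once to qualitatively match published resting-state traces
  and are configurable.
* **Motor task** — a 20-s task / 20-s rest boxcar, 10 repetitions,
  convolved with a canonical double-gamma kernel (peak 6 s, 1/6
  undershoot) and normalized to unit peak so the configured amplitude
  (O2Hb +0.5 µM) is realized exactly; HHb mirrors at −0.3, oxCCO zero.
  The kernel shape is conventional; only the amplitude is a tested
  quantity.
* **Arterial occlusion** — piecewise: a 10-s venous phase (both
  hemoglobins rise ~1.5 µM), a linear arterial ramp to ΔO2Hb −15 µM /
  ΔHHb +15 µM at cuff end, then a fast refill (τ = 4 s) plus a hyperemic
  overshoot/undershoot pulse (peak 8 s, recovery τ = 25 s).  O2Hb falls and
  HHb rises during the arterial phase — the physiologically established
  directions.  The oxCCO trace follows the measured in-vivo behaviour: a
  small upward trend during occlusion capped at 0.08 of the HHb excursion
  (bound: 1/10) and a release peak constructed to land at 1/5 of the HHb
  excursion.  These ratios are enforced by construction and verified
  end-to-end through the acquisition and reconstruction chain.

## Acquisition chain

SiPM gain is linear in overvoltage above breakdown, fitted through the two
anchor points (28 V, 1.4×10⁶) and (33 V, 8.2×10⁶), giving a breakdown of
≈26.97 V; gain is zero at or below breakdown (the 24-V parking bias).
Photon detection efficiencies are fixed per wavelength (13/9/6/4%).  The
fired-cell saturation law N_det = N_cells(1 − e^(−n/N_cells)) is evaluated
per cell-recovery window, default 100 ns (typical for 50-µm cells): a
10-µs window would cap the photocurrent at ≈0.5 mA at maximum gain, below
the instrument's own 1.5-mA software limit and its routine ~1-mA operation,
so the recovery-time window is the only self-consistent choice.  Shot noise
is evaluated per 10-µs ADC sample (Poisson on the photoelectron count), the
electronic floor is a constant voltage sd per subsample, and the calibration
solves for the floor so that a 1-V channel measures a target SNR (default
64 dB) after the 64-sample plateau average.  The calibration fails loudly if
shot noise alone exceeds the budget (e.g. at maximum gain).

The default recording path assumes the detector operates in its linear
regime, as the instrument arranges by adjusting LED currents and
overvoltage for leveled detector intensities: each channel's baseline slot
voltage is the leveling target (1.0 V, i.e. 1 mA photocurrent, matching the
instrument's thermal limit), or, in fixed-settings mode, the target scaled
by the diffuse-reflectance ratio to the 7.5-mm reference — which makes SNR
fall monotonically with optical loss.  The physiological modulation is
applied through the Beer–Lambert attenuation exp(−ΔA) with
ΔA = ln10·εΔc·DPF·L, using the same extinction system later used for
reconstruction, so the forward and inverse models are exactly consistent
and reconstruction fidelity is a well-posed test.  Driving the slot voltage
through the full fired-cell saturation law instead would push 7.5-mm
channels deep into saturation under the constant-PDE assumption and crush
their modulation; the saturation law is therefore exposed for
characterization (`sipm_response`) but not part of the default recording
path.  Warm-up drift multiplies the detected signal (a sensitivity, i.e.
PDE/temperature, effect): an exponential settling whose local relative
slope passes through −0.3‰/s at 60 s and −0.1‰/s at 600 s by construction.
Each slot is measured as the mean of 64 subsamples quantized to the 16-bit
grid (LSB = 3/2¹⁶ V); a noiseless constant input is therefore reproduced
within one LSB.  The backlight slot records the ambient offset added to
every wavelength slot; subtraction happens in the attenuation step.

## Reconstruction

Attenuation changes are natural-log optical-density changes after backlight
subtraction, referenced to a fixed baseline sample by default; the
previous-sample reference is kept as an option whose cumulative sum
telescopes exactly to the baseline form (tested to 1e−12).  The packaged
extinction table (decadic, mM⁻¹cm⁻¹) is converted internally to ln-based
µM⁻¹mm⁻¹; outputs are µM.  The pseudoinverse is SVD-based with a
condition-number guard — for the tall 4×2/4×3 extinction matrices it equals
the normal-equations left inverse (E'E)⁻¹E', the only well-defined reading
(a right inverse does not exist for tall full-column-rank matrices).
Wavelength subsets accept nominal LED names (770/810/850/885) as aliases
for the measured peaks (774/817/865/892), which are what the extinction
lookup uses.  DPF values come from the packaged adult-head table with a
configurable scale, or can be derived from the diffusion model
(`ExtinctionSystem.for_medium`) for self-consistent simulation studies.

## Processing

Filters are Chebyshev-II applied forward-backward (zero phase, squared
magnitude).  The printed band edges (1-Hz lowpass; 0.01–0.5-Hz bandpass)
are interpreted as passband edges, with the Chebyshev-II stopband edges
placed one octave outside (configurable): placing the stopband edges *at*
the printed frequencies would attenuate the 0.025-Hz block-design
fundamental by 61–95% at the printed orders, which would defeat the block
analysis the filters serve.  Stopband attenuation defaults to 40 dB (a
design parameter the band edges do not fix).  Short-channel regression uses
the least-squares projection coefficient — a bare correlation coefficient
has the wrong units for subtraction — per chromophore over a centered
120-s sliding window with per-sample coefficients (hop = 1 sample) and
symmetric shrinking at the record edges; a zero-variance short-channel
window yields α = 0 with a warning.  Block averaging cuts −2 s to +40 s
around onsets, baselines each epoch on its pre-onset mean, and reports the
across-trial mean and standard error (a single trial reports SE 0 with a
warning).  The default pipeline order is band-pass before regression; both
orders are supported.

## What the synthetic data do and do not show

The generators emulate the statistical structure the processing chain is
designed for: multiplexed four-wavelength slots with ambient offset,
shot + electronic noise calibrated to the instrument's short-channel SNR,
multiplicative drift, superficial oscillations common to SS and LS
channels, and a cerebral response confined to LS channels.  They do not
emulate motion artifacts, heterogeneous or layered optics (a single
effective DPF per channel), task-locked scalp perfusion changes, LED
spectral width, or detector nonlinearity in the default path.  Passing
recovery tests therefore demonstrates the correctness and internal
consistency of the implementation under the stated noise model — not that
the same accuracy will be reached on real tissue, where DPF error,
partial-pathlength effects, and systemic task-locked confounds add biases
that the twin deliberately isolates away unless enabled.

## Numerical choices and problem sizes

Reconstruction roundtrips are asserted to 1e−10 (analytic forward) and to
<1% of signal amplitude through the quantized acquisition path.  The OL
root find uses 0.01-mm tolerance; OL↔SDS agreement with the printed
correspondence is asserted at ±15% (the correspondence is printed with a
"∼").  Variance-ratio analysis follows the bench protocol: 11 detrended
400-sample segments, ratios relative to the 770/850-nm inversion, averaged
across segments (averaging chosen over pooling; configurable).  The printed
in-vivo variance reductions (−25% O2Hb, −8% HHb for four vs two
wavelengths) depend on the physical detector's per-wavelength noise
spectrum; the package asserts the direction (<1) under both iid and
calibrated noise, not those magnitudes.  Simulation sizes used in tests —
a 46-s phantom run at 100 Hz, one 410-s motor run and one 1020-s occlusion
run at 25 Hz per channel, 2×10⁵ Monte-Carlo packets, 10⁴ variance-ratio
replicates — were chosen as the smallest sizes at which the asserted
statistics are stable.
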