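# Methods

This note documents the models, the tunable parameters that matter, the
numerical choices, and the limits of what the synthetic tests demonstrate.

## Dual-beam velocity model

Two linear arrays with axes at an inter-angle θ (default 30°) insonate the
vessel transversally. For a velocity vector (Vx, Vz) in the plane spanned by
the lateral direction x (along the skin, in the plane of the two beams) and
depth z, the two beams observe Doppler shifts

    f_dr = (2 f_tx / c) ( Vx sin(θ/2) + Vz cos(θ/2))
    f_dl = (2 f_tx / c) (−Vx sin(θ/2) + Vz cos(θ/2))

with transmit frequency f_tx (7.5 MHz) and sound speed c (1540 m/s, the
standard soft-tissue value; the hardware parameters do not fix it).
Triangulation inverts this 2×2 system exactly; `triangulate` and
`forward_doppler_freqs` are exact inverses to machine precision, which the
property suite asserts. The out-of-plane velocity component is unobservable
with two coplanar beams: a probe rotation ρ about the depth axis scales the
measured magnitude by cos ρ (−6% at 20°), which bounds the accuracy of the
method under rotation misplacement.

Angles are degrees at every interface and radians internally. The
"full PRF range" velocity limit uses f_d,max = PRF (the full width of the
sampled two-sided spectrum, ≈3.17 m/s at 75°); the conventional single-sided
Nyquist limit (PRF/2) is exposed separately as `nyquist_velocity`.

The 11 mm gap printed for the array holder is geometrically inconsistent
with beam axes crossing at 23 mm under any center-to-center reading; the
cross depth is taken as the authoritative given and the beam-origin
separation is derived from it (s = 2 d tan(θ/2) ≈ 12.33 mm).

## Lumen segmentation

Each frame is contrast-stretched between its 1st and 99th intensity
percentiles (a constant frame passes through unchanged) and smoothed with a
Gaussian of σ = 0.5 mm, isotropic in physical units — strong enough to
suppress speckle grain, weak enough to preserve a ≥2.1 mm lumen. Because
B-mode pixels are anisotropic (0.1 mm axial × 0.3 mm lateral by default),
frames are bilinearly resampled to an isotropic 0.15 mm grid before the
Hough accumulation.

The circular Hough transform is the two-stage gradient dialect: Canny edges
with hysteresis thresholds at the 0.80/0.95 gradient quantiles, each edge
pixel voting at distance r *against* its gradient direction so that only
dark-interior circles accumulate, radius bins at one isotropic pixel over
[2.1, 4.0] mm. Accumulator slices are smoothed (σ = 1.5 px) and peaks above
0.5× the global maximum become candidates. Vote counts are not normalized by
radius: a true circle's votes scale with its circumference, which suppresses
spurious small-radius candidates that otherwise win the darkness election
(this was the single largest accuracy lever in development — the top
accumulator peak is stable to <0.1 mm while a darkness election over many
weak candidates scatters by up to 1 mm).

Per frame, the candidate with the darkest mean interior (pixels within
0.9 r, computed on the preprocessed frame — the raw/preprocessed choice is
configurable) is elected; ties break deterministically (darkness, then
depth, then |x|). Over the sequence, candidates are quantized to the
isotropic grid and the modal triad wins; the detection fails when fewer than
3 frames contribute any candidate. The relative accumulator threshold means
*some* candidate exists whenever any edges exist; on vessel-free but
textured input the pipeline therefore usually discards downstream ("no
signal" in the ROI) rather than at segmentation. Only featureless frames
fail outright at segmentation.

## Spectral processing

The wall (clutter) filter is a 4th-order Butterworth high-pass at 100 Hz
applied along slow time, run forward–backward (zero phase) so no samples are
lost and the packet grid is unchanged (2 s at 8 kHz → 249 packets of 128
samples at 50% overlap). The filter padding is set to 3·PRF/cutoff samples:
with default padding, the edge transient of strong (+40 dB) clutter leaks
broadband power into the first packet and produces spurious detections
there; the longer pad absorbs it (verified directly on clutter-plus-noise
ensembles).

Each packet is Hann-windowed and Fourier transformed to the two-sided axis
[−PRF/2, PRF/2); no zero-padding, no aliasing unwrapping. Power is
normalized by the window's power gain.

The centroid estimator is a modified centre of mass. The exact published
scheme it descends from is not fully specified by its citation, so the
"modification" is pinned here, isolated in one function with its parameters
in `CentroidParams`:

1. noise floor = mean of the lowest quartile of spectral bins, subtracted
   from all bins, negatives clipped;
2. bins below 10% of the post-subtraction peak are excluded from the mass;
3. **signal-presence test:** the spectrum is declared undefined (NaN) unless
   its raw maximum exceeds 40× its median bin. For white noise the
   max/median ratio stays below ≈25 even over 10⁴ trials (measured), so the
   threshold sits above the noise population with margin while a tone only a
   few dB above the per-bin floor exceeds it by orders of magnitude. Without
   this test, noise-only gates contribute random centroids that can dominate
   the peak-over-depth-and-time output.

Undefined centroids are excluded from all downstream maxima, never
zero-filled; a velocity entry requires both sides defined (strict
intersection). Packet k of the left map pairs with packet k of the right
map — the 62.5 µs interleave offset between beams is negligible at carotid
time scales.

## Peak extraction and validity

The ROI is a 6 mm gate window centred on the mean of the two detected lumen
depths, shifted (not shrunk) at the gated-range boundaries. The measurement
output is the maximum of |V| over ROI gates and packets — no temporal
smoothing by default, so the peak is permutation-invariant over packets. Two
checks can discard it: a lateral-velocity sign opposite to the expected
carotid flow direction both at the peak and in the ROI median (a jugular
lock), and a plausibility band (default 0.05 m/s to the full-PRF velocity
limit). A discarded result never carries a peak in its JSON output. Whether
the maximum should be taken on direction-gated V rather than |V| is an open
choice; |V| with the separate direction check is implemented because it
keeps the discard logic explicit.

## Synthetic data

The simulator defines the test conditions; it is deliberately minimal.

**B-mode phantom.** A complex circular-Gaussian scatterer field, attenuated
by 10^(contrast/20) inside the lumen disk (default −25 dB, a markedly
hypoechoic lumen), smoothed by an anisotropic Gaussian point-spread kernel
(σ = 0.20 mm axial × 0.35 mm lateral), envelope-detected and log-compressed
to 8 bits over a 50 dB dynamic range. Pixels are 0.1 mm axial (finer than
the 0.6 mm sample volume) × 0.3 mm lateral (the element pitch). A probe tilt
renders the section as an ellipse via a lateral stretch of 1/cos τ. Frames
are independent speckle realizations around a fixed lumen.

**Doppler ensembles.** Gates intersecting the lumen carry a narrowband
complex exponential whose instantaneous frequency follows the forward model
for the local profile velocity (parabolic by default — the laminar
assumption; the true phantom profile shape is not known, so it is
configurable), amplitude-weighted by the profile. All gates carry a near-DC
clutter tone (|f| ≤ 5 Hz, default +40 dB above the peak signal) and circular
white noise (default SNR 20 dB at the peak-amplitude gate). The pulsatile
waveform is a raised half-sine cubed on a 15% diastolic baseline — peak
exactly as specified, two systolic maxima in 2 s at 60 bpm.

What the simulator does **not** model: intrinsic/transit-time spectral
broadening (the signal per gate is a single frequency), acoustic
propagation, beam geometry and element directivity, tissue motion, probe
pressure, attenuation with depth, real carotid wall texture. Consequently,
passing the simulation bounds shows the *processing chain* is correct and
unbiased under its own assumptions at realistic SNR; it does not certify
in-vivo accuracy, where wall variability and spectral broadening raise both
centre errors and velocity spread well above the synthetic figures. The
simulated errors (≈0.1% velocity, ≈0.1 mm centre r.m.s.) sit far inside the
in-vitro bounds (3.2%, 4.5%, 0.43 mm) for exactly this reason — the bounds
are upper limits from hardware experiments, not calibration targets.

## Campaign emulation

The probe-positioning series map to truth transformations: tilt τ rotates
the flow by τ in the x–z plane and stretches the section by 1/cos τ;
rotation ρ scales the observable velocity by cos ρ and stretches the
section; translation moves the lumen laterally; depth moves it axially
(19–30 mm). Grids default to the in-vitro protocol (tilt −15…+15°, rotation
0…20°, depth 19–30 mm); every (grid point, repeat) derives a deterministic
seed from the base seed.

## Problem sizes and numerical conventions

Acceptance-style computations use 20 seeded acquisitions for accuracy, 10
for repeatability, and 50 sequences for segmentation — enough for stable
stochastic estimates while keeping a full run to a few minutes on one CPU.
Sample standard deviation (N−1) throughout; CV% requires ≥2 values and a
nonzero mean; the per-experiment centre distance is reported per experiment
with mean and r.m.s. as separate summaries; the 1 mm discard applies to the
segmentation distance only. Degenerate inputs (constant images, empty
candidate lists, all-undefined maps, zero reference velocity) return
explicit failures or undefined markers rather than silent zeros.
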