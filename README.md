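# carodop

Automatic measurement of the peak blood velocity in the common carotid
artery (CCA) from a dual-angled-array transversal ultrasound acquisition —
plus a synthetic acquisition simulator that stands in for the probe/scanner
hardware.

## The problem

A carotid Doppler exam normally needs an expert sonographer: find the vessel
in the B-mode image, place the sample volume in the lumen, estimate the
Doppler angle, and read off the systolic peak. A self-operated, low-cost
device must do all of that automatically. The approach implemented here uses
two linear arrays mounted with a fixed inter-angle θ (30°) and placed
transversally on the neck:

- **Lumen localization.** In a transverse view the lumen is a dark, roughly
  circular region. Each of 15 B-mode frames per array is contrast-stretched,
  strongly Gaussian-smoothed, and searched with a gradient circular Hough
  transform restricted to dark-interior circles with radii 2.1–4 mm. The
  darkest-interior circle per frame is the frame's candidate; the modal
  quantized (x, y, r) triad over the sequence is the detection.
- **Multigate spectral Doppler.** One non-steered Doppler line per array
  crosses the detected lumen centre. The complex IQ ensemble (512 depth
  gates, 8 kHz PRF per beam, ~2 s) is wall-filtered at 100 Hz, split into
  128-sample packets with 50% overlap, Fourier transformed, and reduced to a
  centroid frequency per (packet, gate) by a modified centre-of-mass
  estimator with noise-floor subtraction, restricted to a 6 mm region of
  interest centred on the mean of the two detected lumen depths.
- **Dual-beam angle correction.** The two beams see a skin-parallel vessel at
  90° − θ/2 and 90° + θ/2. Their simultaneous shifts f_dr, f_dl at the same
  depth triangulate into the in-plane velocity components

      Vx = c (f_dr − f_dl) / (4 f_tx sin(θ/2))
      Vz = c (f_dr + f_dl) / (4 f_tx cos(θ/2)),    V = √(Vx² + Vz²)

  removing the angle dependence without operator input. The single output is
  the maximum of V over depth and time, guarded by validity checks (flow
  direction against the expected carotid direction catches a lock onto the
  jugular vein; a plausibility band catches aliased or noise-driven peaks).
- **Evaluation statistics.** Centre distance error with a 1 mm discard rule,
  its mean and r.m.s. over a series, signed relative velocity error
  Err% = 100 (V_M − V_R)/V_R, and the coefficient of variation
  CV% = 100 · std(V_M)/mean(V_M).

Because no deposited dataset exists for this kind of acquisition, the
package includes a first-class synthetic module: speckled B-mode phantoms
with a known hypoechoic lumen, and dual-beam IQ ensembles whose per-gate
Doppler shifts follow the forward dual-beam model for a chosen velocity
waveform, with near-DC clutter and white noise.

## Worked example

`examples/04_full_measurement.py` builds a complete synthetic acquisition
with a pulsatile, volunteer-like flow (peak 0.67 m/s, 60 bpm, 2 s) and runs
the whole chain:

```
status: ok
peak velocity: 0.670 m/s (truth 0.670) at t = 1.25 s, depth 23.0 mm
systolic peaks in the 2 s velocity trace: 2 at t = [0.25, 1.25] s
```

The 2 s acquisition spans two cardiac cycles, both systolic peaks appear in
the measured velocity trace, and the reported single value — the maximum
over depth and time — recovers the true peak to 3 decimal places at 20 dB
SNR. The other examples cover the probe's closed-form limits (01), phantom
segmentation (02, centre error 0.112 mm), spectral processing and
triangulation (03), and a probe-positioning robustness campaign (05).

A thin CLI mirrors the phases:

```bash
carodop synth bmode --out left.tiff --center-x -1.5 --seed 3
carodop synth doppler --out acq.h5 --velocity 0.34 --seed 3
carodop segment --in left.tiff --out det.json
carodop measure --iq acq.h5 --bmode-left left.tiff --bmode-right right.tiff --out result.json
carodop campaign --series tilt --out tilt.csv
```

## Layout

- `src/carodop/geometry.py` — probe/acquisition parameters, closed forms
- `src/carodop/synth.py` — phantom and IQ simulators with ground truth
- `src/carodop/segmentation.py` — lumen detection (gradient CHT + consensus)
- `src/carodop/spectral.py` — wall filter, packets, FFT, centroid estimator
- `src/carodop/velocity.py` — ROI, triangulation, peak, validity checks
- `src/carodop/metrics.py` — evaluation statistics and discard rules
- `src/carodop/pipeline.py` — end-to-end measurement and campaigns
- `src/carodop/cli.py`, `src/carodop/io.py` — CLI and TIFF/HDF5/JSON I/O
- `docs/methods.md` — model assumptions, parameter choices, limitations
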