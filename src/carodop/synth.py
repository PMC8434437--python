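"""Synthetic acquisitions with known ground truth.

Stands in for the probe/scanner hardware: generates (a) speckled B-mode
phantom sequences containing a dark circular (optionally elliptical) lumen,
and (b) dual-beam multigate IQ Doppler ensembles whose per-gate Doppler
shifts follow the forward dual-beam model for a chosen velocity waveform,
with near-DC clutter and circular white noise.

Speckle model: a complex circular-Gaussian scatterer field, attenuated
inside the lumen disk by the stated contrast, smoothed by an anisotropic
point-spread kernel, envelope-detected and log-compressed to 8 bit over a
stated dynamic range.  This is the minimal model sufficient to exercise a
Hough-based detector; it does not simulate acoustic propagation, shadowing
or tissue motion.

Doppler model: each gate intersecting the lumen carries a narrowband complex
exponential at the dual-beam Doppler frequency of the local profile
velocity, amplitude-weighted by the profile; intrinsic spectral broadening
is not modelled.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import AcquisitionConfig, ProbeGeometry
from .segmentation import BModeSequence
from .spectral import IQEnsemble


@dataclass
class PhantomTruth:
    """Ground-truth lumen placement for one B-mode phantom sequence."""

    center_x: float = 0.0       # mm, lateral
    center_y: float = 23.0      # mm, depth
    radius: float = 3.0         # mm
    side: str = "left"
    seed: int = 0
    lateral_stretch: float = 1.0  # >1 renders an ellipse (tilted-probe view)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class FlowTruth:
    """Ground-truth flow for the Doppler simulator.

    waveform : velocity magnitude vs slow time, m/s (sampled at the PRF).
    direction : unit vector (ux, uz) of the flow in the lateral-depth plane.
    profile_radius_mm : lumen radius R of the velocity profile.
    profile_shape : "parabolic" or "plug".
    """

    waveform: np.ndarray
    direction: tuple[float, float] = (1.0, 0.0)
    profile_radius_mm: float = 3.0
    profile_shape: str = "parabolic"

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        n = math.hypot(*self.direction)
        if n <= 0:
            raise ValueError("direction must be a nonzero vector")
        self.direction = (self.direction[0] / n, self.direction[1] / n)
        if self.profile_radius_mm <= 0:
            raise ValueError("profile_radius_mm must be positive")

    @property
    def peak_velocity(self) -> float:
        return float(self.waveform.max()) if self.waveform.size else 0.0


@dataclass(frozen=True)
class SpeckleParams:
    """Speckle/PSF/compression parameters of the B-mode phantom."""

    psf_sigma_axial_mm: float = 0.20
    psf_sigma_lateral_mm: float = 0.35
    dynamic_range_db: float = 50.0


def parabolic_profile(r_mm, R_mm: float, vmax: float):
    """Laminar (Poiseuille) profile: vmax*(1 - (r/R)^2) inside, 0 outside."""
    if R_mm <= 0:
        raise ValueError("R must be positive")
    r = np.asarray(r_mm, dtype=float)
    v = vmax * np.clip(1.0 - (r / R_mm) ** 2, 0.0, None)
    return float(v) if np.isscalar(r_mm) else v


def plug_profile(r_mm, R_mm: float, vmax: float):
    """Flat profile: vmax inside the lumen, 0 outside."""
    r = np.asarray(r_mm, dtype=float)
    v = np.where(np.abs(r) <= R_mm, vmax, 0.0)
    return float(v) if np.isscalar(r_mm) else v


def pulsatile_waveform(
    peak: float, beats_per_min: float, duration_s: float, fs: float = 8000.0,
    diastolic_fraction: float = 0.15,
) -> np.ndarray:
    """Simple pulsatile carotid-like waveform, m/s, sampled at ``fs``.

    A raised half-sine cubed rides on a diastolic baseline; the maximum is
    exactly ``peak`` and the minimum is ``diastolic_fraction * peak`` >= 0.
    ``beats_per_min = 0`` yields a constant (steady) waveform at ``peak``.
    60 bpm over 2 s produces exactly 2 systolic maxima.
    """
    if peak <= 0:
        raise ValueError("peak must be positive")
    n = int(round(duration_s * fs))
    if n <= 0:
        return np.empty(0)
    t = np.arange(n) / fs
    if beats_per_min == 0:
        return np.full(n, peak)
    base = diastolic_fraction * peak
    pulse = np.clip(np.sin(2 * np.pi * (beats_per_min / 60.0) * t), 0.0, None) ** 3
    return base + (peak - base) * pulse


def steady_flow(velocity: float, profile_radius_mm: float = 3.0,
                duration_s: float = 2.0, prf: float = 8000.0,
                direction=(1.0, 0.0), profile_shape: str = "parabolic") -> FlowTruth:
    """Convenience constructor for a steady (pump-like) flow truth."""
    wf = np.full(int(round(duration_s * prf)), float(velocity))
    return FlowTruth(wf, direction=direction,
                     profile_radius_mm=profile_radius_mm, profile_shape=profile_shape)


def make_phantom_sequence(
    truth: PhantomTruth,
    n_frames: int = 15,
    contrast_db: float = -25.0,
    speckle_params: SpeckleParams | None = None,
    pixel_spacing: tuple[float, float] = (0.1, 0.3),
    image_extent_mm: tuple[float, float] = (40.0, 38.4),
) -> BModeSequence:
    """Speckled B-mode sequence with a hypoechoic disk at the truth position.

    Each frame is an independent speckle realization around the same, fixed
    lumen.  ``contrast_db`` scales the scatterer amplitude inside the disk
    (default -25 dB, a markedly hypoechoic lumen); -inf renders a perfectly
    anechoic (black) interior.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    sp = speckle_params or SpeckleParams()
    rows = int(round(image_extent_mm[0] / pixel_spacing[0]))
    cols = int(round(image_extent_mm[1] / pixel_spacing[1]))
    lateral_origin = -(cols - 1) * pixel_spacing[1] / 2.0

    ys = np.arange(rows) * pixel_spacing[0]
    xs = lateral_origin + np.arange(cols) * pixel_spacing[1]
    dy = (ys[:, None] - truth.center_y)
    dx = (xs[None, :] - truth.center_x) / truth.lateral_stretch
    inside = dy**2 + dx**2 <= truth.radius**2

    ry = truth.radius
    rx = truth.radius * truth.lateral_stretch
    if (truth.center_y - ry < 0 or truth.center_y + ry > image_extent_mm[0]
            or truth.center_x - rx < xs[0] or truth.center_x + rx > xs[-1]):
        raise ValueError("lumen circle extends outside the field of view")

    amp_in = 10.0 ** (contrast_db / 20.0) if np.isfinite(contrast_db) else 0.0
    gain = np.where(inside, amp_in, 1.0)
    sigma_px = (sp.psf_sigma_axial_mm / pixel_spacing[0],
                sp.psf_sigma_lateral_mm / pixel_spacing[1])

    rng = np.random.default_rng(truth.seed)
    frames = np.empty((n_frames, rows, cols), dtype=np.uint8)
    for i in range(n_frames):
        scat = gain * (rng.standard_normal((rows, cols))
                       + 1j * rng.standard_normal((rows, cols)))
        env = np.abs(ndimage.gaussian_filter(scat.real, sigma_px)
                     + 1j * ndimage.gaussian_filter(scat.imag, sigma_px))
        ref = env.max()
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(np.where(env > 0, env / ref, np.finfo(float).tiny))
        img = np.clip(db + sp.dynamic_range_db, 0.0, sp.dynamic_range_db)
        frames[i] = np.round(img / sp.dynamic_range_db * 255.0).astype(np.uint8)

    return BModeSequence(
        frames=frames, pixel_spacing=pixel_spacing,
        lateral_origin=lateral_origin, side=truth.side,
    )


def forward_doppler_freqs(Vx, Vz, geom: ProbeGeometry, cfg: AcquisitionConfig):
    """Doppler shifts (fdr, fdl) in Hz seen by the right/left beams.

    The algebraic inverse of the dual-beam triangulation:
    fdr = (2 ftx / c)(Vx sin(theta/2) + Vz cos(theta/2)),
    fdl = (2 ftx / c)(-Vx sin(theta/2) + Vz cos(theta/2)).
    """
    k = 2.0 * geom.tx_frequency_ftx / cfg.sound_speed_c
    s, c = math.sin(geom.theta_rad / 2.0), math.cos(geom.theta_rad / 2.0)
    Vx = np.asarray(Vx, dtype=float)
    Vz = np.asarray(Vz, dtype=float)
    fdr = k * (Vx * s + Vz * c)
    fdl = k * (-Vx * s + Vz * c)
    if fdr.ndim == 0:
        return float(fdr), float(fdl)
    return fdr, fdl


def simulate_iq_pair(
    flow: FlowTruth,
    lumen_depth_mm: float,
    geom: ProbeGeometry,
    cfg: AcquisitionConfig,
    snr_db: float = 20.0,
    clutter_db: float = 40.0,
    seed: int = 0,
    duration_s: float = 2.0,
) -> tuple[IQEnsemble, IQEnsemble]:
    """Dual-beam multigate IQ ensembles for the given flow truth.

    Gates intersecting the lumen carry a unit-peak-amplitude complex
    exponential whose instantaneous frequency is the forward dual-beam
    Doppler shift of the local profile velocity, amplitude-weighted by the
    profile.  All gates carry a near-DC clutter component ``clutter_db``
    above the peak signal and circular white noise at ``snr_db`` below it.
    The waveform is resampled/truncated to the slow-time grid as needed.
    """
    n_slow = int(round(duration_s * cfg.prf_per_beam))
    gates_mm = cfg.gate_depths_mm
    n_gates = len(gates_mm)

    if not (gates_mm[0] <= lumen_depth_mm <= gates_mm[-1]):
        raise ValueError("lumen depth outside the gated range")

    wf = flow.waveform
    if wf.size < n_slow:
        wf = np.resize(wf, n_slow) if wf.size else np.zeros(n_slow)
    wf = wf[:n_slow]

    offs = gates_mm - lumen_depth_mm
    R = flow.profile_radius_mm
    if flow.profile_shape == "plug":
        weight = np.where(np.abs(offs) <= R, 1.0, 0.0)
    else:
        weight = np.clip(1.0 - (offs / R) ** 2, 0.0, None)
    in_lumen = weight > 0

    ux, uz = flow.direction
    rng = np.random.default_rng(seed)
    noise_power = 10.0 ** (-snr_db / 10.0)
    clutter_amp = 10.0 ** (clutter_db / 20.0)

    out = []
    for side, sign in (("left", -1.0), ("right", +1.0)):
        samples = np.zeros((n_gates, n_slow), dtype=np.complex128)
        k = 2.0 * geom.tx_frequency_ftx / cfg.sound_speed_c
        s_half = math.sin(geom.theta_rad / 2.0)
        c_half = math.cos(geom.theta_rad / 2.0)
        # per-gate, per-sample instantaneous Doppler frequency
        v_gate = weight[in_lumen, None] * wf[None, :]          # (n_in, n_slow)
        fd = k * (sign * ux * s_half + uz * c_half) * v_gate
        phase = 2.0 * np.pi * np.cumsum(fd, axis=1) / cfg.prf_per_beam
        samples[in_lumen] = weight[in_lumen, None] * np.exp(1j * phase)

        # near-DC clutter: slow complex drift common to all tissue
        f_cl = rng.uniform(-5.0, 5.0, size=(n_gates, 1))
        ph0 = rng.uniform(0, 2 * np.pi, size=(n_gates, 1))
        t = np.arange(n_slow) / cfg.prf_per_beam
        samples += clutter_amp * np.exp(1j * (2 * np.pi * f_cl * t[None, :] + ph0))

        noise = rng.standard_normal((n_gates, n_slow)) + 1j * rng.standard_normal(
            (n_gates, n_slow)
        )
        samples += math.sqrt(noise_power / 2.0) * noise

        out.append(
            IQEnsemble(
                samples=samples,
                prf=cfg.prf_per_beam,
                gate_spacing_mm=cfg.gate_spacing * 1e3,
                first_gate_depth_mm=cfg.first_gate_depth * 1e3,
                side=side,
            )
        )
    return out[0], out[1]
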