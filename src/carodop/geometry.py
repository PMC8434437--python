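"""Probe geometry and acquisition configuration.

The sensor is a pair of identical linear arrays mounted on a rigid holder so
that their depth axes form a fixed inter-angle ``theta`` (default 30 deg).
Placed transversally on the neck, each array insonates the common carotid
artery from a different direction, which makes angle-corrected (vector)
Doppler velocimetry possible without operator input.

All lengths are SI metres, frequencies Hz, angles degrees at the interface
(radians internally).  Sound speed defaults to 1540 m/s, the standard
soft-tissue value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass(frozen=True)
class ProbeGeometry:
    """Dual linear-array probe configuration.

    Parameters
    ----------
    n_elements : int
        Transducer elements per array.
    active_elements : int
        Elements used in the active aperture.
    pitch : float
        Element pitch in metres.
    inter_angle_theta : float
        Angle theta between the two array axes, degrees, in (0, 90).
    array_gap : float
        Gap between the two arrays at the skin plane, metres.
    cross_depth : float
        Depth at which the two beam axes cross, metres.  Treated as the
        authoritative geometric given; the beam-origin separation is derived
        from it (see :func:`beam_origin_separation`).
    tx_frequency_ftx : float
        Transmit centre frequency, Hz.
    tx_cycles : int
        Sinusoidal cycles per Doppler transmission burst.
    elevation_focus : float
        Elevation focus depth, metres.
    """

    n_elements: int = 128
    active_elements: int = 96
    pitch: float = 300e-6
    inter_angle_theta: float = 30.0
    array_gap: float = 11e-3
    cross_depth: float = 23e-3
    tx_frequency_ftx: float = 7.5e6
    tx_cycles: int = 3
    elevation_focus: float = 20e-3

    def __post_init__(self) -> None:
        if not 0.0 < self.inter_angle_theta < 90.0:
            raise ValueError(f"inter_angle_theta must be in (0, 90) deg, got {self.inter_angle_theta}")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.active_elements > self.n_elements:
            raise ValueError("active_elements cannot exceed n_elements")
        if self.tx_frequency_ftx <= 0:
            raise ValueError("tx_frequency_ftx must be positive")

    @property
    def theta_rad(self) -> float:
        return math.radians(self.inter_angle_theta)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition parameters shared by the B-mode and Doppler phases.

    ``prf_per_beam`` is the pulse repetition frequency of each beam; the two
    beams are interleaved, so the combined transmission rate is twice this.
    ``n_gates`` depth gates spaced ``gate_spacing`` apart are estimated
    simultaneously (multigate Doppler); the velocity search is restricted to
    a ``roi_extent`` window centred on the segmented lumen depth.
    """

    sound_speed_c: float = 1540.0
    prf_per_beam: float = 8000.0
    packet_size: int = 128
    packet_overlap: float = 0.5
    clutter_cutoff: float = 100.0
    n_gates: int = 512
    gate_spacing: float = 0.15e-3
    first_gate_depth: float = 2e-3
    roi_extent: float = 6e-3
    bmode_frames: int = 15

    def __post_init__(self) -> None:
        if not 0.0 <= self.packet_overlap < 1.0:
            raise ValueError("packet_overlap must be in [0, 1)")
        if self.packet_size < 2:
            raise ValueError("packet_size must be >= 2")
        if self.prf_per_beam <= 2.0 * self.clutter_cutoff:
            raise ValueError("prf_per_beam must exceed twice the clutter cutoff")
        if self.roi_extent <= 0:
            raise ValueError("roi_extent must be positive")

    @property
    def gate_depths_mm(self):
        import numpy as np

        return (self.first_gate_depth + np.arange(self.n_gates) * self.gate_spacing) * 1e3


def doppler_angles(geom: ProbeGeometry) -> tuple[float, float]:
    """Doppler angles (deg) of the two beams relative to a horizontal vessel.

    With the probe perpendicular to the vessel the beams see the flow at
    ``90 - theta/2`` and ``90 + theta/2`` degrees; the pair always sums to
    180 deg.
    """
    half = geom.inter_angle_theta / 2.0
    return (90.0 - half, 90.0 + half)


def max_unambiguous_depth(cfg: AcquisitionConfig) -> float:
    """Maximum depth (m) reachable without range ambiguity: c / (2 PRF)."""
    if cfg.prf_per_beam <= 0:
        raise ValueError("PRF must be positive")
    return cfg.sound_speed_c / (2.0 * cfg.prf_per_beam)


def max_detectable_velocity(
    cfg: AcquisitionConfig, geom: ProbeGeometry, angle_deg: float
) -> float:
    """Maximum detectable velocity (m/s) using the full PRF range.

    The full span of the sampled Doppler spectrum is PRF (not PRF/2), so the
    largest recoverable shift is fd_max = PRF, giving
    ``c * PRF / (2 * ftx * |cos(angle)|)``.  Use
    :func:`nyquist_velocity` for the conventional single-sided (PRF/2) limit.
    """
    c = math.cos(math.radians(angle_deg))
    if abs(c) < 1e-12:
        raise ValueError("Doppler angle of 90 deg has no axial velocity component")
    return cfg.sound_speed_c * cfg.prf_per_beam / (2.0 * geom.tx_frequency_ftx * abs(c))


def nyquist_velocity(cfg: AcquisitionConfig, geom: ProbeGeometry, angle_deg: float) -> float:
    """Velocity limit (m/s) at the Nyquist shift PRF/2 (half the full-range limit)."""
    return 0.5 * max_detectable_velocity(cfg, geom, angle_deg)


def sample_volume_axial_extent(geom: ProbeGeometry, cfg: AcquisitionConfig) -> float:
    """Axial extent (m) of the Doppler sample volume: tx_cycles wavelengths."""
    if geom.tx_cycles < 1:
        raise ValueError("tx_cycles must be >= 1")
    return geom.tx_cycles * cfg.sound_speed_c / geom.tx_frequency_ftx


def active_aperture(n_active: int, pitch: float) -> float:
    """Active aperture length (m): element count times pitch."""
    if n_active < 0:
        raise ValueError("n_active must be non-negative")
    return n_active * pitch


def beam_cross_depth(beam_origin_separation: float, theta_deg: float) -> float:
    """Depth (m) at which two beams separated by ``s`` at the skin cross.

    Each beam is inclined theta/2 from vertical towards the other, so
    ``d = s / (2 tan(theta/2))``.
    """
    if theta_deg <= 0:
        raise ValueError("parallel beams (theta = 0) never cross")
    return beam_origin_separation / (2.0 * math.tan(math.radians(theta_deg) / 2.0))


def beam_origin_separation(geom: ProbeGeometry) -> float:
    """Beam-origin separation (m) at the skin implied by the cross depth."""
    return 2.0 * geom.cross_depth * math.tan(geom.theta_rad / 2.0)


_UNITS = {
    "pitch": "m", "array_gap": "m", "cross_depth": "m", "elevation_focus": "m",
    "tx_frequency_ftx": "Hz", "inter_angle_theta": "deg",
    "sound_speed_c": "m/s", "prf_per_beam": "Hz", "clutter_cutoff": "Hz",
    "gate_spacing": "m", "first_gate_depth": "m", "roi_extent": "m",
    "packet_overlap": "fraction",
}


def save_config(geom: ProbeGeometry, cfg: AcquisitionConfig, path: str | Path) -> None:
    """Serialize geometry + acquisition config to one JSON document."""
    doc = {
        "probe_geometry": asdict(geom),
        "acquisition": asdict(cfg),
        "units": _UNITS,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_config(path: str | Path) -> tuple[ProbeGeometry, AcquisitionConfig]:
    """Load a JSON document written by :func:`save_config`."""
    doc = json.loads(Path(path).read_text())
    return ProbeGeometry(**doc["probe_geometry"]), AcquisitionConfig(**doc["acquisition"])
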