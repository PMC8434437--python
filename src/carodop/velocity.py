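"""Dual-beam velocity triangulation and peak extraction.

The two beams see the flow at 90 - theta/2 and 90 + theta/2 degrees; their
centroid Doppler shifts fdr, fdl at the same depth and time are triangulated
into the lateral and axial velocity components

    Vx = c (fdr - fdl) / (4 ftx sin(theta/2))
    Vz = c (fdr + fdl) / (4 ftx cos(theta/2))

and the angle-corrected magnitude V = sqrt(Vx^2 + Vz^2).  The single
measurement output is the maximum of V over the Doppler region of interest
(depth) and over time, with basic sanity checks: flow direction must match
the expected carotid direction, and the peak must fall in a plausible band.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import AcquisitionConfig, ProbeGeometry, max_detectable_velocity, doppler_angles
from .spectral import FrequencyMap


@dataclass
class VelocityMap:
    """Angle-corrected velocity fields over (packet time, ROI gate)."""

    Vx: np.ndarray
    Vz: np.ndarray
    V: np.ndarray
    packet_times: np.ndarray
    gate_depths_mm: np.ndarray

    @property
    def roi_depth_range(self) -> tuple[float, float]:
        return (float(self.gate_depths_mm[0]), float(self.gate_depths_mm[-1]))


@dataclass
class MeasurementResult:
    """The single peak-velocity output with validity status."""

    peak_velocity: float = np.nan   # m/s
    peak_time: float = np.nan       # s
    peak_depth: float = np.nan      # mm
    status: str = "ok"              # "ok" | "discarded"
    discard_reason: str = ""
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "peak_velocity_m_s": None if np.isnan(self.peak_velocity) else self.peak_velocity,
            "peak_time_s": None if np.isnan(self.peak_time) else self.peak_time,
            "peak_depth_mm": None if np.isnan(self.peak_depth) else self.peak_depth,
            "status": self.status,
            "discard_reason": self.discard_reason,
            "provenance": self.provenance,
        }
        return json.dumps(doc, indent=2)


def config_digest(geom: ProbeGeometry, cfg: AcquisitionConfig) -> str:
    """Short stable digest of the effective configuration, for provenance."""
    blob = json.dumps({"geom": asdict(geom), "cfg": asdict(cfg)}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def select_roi(
    depth_left_mm: float,
    depth_right_mm: float,
    roi_extent_mm: float,
    gate_depths_mm: np.ndarray,
) -> tuple[int, int]:
    """Contiguous gate index range [i0, i1) of the Doppler ROI.

    The ROI is centred on the mean of the two segmented lumen depths with
    total extent ``roi_extent_mm``, shifted (not shrunk) where it would
    overrun the gated depth range.
    """
    gate_depths_mm = np.asarray(gate_depths_mm)
    center = 0.5 * (depth_left_mm + depth_right_mm)
    lo = center - roi_extent_mm / 2.0
    hi = center + roi_extent_mm / 2.0
    if hi < gate_depths_mm[0] or lo > gate_depths_mm[-1]:
        raise ValueError("ROI entirely outside the gated depth range")
    if lo < gate_depths_mm[0]:
        hi += gate_depths_mm[0] - lo
        lo = gate_depths_mm[0]
    if hi > gate_depths_mm[-1]:
        lo -= hi - gate_depths_mm[-1]
        hi = gate_depths_mm[-1]
        lo = max(lo, gate_depths_mm[0])
    i0 = int(np.searchsorted(gate_depths_mm, lo - 1e-9, side="left"))
    i1 = int(np.searchsorted(gate_depths_mm, hi + 1e-9, side="right"))
    return i0, max(i1, i0 + 1)


def triangulate(fdr, fdl, geom: ProbeGeometry, cfg: AcquisitionConfig):
    """Invert the dual-beam Doppler equations to (Vx, Vz) in m/s.

    Undefined (NaN) frequencies propagate to undefined velocities.
    """
    s = math.sin(geom.theta_rad / 2.0)
    c = math.cos(geom.theta_rad / 2.0)
    if s <= 0:
        raise ValueError("theta = 0 leaves Vx unobservable")
    k = cfg.sound_speed_c / (4.0 * geom.tx_frequency_ftx)
    fdr = np.asarray(fdr, dtype=float)
    fdl = np.asarray(fdl, dtype=float)
    Vx = k * (fdr - fdl) / s
    Vz = k * (fdr + fdl) / c
    if Vx.ndim == 0:
        return float(Vx), float(Vz)
    return Vx, Vz


def velocity_magnitude(Vx, Vz):
    """Angle-corrected speed |V| = sqrt(Vx^2 + Vz^2)."""
    out = np.hypot(np.asarray(Vx, dtype=float), np.asarray(Vz, dtype=float))
    return float(out) if out.ndim == 0 else out


def velocity_map(
    fmap_left: FrequencyMap,
    fmap_right: FrequencyMap,
    geom: ProbeGeometry,
    cfg: AcquisitionConfig,
) -> VelocityMap:
    """Pairwise triangulation of the left/right frequency maps.

    Packet k of one side pairs with packet k of the other (the interleave
    offset between beams is negligible at carotid time scales); entries where
    either side is undefined are undefined in the result.
    """
    n = min(fmap_left.n_packets, fmap_right.n_packets)
    fdl = fmap_left.fd[:n]
    fdr = fmap_right.fd[:n]
    Vx, Vz = triangulate(fdr, fdl, geom, cfg)
    return VelocityMap(
        Vx=Vx, Vz=Vz, V=np.hypot(Vx, Vz),
        packet_times=fmap_left.packet_times[:n],
        gate_depths_mm=np.asarray(fmap_left.gate_depths_mm),
    )


def peak_velocity(vmap: VelocityMap, provenance: dict | None = None) -> MeasurementResult:
    """Maximum of |V| over depth and time; the single measurement output."""
    V = vmap.V
    if V.size == 0 or np.all(np.isnan(V)):
        return MeasurementResult(
            status="discarded", discard_reason="no signal",
            provenance=provenance or {},
        )
    idx = np.unravel_index(np.nanargmax(V), V.shape)
    return MeasurementResult(
        peak_velocity=float(V[idx]),
        peak_time=float(vmap.packet_times[idx[0]]),
        peak_depth=float(vmap.gate_depths_mm[idx[1]]),
        status="ok",
        provenance=provenance or {},
    )


def validate(
    result: MeasurementResult,
    vmap: VelocityMap,
    expected_flow_sign: int = +1,
    geom: ProbeGeometry | None = None,
    cfg: AcquisitionConfig | None = None,
    v_min: float = 0.05,
    v_max: float | None = None,
) -> MeasurementResult:
    """Sanity checks that catch obviously wrong measurements.

    A lateral-velocity sign opposite to the expected carotid flow direction
    (both at the peak and in the ROI median) indicates a lock onto the wrong
    vessel (e.g. the jugular vein) and discards the measurement; a peak
    outside the plausibility band (default 0.05 m/s to the full-PRF-range
    velocity limit) is discarded as implausible.
    """
    if result.status == "discarded":
        return result
    if v_max is None:
        if geom is not None and cfg is not None:
            ang = doppler_angles(geom)[0]
            v_max = max_detectable_velocity(cfg, geom, ang)
        else:
            v_max = 3.0

    t_idx = int(np.argmin(np.abs(vmap.packet_times - result.peak_time)))
    d_idx = int(np.argmin(np.abs(vmap.gate_depths_mm - result.peak_depth)))
    vx_peak = vmap.Vx[t_idx, d_idx]
    with np.errstate(all="ignore"):
        vx_median = np.nanmedian(vmap.Vx)

    if expected_flow_sign != 0 and np.sign(vx_peak) == -np.sign(expected_flow_sign) \
            and np.sign(vx_median) == -np.sign(expected_flow_sign):
        return MeasurementResult(
            peak_velocity=result.peak_velocity, peak_time=result.peak_time,
            peak_depth=result.peak_depth, status="discarded",
            discard_reason="wrong direction", provenance=result.provenance,
        )
    if not (v_min <= result.peak_velocity <= v_max):
        return MeasurementResult(
            peak_velocity=result.peak_velocity, peak_time=result.peak_time,
            peak_depth=result.peak_depth, status="discarded",
            discard_reason="implausible", provenance=result.provenance,
        )
    return result
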