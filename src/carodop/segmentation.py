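"""Automatic lumen localization in transversal B-mode sequences.

In a transverse view the carotid lumen appears as a dark, roughly circular
anechoic region surrounded by brighter tissue.  The detector therefore:

1. stretches brightness/contrast and smooths each frame with a strong
   Gaussian filter (speckle suppression),
2. runs a gradient circular Hough transform restricted to dark-interior
   circles with radii in a physiological range (default 2.1-4.0 mm),
3. elects the darkest-interior circle of each frame as that frame's
   candidate, and
4. takes the modal (most frequent) quantized (x, y, r) triad over the frame
   sequence as the consensus detection.

Coordinates: x = lateral position (mm, image-left negative), y = depth from
the transducer face (mm, positive downward).  Because B-mode pixels are
anisotropic, frames are resampled to an isotropic grid before the Hough
accumulation; all results are reported in millimetres.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature


@dataclass
class BModeSequence:
    """Stack of grayscale B-mode frames with physical pixel spacing.

    frames : (n_frames, depth_px, lateral_px), 8-bit intensities.
    pixel_spacing : (axial_mm, lateral_mm) per pixel.
    lateral_origin : x coordinate (mm) of the first column.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    lateral_origin: float = 0.0
    side: str = "left"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, depth, lateral)")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class CircleCandidate:
    x: float        # lateral, mm
    y: float        # depth, mm
    r: float        # radius, mm
    darkness: float = np.nan  # mean interior intensity
    frame_index: int = -1
    score: float = 0.0        # Hough accumulator value


@dataclass
class LumenDetection:
    xc: float
    yc: float
    rc: float
    per_frame_candidates: list = field(default_factory=list)
    n_supporting_frames: int = 0
    status: str = "ok"        # "ok" | "failed"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the lumen detector.

    r_min_mm, r_max_mm : admissible lumen radius range.
    smooth_sigma_mm : Gaussian smoothing, isotropic in physical units.
    stretch_percentiles : contrast-stretch anchors.
    iso_spacing_mm : isotropic grid for the Hough accumulation; also the
        quantization step of the consensus mode.
    accumulator_threshold : candidate peaks must exceed this fraction of the
        accumulator maximum.
    canny_quantiles : automatic hysteresis thresholds (low, high) as
        intensity-gradient quantiles.
    darkness_radius_fraction : interior darkness averaged over pixels within
        this fraction of the radius.
    min_support : minimum number of frames that must contribute a candidate.
    """

    r_min_mm: float = 2.1
    r_max_mm: float = 4.0
    smooth_sigma_mm: float = 0.5
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    iso_spacing_mm: float = 0.15
    accumulator_threshold: float = 0.5
    canny_sigma_mm: float = 0.3
    canny_quantiles: tuple[float, float] = (0.80, 0.95)
    darkness_radius_fraction: float = 0.9
    accumulator_smooth_px: float = 1.5
    min_support: int = 3
    max_candidates: int = 8


def preprocess_frame(
    frame: np.ndarray,
    pixel_spacing: tuple[float, float],
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Brightness/contrast optimization followed by strong Gaussian smoothing.

    Intensities are linearly stretched between the configured percentiles to
    [0, 255] (a constant image passes through unchanged), then smoothed with
    an isotropic-in-mm Gaussian that suppresses speckle grain while
    preserving lumen-scale structure.
    """
    params = params or SegmentationParams()
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    lo, hi = np.percentile(frame, params.stretch_percentiles)
    if hi > lo:
        frame = np.clip((frame - lo) / (hi - lo), 0.0, 1.0) * 255.0
    sigma_px = (params.smooth_sigma_mm / pixel_spacing[0],
                params.smooth_sigma_mm / pixel_spacing[1])
    return ndimage.gaussian_filter(frame, sigma_px)


def _to_isotropic(frame: np.ndarray, pixel_spacing, iso_mm: float) -> np.ndarray:
    zoom = (pixel_spacing[0] / iso_mm, pixel_spacing[1] / iso_mm)
    return ndimage.zoom(frame, zoom, order=1)


def detect_dark_circles(
    frame: np.ndarray,
    pixel_spacing: tuple[float, float],
    lateral_origin: float = 0.0,
    params: SegmentationParams | None = None,
    frame_index: int = -1,
) -> list[CircleCandidate]:
    """Gradient circular Hough transform restricted to dark-interior circles.

    Canny edges (automatic hysteresis from gradient quantiles) vote at a
    distance r *against* the local gradient direction; since the intensity
    gradient at the rim of a dark disk points outward, votes from bright-
    interior circles scatter and only dark-interior circles accumulate.
    Returns all accumulator peaks above the configured fraction of the
    maximum, in physical (mm) coordinates.
    """
    params = params or SegmentationParams()
    iso = params.iso_spacing_mm
    r_min_px = int(np.floor(params.r_min_mm / iso))
    r_max_px = int(np.floor(params.r_max_mm / iso + 1e-9))  # stay within range
    if r_min_px < 2:
        raise ValueError("radius range below 2 pixels on the isotropic grid")
    if params.r_min_mm >= params.r_max_mm:
        raise ValueError("r_min must be below r_max")

    img = _to_isotropic(np.asarray(frame, dtype=float), pixel_spacing, iso)
    h, w = img.shape
    rng = img.max() - img.min()
    if rng <= 1e-6 * (abs(img.max()) + 1.0):  # flat frame: nothing to detect
        return []
    norm = (img - img.min()) / rng

    edges = feature.canny(
        norm,
        sigma=params.canny_sigma_mm / iso,
        low_threshold=params.canny_quantiles[0],
        high_threshold=params.canny_quantiles[1],
        use_quantiles=True,
    )
    ey, ex = np.nonzero(edges)
    if ey.size == 0:
        return []

    gy = ndimage.sobel(norm, axis=0)
    gx = ndimage.sobel(norm, axis=1)
    gmag = np.hypot(gy[ey, ex], gx[ey, ex])
    good = gmag > 1e-12
    ey, ex, gmag = ey[good], ex[good], gmag[good]
    uy = gy[ey, ex] / gmag
    ux = gx[ey, ex] / gmag

    radii = np.arange(r_min_px, r_max_px + 1)
    acc = np.zeros((len(radii), h, w), dtype=np.float32)
    for i, r in enumerate(radii):
        # dark interior: gradient points outward, centre lies up-gradient inward
        cy = np.rint(ey - r * uy).astype(int)
        cx = np.rint(ex - r * ux).astype(int)
        ok = (cy >= 0) & (cy < h) & (cx >= 0) & (cx < w)
        np.add.at(acc[i], (cy[ok], cx[ok]), 1.0)
        acc[i] = ndimage.gaussian_filter(acc[i], params.accumulator_smooth_px)

    peak = acc.max()
    if peak <= 0:
        return []
    thr = params.accumulator_threshold * peak
    maxed = ndimage.maximum_filter(acc, size=(3, 5, 5), mode="constant")
    ri, yi, xi = np.nonzero((acc >= thr) & (acc == maxed))
    order = np.argsort(acc[ri, yi, xi])[::-1][: params.max_candidates]

    out = []
    for k in order:
        out.append(
            CircleCandidate(
                x=lateral_origin + xi[k] * iso,
                y=yi[k] * iso,
                r=radii[ri[k]] * iso,
                frame_index=frame_index,
                score=float(acc[ri[k], yi[k], xi[k]]),
            )
        )
    return out


def _interior_mean(frame, pixel_spacing, cand: CircleCandidate,
                   lateral_origin: float, fraction: float) -> float:
    ys = (np.arange(frame.shape[0])) * pixel_spacing[0]
    xs = lateral_origin + np.arange(frame.shape[1]) * pixel_spacing[1]
    dist2 = (ys[:, None] - cand.y) ** 2 + (xs[None, :] - cand.x) ** 2
    mask = dist2 <= (fraction * cand.r) ** 2
    if not mask.any():
        return float("inf")
    return float(np.asarray(frame, dtype=float)[mask].mean())


def select_darkest(
    frame: np.ndarray,
    candidates: list[CircleCandidate],
    pixel_spacing: tuple[float, float],
    lateral_origin: float = 0.0,
    params: SegmentationParams | None = None,
) -> CircleCandidate | None:
    """Elect the candidate with the darkest interior (on the given frame).

    Darkness is the mean intensity over pixels within 0.9 r of the centre.
    Ties break deterministically: lowest darkness, then smallest depth, then
    smallest |x|.  Returns None for an empty candidate list.
    """
    params = params or SegmentationParams()
    if not candidates:
        return None
    for c in candidates:
        c.darkness = _interior_mean(
            frame, pixel_spacing, c, lateral_origin, params.darkness_radius_fraction
        )
    return min(candidates, key=lambda c: (c.darkness, c.y, abs(c.x)))


def consensus(
    per_frame: list[CircleCandidate | None],
    params: SegmentationParams | None = None,
) -> LumenDetection:
    """Modal quantized (x, y, r) triad over the per-frame candidates.

    Centres and radii are quantized to the isotropic Hough grid; the most
    frequent triad wins.  Ties break by lowest mean darkness, then smallest
    depth, then smallest |x|.  status="failed" when fewer than
    ``min_support`` frames contributed a candidate.
    """
    params = params or SegmentationParams()
    present = [c for c in per_frame if c is not None]
    if len(present) < params.min_support:
        return LumenDetection(
            xc=np.nan, yc=np.nan, rc=np.nan,
            per_frame_candidates=present, n_supporting_frames=len(present),
            status="failed",
        )
    q = params.iso_spacing_mm
    triads = [(round(c.x / q), round(c.y / q), round(c.r / q)) for c in present]
    counts = Counter(triads)
    best_count = max(counts.values())
    tied = [t for t, n in counts.items() if n == best_count]

    def tie_key(t):
        members = [c for c, tr in zip(present, triads) if tr == t]
        dark = float(np.mean([c.darkness for c in members]))
        return (dark, t[1], abs(t[0]))

    winner = min(tied, key=tie_key)
    return LumenDetection(
        xc=winner[0] * q, yc=winner[1] * q, rc=winner[2] * q,
        per_frame_candidates=present, n_supporting_frames=best_count,
        status="ok",
    )


def segment_sequence(
    seq: BModeSequence, params: SegmentationParams | None = None
) -> LumenDetection:
    """Full per-sequence lumen detection: preprocess, detect, elect, vote."""
    params = params or SegmentationParams()
    per_frame: list[CircleCandidate | None] = []
    for i in range(seq.n_frames):
        pre = preprocess_frame(seq.frames[i], seq.pixel_spacing, params)
        cands = detect_dark_circles(
            pre, seq.pixel_spacing, seq.lateral_origin, params, frame_index=i
        )
        per_frame.append(
            select_darkest(pre, cands, seq.pixel_spacing, seq.lateral_origin, params)
        )
    return consensus(per_frame, params)
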