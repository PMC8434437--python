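"""Multigate spectral Doppler processing.

Each beam delivers a complex IQ ensemble sampled at the PRF along slow time
for every depth gate.  Processing follows the classic pulsed-wave chain:
a high-pass clutter (wall) filter removes the strong near-DC tissue echo,
the slow-time signal is split into overlapping packets, each packet is
Fourier transformed, and a single Doppler frequency per (packet, gate) is
extracted as a noise-robust spectral centroid.

The centroid estimator is a modified centre-of-mass: the noise floor
(mean of the lowest quartile of spectral bins) is subtracted, negative
residuals are clipped, bins below a fraction of the residual peak are
excluded, and spectra whose raw peak does not stand sufficiently above the
median bin are declared undefined (NaN) rather than contributing a random
frequency.  Undefined entries are excluded from all downstream maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .geometry import AcquisitionConfig

UNDEFINED = np.nan


@dataclass
class IQEnsemble:
    """Complex baseband Doppler ensemble for one beam.

    ``samples`` is (n_gates, n_slow_time); slow time is sampled at ``prf``.
    Depth of gate *g* is ``first_gate_depth_mm + g * gate_spacing_mm``.
    """

    samples: np.ndarray
    prf: float
    gate_spacing_mm: float
    first_gate_depth_mm: float
    side: str = "left"

    def __post_init__(self) -> None:
        if self.prf <= 0:
            raise ValueError("prf must be positive")
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (gates x slow time)")

    @property
    def n_gates(self) -> int:
        return self.samples.shape[0]

    @property
    def n_slow_time(self) -> int:
        return self.samples.shape[1]

    @property
    def gate_depths_mm(self) -> np.ndarray:
        return self.first_gate_depth_mm + np.arange(self.n_gates) * self.gate_spacing_mm

    def slice_gates(self, i0: int, i1: int) -> "IQEnsemble":
        """View of gates [i0, i1)."""
        return IQEnsemble(
            samples=self.samples[i0:i1],
            prf=self.prf,
            gate_spacing_mm=self.gate_spacing_mm,
            first_gate_depth_mm=self.first_gate_depth_mm + i0 * self.gate_spacing_mm,
            side=self.side,
        )


@dataclass
class FrequencyMap:
    """Centroid Doppler frequency over (packet time, depth gate) for one beam."""

    fd: np.ndarray            # Hz, (n_packets, n_gates); NaN = undefined
    packet_times: np.ndarray  # s, packet centres
    gate_depths_mm: np.ndarray
    side: str = "left"

    @property
    def n_packets(self) -> int:
        return self.fd.shape[0]


@dataclass(frozen=True)
class CentroidParams:
    """Tuning of the modified centre-of-mass estimator.

    noise_quantile : fraction of lowest bins averaged as the noise floor.
    peak_exclusion : bins below this fraction of the residual peak are
        excluded from the mass.
    detect_factor : a spectrum is declared undefined unless its raw maximum
        exceeds this multiple of the raw median bin (signal-presence test).
    """

    noise_quantile: float = 0.25
    peak_exclusion: float = 0.10
    detect_factor: float = 40.0


def clutter_filter(ens: IQEnsemble, cutoff: float | None = None, order: int = 4) -> IQEnsemble:
    """High-pass wall filter along slow time, removing the near-DC tissue echo.

    Zero-phase (forward-backward) Butterworth filtering is used so that no
    slow-time samples are lost to the filter transient and the packet grid
    is unchanged.

    Parameters
    ----------
    cutoff : float
        Stop-band edge in Hz (default 100).  Must be below prf/2.
    """
    cutoff = 100.0 if cutoff is None else float(cutoff)
    if cutoff >= ens.prf / 2.0:
        raise ValueError(f"clutter cutoff {cutoff} Hz must be below prf/2 = {ens.prf / 2}")
    sos = sps.butter(order, cutoff, btype="highpass", fs=ens.prf, output="sos")
    x = ens.samples.astype(np.complex128, copy=False)
    # generous padding lets the edge transient of strong clutter settle
    # inside the pad instead of leaking broadband power into the end packets
    padlen = int(min(x.shape[1] - 1, 3 * ens.prf / cutoff))
    filtered = (sps.sosfiltfilt(sos, x.real, axis=1, padlen=padlen)
                + 1j * sps.sosfiltfilt(sos, x.imag, axis=1, padlen=padlen))
    return IQEnsemble(
        samples=filtered,
        prf=ens.prf,
        gate_spacing_mm=ens.gate_spacing_mm,
        first_gate_depth_mm=ens.first_gate_depth_mm,
        side=ens.side,
    )


def packet_starts(n_slow_time: int, packet_size: int, overlap: float) -> np.ndarray:
    """Start indices of overlapping slow-time packets.

    hop = packet_size*(1-overlap); packet k covers [k*hop, k*hop+packet_size).
    """
    if n_slow_time < packet_size:
        raise ValueError(f"need at least {packet_size} slow-time samples, got {n_slow_time}")
    hop = int(round(packet_size * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too close to 1: empty hop")
    n_packets = (n_slow_time - packet_size) // hop + 1
    return np.arange(n_packets) * hop


def make_packets(x: np.ndarray, packet_size: int, overlap: float) -> np.ndarray:
    """Split slow time (last axis) into overlapping packets.

    Returns an array with shape (..., n_packets, packet_size); a view, no copy.
    """
    starts = packet_starts(x.shape[-1], packet_size, overlap)
    hop = starts[1] - starts[0] if len(starts) > 1 else 1
    win = sliding_window_view(x, packet_size, axis=-1)
    return win[..., ::hop, :][..., : len(starts), :]


def power_spectrum(packets: np.ndarray, prf: float, window: str = "hann"):
    """Windowed periodogram of each packet on the two-sided frequency axis.

    Returns (power, freqs) with freqs on [-prf/2, prf/2), bin width
    prf/packet_size.  Power is normalized by the window's power gain so that
    total spectral power equals mean signal power.
    """
    packets = np.asarray(packets)
    n = packets.shape[-1]
    w = sps.get_window(window, n, fftbins=True)
    spec = np.fft.fftshift(np.fft.fft(packets * w, axis=-1), axes=-1)
    power = (np.abs(spec) ** 2) / (n * np.sum(w**2))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / prf))
    return power, freqs


def centroid_frequency(
    spectrum: np.ndarray, freqs: np.ndarray, params: CentroidParams | None = None
) -> np.ndarray | float:
    """Modified centre-of-mass Doppler frequency of power spectra.

    Works on a single spectrum or any stack with frequency on the last axis.
    Returns NaN where no signal stands above the noise.
    """
    params = params or CentroidParams()
    spec = np.atleast_2d(np.asarray(spectrum, dtype=float))
    squeeze = np.asarray(spectrum).ndim == 1
    nbins = spec.shape[-1]

    srt = np.sort(spec, axis=-1)
    k = max(1, int(nbins * params.noise_quantile))
    floor = srt[..., :k].mean(axis=-1, keepdims=True)
    median = srt[..., nbins // 2][..., None]

    residual = np.clip(spec - floor, 0.0, None)
    peak = residual.max(axis=-1, keepdims=True)
    mass = np.where(residual >= params.peak_exclusion * peak, residual, 0.0)
    total = mass.sum(axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        fd = (mass * freqs).sum(axis=-1) / total

    raw_max = spec.max(axis=-1)
    detected = raw_max > params.detect_factor * np.squeeze(median, axis=-1)
    detected &= total > 0
    fd = np.where(detected, fd, UNDEFINED)
    return float(fd[0]) if squeeze else fd.reshape(np.asarray(spectrum).shape[:-1])


def frequency_map(
    ens: IQEnsemble,
    cfg: AcquisitionConfig,
    params: CentroidParams | None = None,
    apply_clutter_filter: bool = True,
) -> FrequencyMap:
    """Full chain: clutter filter -> packets -> FFT -> centroid per (packet, gate)."""
    work = clutter_filter(ens, cfg.clutter_cutoff) if apply_clutter_filter else ens
    packets = make_packets(work.samples, cfg.packet_size, cfg.packet_overlap)
    power, freqs = power_spectrum(packets, ens.prf)  # (gates, packets, bins)
    fd = centroid_frequency(power.reshape(-1, power.shape[-1]), freqs, params)
    fd = fd.reshape(power.shape[:2]).T  # (packets, gates)
    starts = packet_starts(work.n_slow_time, cfg.packet_size, cfg.packet_overlap)
    times = (starts + cfg.packet_size / 2.0) / ens.prf
    return FrequencyMap(
        fd=fd, packet_times=times, gate_depths_mm=ens.gate_depths_mm, side=ens.side
    )
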