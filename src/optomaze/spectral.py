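"""Spectral image-regularity metric for rendered movies.

Each frame is converted to luminance, every pixel row is Fourier
transformed, and the per-bin power ``|F_k|^2 / width`` is averaged over
rows and then over frames. The movie's "image regularity" is the peak of
the mean spectrum with the DC bin excluded — large for a periodic grating,
small for broadband dot fields. Because power discards phase, the metric
is insensitive to translation, i.e. to the motion itself.

Normalization: power at bin k is ``|F_k|^2 / width`` with the NumPy DFT
convention, averaged over rows. Under this constant, Parseval's identity
reads ``P_0 + P_{w/2} + 2·sum(P_middle) = width · mean(lum^2)`` for even
widths. Frequencies are reported in cycles per image width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .stimuli import FrameSequence, ScreenGeometry

__all__ = [
    "SpectrumSummary",
    "to_luminance",
    "frame_power_spectrum",
    "movie_spectrum",
    "peak_power",
]


@dataclass(frozen=True)
class SpectrumSummary:
    """Frame-averaged row power spectrum of a movie, with its non-DC peak."""

    frequencies: np.ndarray   # integer bins, cycles per image width, 0..w//2
    mean_power: np.ndarray
    sem_power: np.ndarray
    n_frames: int
    peak_power: float
    peak_frequency: int

    def __post_init__(self) -> None:
        if np.any(self.mean_power < 0):
            raise ValueError("mean power must be non-negative")
        if self.peak_frequency < 1:
            raise ValueError("peak frequency excludes the DC bin")

    def frequencies_cpd(self, geometry: ScreenGeometry) -> np.ndarray:
        """Convert bin frequencies to cycles per visual degree."""
        return np.asarray(self.frequencies) / geometry.width_deg


def to_luminance(frame: np.ndarray) -> np.ndarray:
    """Unweighted mean of the three channels, per pixel (range [0, 255])."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected an (h, w, 3) RGB frame, got shape {frame.shape}")
    f = frame.astype(np.float64)
    if f.min() < 0 or f.max() > 255:
        raise ValueError("frame intensities must lie in [0, 255]")
    return f.mean(axis=-1)


def frame_power_spectrum(lum: np.ndarray) -> np.ndarray:
    """Row-averaged power spectrum of a luminance image.

    Returns power per integer frequency bin 0..w//2 (cycles per image
    width), normalized as ``|F_k|^2 / width`` and averaged over rows.
    """
    lum = np.asarray(lum, dtype=np.float64)
    if lum.ndim != 2:
        raise ValueError("expected a 2-D luminance array")
    if lum.shape[1] < 4:
        raise ValueError("image width must be at least 4 pixels")
    if not np.all(np.isfinite(lum)):
        raise ValueError("luminance contains non-finite values")
    coeffs = np.fft.rfft(lum, axis=1)
    power = (np.abs(coeffs) ** 2) / lum.shape[1]
    return power.mean(axis=0)


def movie_spectrum(frames: Union[FrameSequence, np.ndarray]) -> SpectrumSummary:
    """Mean ± s.e.m. over frames of the row-averaged power spectrum."""
    arr = frames.frames if isinstance(frames, FrameSequence) else np.asarray(frames)
    if arr.ndim != 4 or arr.shape[0] < 1:
        raise ValueError("need at least one RGB frame")
    spectra = np.stack([frame_power_spectrum(to_luminance(f)) for f in arr])
    n = spectra.shape[0]
    mean = spectra.mean(axis=0)
    sem = spectra.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    peak_bin = int(np.argmax(mean[1:]) + 1)
    return SpectrumSummary(
        frequencies=np.arange(mean.size),
        mean_power=mean,
        sem_power=sem,
        n_frames=n,
        peak_power=float(mean[peak_bin]),
        peak_frequency=peak_bin,
    )


def peak_power(summary: SpectrumSummary) -> tuple[float, int]:
    """Maximum of the mean spectrum over non-DC bins, with its bin index."""
    mean = np.asarray(summary.mean_power)
    if mean.size < 3:
        raise ValueError("spectrum too short to have a non-DC peak")
    k = int(np.argmax(mean[1:]) + 1)
    return float(mean[k]), k
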