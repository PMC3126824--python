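import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from optomaze import ScreenGeometry

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_geometry():
    """A 64x32 screen at 2 px/degree: fast to render, wide enough for FFTs."""
    return ScreenGeometry(width_px=64, height_px=32, pixels_per_degree=2.0,
                          frame_rate_hz=60.0)


def circular_shift_px(reference: np.ndarray, shifted: np.ndarray) -> int:
    """Integer horizontal displacement of `shifted` relative to `reference`
    (both 2-D luminance arrays), estimated by circular cross-correlation.
    Positive means rightward."""
    a = reference.mean(axis=0)
    b = shifted.mean(axis=0)
    cc = np.fft.ifft(np.fft.fft(a).conj() * np.fft.fft(b)).real
    s = int(np.argmax(cc))
    return s if s <= a.size // 2 else s - a.size


def circular_centroid(coords: np.ndarray, period: int) -> float:
    """Centroid of pixel coordinates on a wrapped axis of given period."""
    ang = 2 * np.pi * coords / period
    mean_ang = np.angle(np.mean(np.exp(1j * ang)))
    return (mean_ang * period / (2 * np.pi)) % period


def circular_delta(a: float, b: float, period: int) -> float:
    """Signed displacement from a to b on a wrapped axis."""
    d = (b - a) % period
    return d if d <= period / 2 else d - period
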