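"""Parameterized moving visual stimuli for walking-fly psychophysics.

Renders the stimulus families used in automated choice-maze assays —
drifting square-wave gratings, random-dot kinematograms (RDKs), dots
superimposed on a grating in competition, and translating 1/f noise
textures — as deterministic, seedable RGB frame sequences.

Conventions
-----------
* All physical stimulus units are visual degrees; :class:`ScreenGeometry`
  (``pixels_per_degree``) is the single degrees↔pixels conversion point.
* Direction 0° is rightward (+x), counterclockwise positive (90° is up).
* Frames are ``(height, width, 3)`` uint8 arrays, intensities in [0, 255].
* Edges wrap toroidally, so dot density and grating coverage are constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ScreenGeometry",
    "GratingSpec",
    "RDKSpec",
    "CombinedSpec",
    "TextureSpec",
    "FrameSequence",
    "ResolutionError",
    "derive_temporal_frequency",
    "michelson_contrast",
    "render_grating",
    "render_rdk",
    "render_combined",
    "synth_texture",
    "render",
    "DEFAULT_GEOMETRY",
    "STANDARD_GRATING",
    "STANDARD_RDK",
]

RGB = Tuple[int, int, int]


class ResolutionError(ValueError):
    """The requested stimulus cannot be represented at the given geometry."""


def _check_color(name: str, c: Sequence[float]) -> Tuple[int, int, int]:
    c = tuple(int(v) for v in c)
    if len(c) != 3 or any(v < 0 or v > 255 for v in c):
        raise ValueError(f"{name} must be an RGB triple with values in [0, 255], got {c!r}")
    return c


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry and timing.

    ``pixels_per_degree`` converts visual degrees (the unit of every
    stimulus parameter) to pixels; ``frame_rate_hz`` converts per-second
    quantities to per-frame ones.
    """

    width_px: int = 640
    height_px: int = 480
    pixels_per_degree: float = 2.0
    frame_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if not (isinstance(self.width_px, (int, np.integer)) and isinstance(self.height_px, (int, np.integer))):
            raise ValueError("width_px and height_px must be integers")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be strictly positive")
        if self.pixels_per_degree <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("pixels_per_degree and frame_rate_hz must be strictly positive")

    @property
    def width_deg(self) -> float:
        return self.width_px / self.pixels_per_degree

    @property
    def height_deg(self) -> float:
        return self.height_px / self.pixels_per_degree


DEFAULT_GEOMETRY = ScreenGeometry()


@dataclass(frozen=True)
class GratingSpec:
    """A drifting two-color square-wave grating (uniform bars, not a sinusoid).

    ``velocity_dps`` is signed: positive drifts rightward. Temporal frequency
    is not an independent parameter; it is derived as
    ``spatial_frequency_cpd * |velocity_dps|``.
    """

    spatial_frequency_cpd: float = 0.016
    velocity_dps: float = 130.0
    fg_color: RGB = (0, 255, 0)
    bg_color: RGB = (0, 0, 0)
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if self.spatial_frequency_cpd < 0:
            raise ValueError("spatial_frequency_cpd must be >= 0")
        if not math.isfinite(self.velocity_dps):
            raise ValueError("velocity_dps must be finite")
        if not (0.0 <= self.phase0 < 1.0):
            raise ValueError("phase0 must lie in [0, 1) cycles")
        object.__setattr__(self, "fg_color", _check_color("fg_color", self.fg_color))
        object.__setattr__(self, "bg_color", _check_color("bg_color", self.bg_color))

    @property
    def temporal_frequency_hz(self) -> float:
        return derive_temporal_frequency(self.spatial_frequency_cpd, self.velocity_dps)

    @property
    def direction_deg(self) -> float:
        """Motion direction implied by the velocity sign (0 right, 180 left)."""
        return 0.0 if self.velocity_dps >= 0 else 180.0


@dataclass(frozen=True)
class RDKSpec:
    """A random-dot kinematogram.

    A fraction ``coherence`` of the dots (signal dots) translate along
    ``direction_deg``; each remaining noise dot translates along its own
    uniformly random direction, redrawn when the dot is respawned. Dots
    older than ``lifespan_s`` respawn at a uniform random position.
    """

    n_dots: int = 1500
    coherence: float = 1.0
    direction_deg: float = 0.0
    speed_dps: float = 130.0
    dot_diameter_deg: float = 13.8
    lifespan_s: float = 10.0
    dot_color: RGB = (0, 255, 0)
    bg_color: RGB = (0, 0, 0)
    shape: str = "circle"

    def __post_init__(self) -> None:
        if self.n_dots < 0:
            raise ValueError("n_dots must be >= 0")
        if not (0.0 <= self.coherence <= 1.0):
            raise ValueError("coherence must lie in [0, 1]")
        if self.speed_dps < 0:
            raise ValueError("speed_dps must be >= 0")
        if self.dot_diameter_deg <= 0:
            raise ValueError("dot_diameter_deg must be > 0")
        if self.lifespan_s <= 0:
            raise ValueError("lifespan_s must be > 0")
        if self.shape not in ("circle", "square"):
            raise ValueError(f"shape must be 'circle' or 'square', got {self.shape!r}")
        object.__setattr__(self, "dot_color", _check_color("dot_color", self.dot_color))
        object.__setattr__(self, "bg_color", _check_color("bg_color", self.bg_color))


@dataclass(frozen=True)
class CombinedSpec:
    """Coherent dots layered opaquely on a drifting grating (competition).

    The dots' own ``direction_deg`` is ignored; they move along the grating
    direction rotated by ``relative_direction_deg``, which must be one of the
    eight multiples of 45° in [0, 315].
    """

    grating: GratingSpec = field(default_factory=GratingSpec)
    rdk: RDKSpec = field(default_factory=RDKSpec)
    relative_direction_deg: float = 0.0

    def __post_init__(self) -> None:
        allowed = {0, 45, 90, 135, 180, 225, 270, 315}
        if self.relative_direction_deg not in allowed:
            raise ValueError(
                f"relative_direction_deg must be a multiple of 45 in [0, 315], got {self.relative_direction_deg!r}"
            )


@dataclass(frozen=True)
class TextureSpec:
    """A translating random texture with a power-law spatial spectrum.

    The expected log power of the horizontal-frequency spectrum falls
    linearly in log frequency with slope ``-spectral_exponent``; exponent 0
    is white noise, exponent ~2 emulates the low-frequency-heavy spectra of
    natural scenes.
    """

    spectral_exponent: float = 2.0
    velocity_dps: float = 130.0

    def __post_init__(self) -> None:
        if self.spectral_exponent < 0:
            raise ValueError("spectral_exponent must be >= 0")
        if not math.isfinite(self.velocity_dps):
            raise ValueError("velocity_dps must be finite")


STANDARD_GRATING = GratingSpec()
STANDARD_RDK = RDKSpec()


@dataclass(frozen=True)
class FrameSequence:
    """A rendered movie: time-ordered RGB frames plus the geometry used."""

    frames: np.ndarray  # (n_frames, height, width, 3) uint8
    geometry: ScreenGeometry
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 4 or f.shape[-1] != 3:
            raise ValueError("frames must have shape (n, height, width, 3)")
        if f.shape[0] < 1:
            raise ValueError("a FrameSequence needs at least one frame")
        if f.dtype != np.uint8:
            if f.min() < 0 or f.max() > 255:
                raise ValueError("frame intensities must lie in [0, 255]")
            f = f.astype(np.uint8)
        if (f.shape[1], f.shape[2]) != (self.geometry.height_px, self.geometry.width_px):
            raise ValueError("frame dimensions do not match the geometry")
        object.__setattr__(self, "frames", f)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


# ---------------------------------------------------------------------------
# Scalar helpers
# ---------------------------------------------------------------------------

def derive_temporal_frequency(sf_cpd: float, velocity_dps: float) -> float:
    """Temporal frequency (Hz) of a drifting grating: ``sf * |v|``.

    The stimulus engine treats (spatial frequency, velocity) as the primary
    pair and always derives temporal frequency from them.
    """
    if sf_cpd < 0:
        raise ValueError("spatial frequency must be >= 0")
    if not math.isfinite(velocity_dps):
        raise ValueError("velocity must be finite")
    return sf_cpd * abs(velocity_dps)


def michelson_contrast(l_max: float, l_min: float) -> float:
    """Michelson contrast (Lmax − Lmin)/(Lmax + Lmin); 0 for a black field."""
    if l_min < 0:
        raise ValueError("intensities must be >= 0")
    if l_min > l_max:
        raise ValueError("l_min must not exceed l_max")
    if l_max == 0:
        return 0.0
    return (l_max - l_min) / (l_max + l_min)


# ---------------------------------------------------------------------------
# Grating rendering
# ---------------------------------------------------------------------------

def render_grating(spec: GratingSpec, geometry: ScreenGeometry = DEFAULT_GEOMETRY,
                   n_frames: int = 60) -> FrameSequence:
    """Render a drifting square-wave grating.

    Vertical bars drift along x; per-frame phase advance is
    ``velocity_dps * spatial_frequency_cpd / frame_rate_hz`` cycles. Every
    pixel is exactly ``fg_color`` or ``bg_color``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    sf = spec.spatial_frequency_cpd
    if sf > 0:
        period_px = geometry.pixels_per_degree / sf
        if period_px < 2:
            raise ResolutionError(
                f"grating period {period_px:.3f} px is below the 2-px sampling limit"
            )
    x_cycles = (np.arange(geometry.width_px) / geometry.pixels_per_degree) * sf
    dphase = spec.velocity_dps * sf / geometry.frame_rate_hz  # cycles/frame
    fg = np.array(spec.fg_color, dtype=np.uint8)
    bg = np.array(spec.bg_color, dtype=np.uint8)
    frames = np.empty((n_frames, geometry.height_px, geometry.width_px, 3), dtype=np.uint8)
    for t in range(n_frames):
        phase = spec.phase0 + dphase * t
        is_fg = np.mod(x_cycles - phase, 1.0) < 0.5  # (width,)
        row = np.where(is_fg[:, None], fg[None, :], bg[None, :])
        frames[t] = row[None, :, :]
    return FrameSequence(frames=frames, geometry=geometry, seed=None)


# ---------------------------------------------------------------------------
# Dot rasterization: equal-pixel-area circle and square stamps
# ---------------------------------------------------------------------------

def _circle_offsets(diameter_px: int) -> np.ndarray:
    """Pixel offsets (dy, dx) of a filled circle stamp centred on (0, 0)."""
    r = diameter_px / 2.0
    half = (diameter_px - 1) / 2.0
    g = np.arange(diameter_px) - half
    yy, xx = np.meshgrid(g, g, indexing="ij")
    mask = (xx ** 2 + yy ** 2) <= r ** 2 + 1e-9
    dy, dx = np.nonzero(mask)
    return np.stack([dy - diameter_px // 2, dx - diameter_px // 2], axis=1)


def _square_offsets(target_px: int) -> np.ndarray:
    """Square stamp trimmed to exactly ``target_px`` pixels.

    Side length is the nearest integer to sqrt(target), rounded up when the
    square would fall short; excess pixels are trimmed from the corners
    (largest distance from centre first, deterministic tie-break) so circle
    and square stamps of the same nominal diameter cover identical areas.
    """
    side = int(round(math.sqrt(target_px)))
    if side * side < target_px:
        side += 1
    half = (side - 1) / 2.0
    g = np.arange(side) - half
    yy, xx = np.meshgrid(g, g, indexing="ij")
    d2 = (xx ** 2 + yy ** 2).ravel()
    order = np.lexsort((xx.ravel(), yy.ravel(), -d2))  # far corners first
    keep = np.sort(order[side * side - target_px:])
    dy = yy.ravel()[keep] + half - side // 2
    dx = xx.ravel()[keep] + half - side // 2
    return np.stack([dy.astype(int), dx.astype(int)], axis=1)


def _dot_offsets(spec: RDKSpec, geometry: ScreenGeometry) -> np.ndarray:
    diameter_px = int(round(spec.dot_diameter_deg * geometry.pixels_per_degree))
    if diameter_px < 1:
        raise ResolutionError(
            f"dot diameter {spec.dot_diameter_deg}° rasterizes to 0 px at "
            f"{geometry.pixels_per_degree} px/°"
        )
    circle = _circle_offsets(diameter_px)
    if spec.shape == "circle":
        return circle
    return _square_offsets(len(circle))


class _DotField:
    """Internal state of an RDK dot population (positions, headings, ages)."""

    def __init__(self, spec: RDKSpec, geometry: ScreenGeometry, rng: np.random.Generator,
                 direction_deg: Optional[float] = None):
        self.spec = spec
        self.geometry = geometry
        self.rng = rng
        n = spec.n_dots
        direction = spec.direction_deg if direction_deg is None else direction_deg
        self.n_signal = int(round(spec.coherence * n))
        self.pos = np.empty((n, 2))  # columns: x, y in px
        self.pos[:, 0] = rng.uniform(0, geometry.width_px, n)
        self.pos[:, 1] = rng.uniform(0, geometry.height_px, n)
        self.theta = np.empty(n)
        self.theta[: self.n_signal] = math.radians(direction)
        self.theta[self.n_signal:] = rng.uniform(0, 2 * math.pi, n - self.n_signal)
        self.age = rng.uniform(0, spec.lifespan_s, n)

    def step(self) -> None:
        g = self.geometry
        v_px = self.spec.speed_dps * g.pixels_per_degree / g.frame_rate_hz
        self.pos[:, 0] += v_px * np.cos(self.theta)
        self.pos[:, 1] -= v_px * np.sin(self.theta)  # screen y grows downward
        self.pos[:, 0] %= g.width_px
        self.pos[:, 1] %= g.height_px
        self.age += 1.0 / g.frame_rate_hz
        expired = self.age > self.spec.lifespan_s
        n_exp = int(expired.sum())
        if n_exp:
            self.pos[expired, 0] = self.rng.uniform(0, g.width_px, n_exp)
            self.pos[expired, 1] = self.rng.uniform(0, g.height_px, n_exp)
            self.age[expired] = 0.0
            noise_expired = expired.copy()
            noise_expired[: self.n_signal] = False
            k = int(noise_expired.sum())
            if k:
                self.theta[noise_expired] = self.rng.uniform(0, 2 * math.pi, k)

    def paint(self, frame: np.ndarray, offsets: np.ndarray) -> None:
        if self.spec.n_dots == 0:
            return
        g = self.geometry
        cy = np.round(self.pos[:, 1]).astype(int)
        cx = np.round(self.pos[:, 0]).astype(int)
        ys = (cy[:, None] + offsets[None, :, 0]) % g.height_px
        xs = (cx[:, None] + offsets[None, :, 1]) % g.width_px
        frame[ys.ravel(), xs.ravel()] = self.spec.dot_color


def render_rdk(spec: RDKSpec, geometry: ScreenGeometry = DEFAULT_GEOMETRY,
               n_frames: int = 60, seed: int = 0) -> FrameSequence:
    """Render a random-dot kinematogram; identical inputs give identical frames."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    offsets = _dot_offsets(spec, geometry)
    rng = np.random.default_rng(seed)
    dots = _DotField(spec, geometry, rng)
    bg = np.array(spec.bg_color, dtype=np.uint8)
    frames = np.empty((n_frames, geometry.height_px, geometry.width_px, 3), dtype=np.uint8)
    for t in range(n_frames):
        frame = np.broadcast_to(bg, (geometry.height_px, geometry.width_px, 3)).copy()
        dots.paint(frame, offsets)
        frames[t] = frame
        dots.step()
    return FrameSequence(frames=frames, geometry=geometry, seed=seed)


def render_combined(spec: CombinedSpec, geometry: ScreenGeometry = DEFAULT_GEOMETRY,
                    n_frames: int = 60, seed: int = 0) -> FrameSequence:
    """Render dots layered opaquely over a drifting grating.

    Dot motion direction is the grating direction rotated by
    ``relative_direction_deg``; the RDK spec's own direction is ignored.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    grating_seq = render_grating(spec.grating, geometry, n_frames)
    offsets = _dot_offsets(spec.rdk, geometry)
    direction = spec.grating.direction_deg + spec.relative_direction_deg
    rng = np.random.default_rng(seed)
    dots = _DotField(spec.rdk, geometry, rng, direction_deg=direction)
    frames = grating_seq.frames.copy()
    for t in range(n_frames):
        dots.paint(frames[t], offsets)
        dots.step()
    return FrameSequence(frames=frames, geometry=geometry, seed=seed)


# ---------------------------------------------------------------------------
# Synthetic power-law texture
# ---------------------------------------------------------------------------

def synth_texture(geometry: ScreenGeometry = DEFAULT_GEOMETRY, spectral_exponent: float = 2.0,
                  velocity_dps: float = 130.0, n_frames: int = 60, seed: int = 0) -> FrameSequence:
    """Render a rigidly translating random texture with a 1/f^exponent spectrum.

    White noise is filtered along the horizontal frequency axis so the
    expected row power spectrum falls as ``f^-exponent`` (the axis measured
    by the image-regularity metric), the base image is rescaled to [0, 255],
    and each frame is the base image rolled toroidally by the accumulated
    displacement.
    """
    if spectral_exponent < 0:
        raise ValueError("spectral_exponent must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    w, h = geometry.width_px, geometry.height_px
    noise = rng.standard_normal((h, w))
    fx = np.fft.fftfreq(w)
    with np.errstate(divide="ignore"):
        amp = np.abs(fx) ** (-spectral_exponent / 2.0)
    amp[0] = 0.0  # remove per-row DC; the global mean is set by the rescale
    base = np.fft.ifft(np.fft.fft(noise, axis=1) * amp[None, :], axis=1).real
    lo, hi = base.min(), base.max()
    if hi > lo:
        base = (base - lo) / (hi - lo) * 255.0
    else:
        base = np.full_like(base, 127.5)
    base = np.round(base).astype(np.uint8)
    img = np.repeat(base[:, :, None], 3, axis=2)

    v_px = velocity_dps * geometry.pixels_per_degree / geometry.frame_rate_hz
    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    for t in range(n_frames):
        frames[t] = np.roll(img, int(round(v_px * t)), axis=1)
    return FrameSequence(frames=frames, geometry=geometry, seed=seed)


# ---------------------------------------------------------------------------
# Dispatch and (de)serialization of specs
# ---------------------------------------------------------------------------

_SPEC_KINDS = {
    "grating": GratingSpec,
    "rdk": RDKSpec,
    "combined": CombinedSpec,
    "texture": TextureSpec,
}


def spec_to_dict(spec) -> dict:
    """Serialize any stimulus spec to a plain dict with a ``kind`` tag."""
    for kind, cls in _SPEC_KINDS.items():
        if isinstance(spec, cls):
            d = asdict(spec)
            d["kind"] = kind
            return d
    raise TypeError(f"not a stimulus spec: {type(spec).__name__}")


def spec_from_dict(d: dict):
    """Inverse of :func:`spec_to_dict`."""
    d = dict(d)
    kind = d.pop("kind", None)
    if kind not in _SPEC_KINDS:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    if kind == "combined":
        return CombinedSpec(
            grating=GratingSpec(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in d.pop("grating").items()}),
            rdk=RDKSpec(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in d.pop("rdk").items()}),
            **d,
        )
    d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return _SPEC_KINDS[kind](**d)


def render(spec, geometry: ScreenGeometry = DEFAULT_GEOMETRY, n_frames: int = 60,
           seed: int = 0) -> FrameSequence:
    """Render any stimulus spec (dispatch on its type)."""
    if isinstance(spec, GratingSpec):
        return render_grating(spec, geometry, n_frames)
    if isinstance(spec, RDKSpec):
        return render_rdk(spec, geometry, n_frames, seed)
    if isinstance(spec, CombinedSpec):
        return render_combined(spec, geometry, n_frames, seed)
    if isinstance(spec, TextureSpec):
        return synth_texture(geometry, spec.spectral_exponent, spec.velocity_dps,
                             n_frames, seed)
    raise TypeError(f"cannot render object of type {type(spec).__name__}")
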