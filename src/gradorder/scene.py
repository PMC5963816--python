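"""Synthetic scene generation: band-pass bumpy height fields, bumpy-sphere
normal maps, and point-light configurations.

Coordinate conventions
----------------------
Pixels are 0-based, row-major.  The x axis increases rightward (with the
column index) and the y axis increases upward (against the row index), so a
gradient direction of 0 rad points right and pi/2 rad points up.  The camera
is orthographic at +z; the viewing direction is (0, 0, 1), and illumination
slant 0 means the light shines along the viewing direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "HeightField",
    "NormalField",
    "LightConfig",
    "light_direction",
    "make_bandpass_heightfield",
    "heightfield_to_normals",
    "make_bumpy_sphere_normals",
]


@dataclass(frozen=True)
class HeightField:
    """A rectangular grid of surface elevations.

    Parameters
    ----------
    elevations : ndarray, shape (H, W)
        Depth modulation in world units (arbitrary depth scale).
    pitch : float
        World units per pixel (> 0); sets the slope scale of the normals.
    """

    elevations: np.ndarray
    pitch: float = 1.0

    def __post_init__(self):
        z = np.asarray(self.elevations, dtype=float)
        if z.ndim != 2:
            raise InvalidParameterError("elevations must be a 2-D grid")
        if not np.all(np.isfinite(z)):
            raise InvalidParameterError("elevations must be finite")
        if not self.pitch > 0:
            raise InvalidParameterError("pitch must be > 0")
        object.__setattr__(self, "elevations", z)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape


@dataclass(frozen=True)
class NormalField:
    """Per-pixel unit surface normals with an inside-silhouette mask.

    Every masked-in normal has unit length (to 1e-9) and a non-negative
    z component (front-facing under the orthographic +z camera).
    """

    normals: np.ndarray  # (H, W, 3)
    mask: np.ndarray  # (H, W) bool

    def __post_init__(self):
        n = np.asarray(self.normals, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if n.ndim != 3 or n.shape[2] != 3:
            raise InvalidParameterError("normals must have shape (H, W, 3)")
        if m.shape != n.shape[:2]:
            raise InvalidParameterError("mask shape must match normals")
        if m.any():
            norms = np.linalg.norm(n[m], axis=-1)
            if np.max(np.abs(norms - 1.0)) > 1e-9:
                raise InvalidParameterError("masked-in normals must be unit length")
            if np.min(n[m][:, 2]) < 0:
                raise InvalidParameterError("masked-in normals must be front-facing")
        object.__setattr__(self, "normals", n)
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class LightConfig:
    """A distant point light given by slant/tilt relative to the view axis.

    slant_deg in [0, 90): angle from the viewing direction; slant 0 puts the
    light along the line of sight.  tilt_deg in [0, 360): azimuth in the
    image plane.  intensity is the light term l of the shading equations.
    """

    slant_deg: float = 0.0
    tilt_deg: float = 0.0
    intensity: float = math.pi

    def __post_init__(self):
        if not (0.0 <= self.slant_deg < 90.0):
            raise InvalidParameterError("slant_deg must lie in [0, 90)")
        if not (0.0 <= self.tilt_deg < 360.0):
            raise InvalidParameterError("tilt_deg must lie in [0, 360)")
        if not self.intensity > 0:
            raise InvalidParameterError("intensity must be > 0")

    @property
    def direction(self) -> np.ndarray:
        return light_direction(self)


def light_direction(light: LightConfig) -> np.ndarray:
    """Unit direction toward the light: (sin s cos t, sin s sin t, cos s)."""
    s = math.radians(light.slant_deg)
    t = math.radians(light.tilt_deg)
    return np.array([math.sin(s) * math.cos(t), math.sin(s) * math.sin(t), math.cos(s)])


def _bandpass_noise(size: int, center_freq: float, rel_bandwidth: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise with an annular Gaussian spectrum.

    The amplitude spectrum is exp(-(f - f0)^2 / (2 sigma^2)) with
    sigma = f0 * rel_bandwidth / 3, which keeps well over 80% of the power
    inside [f0/(1+b), f0*(1+b)].
    """
    white = rng.standard_normal((size, size))
    f = np.fft.fftfreq(size, d=1.0 / size)  # cycles per image
    radius = np.hypot(*np.meshgrid(f, f, indexing="ij"))
    sigma = center_freq * rel_bandwidth / 3.0
    filt = np.exp(-((radius - center_freq) ** 2) / (2.0 * sigma**2))
    filt[0, 0] = 0.0  # zero mean
    z = np.fft.ifft2(np.fft.fft2(white) * filt).real
    z -= z.mean()
    rms = np.sqrt(np.mean(z**2))
    if rms > 0:
        z /= rms
    return z


def make_bandpass_heightfield(size: int, center_freq: float = 8.0,
                              rel_bandwidth: float = 0.5, amplitude: float = 4.0,
                              seed: int = 0) -> HeightField:
    """Surface modulated in depth by Gaussian band-pass noise.

    Parameters
    ----------
    size : int
        Grid side length (>= 8).
    center_freq : float
        Spectral peak in cycles per image (> 0).
    rel_bandwidth : float
        Relative half-width b of the pass band [f0/(1+b), f0*(1+b)].
    amplitude : float
        RMS elevation in world units; 0 yields an exactly flat field.
    seed : int
        Seed; the generator is a pure function of its arguments.
    """
    if size < 8:
        raise InvalidParameterError("size must be >= 8")
    if center_freq <= 0:
        raise InvalidParameterError("center_freq must be > 0")
    if rel_bandwidth <= 0:
        raise InvalidParameterError("rel_bandwidth must be > 0")
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    z = _bandpass_noise(size, center_freq, rel_bandwidth, rng) * amplitude
    return HeightField(z, pitch=1.0)


def heightfield_to_normals(hf: HeightField) -> NormalField:
    """Surface normals of a height field: normalize(-dz/dx, -dz/dy, 1).

    The y axis points up, so dz/dy = -(dz/drow).  The mask is all-true
    (the field fills the frame; there is no silhouette).
    """
    dz_drow, dz_dcol = np.gradient(hf.elevations, hf.pitch)
    dzdx = dz_dcol
    dzdy = -dz_drow
    n = np.stack([-dzdx, -dzdy, np.ones_like(dzdx)], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return NormalField(n, np.ones(hf.shape, dtype=bool))


def make_bumpy_sphere_normals(size: int, bump_freq: float = 8.0,
                              bump_amplitude: float = 0.3,
                              seed: int = 0) -> NormalField:
    """Normals of a hemisphere perturbed by Gaussian band-pass noise.

    The hemisphere fills the inscribed disc; pixels at or beyond the disc
    radius are masked out.  Each normal's in-plane components are modulated
    by two independent band-pass noise fields of RMS ``bump_amplitude`` and
    the result is renormalized, so the z component stays non-negative.
    """
    if size < 8:
        raise InvalidParameterError("size must be >= 8")
    if bump_amplitude < 0:
        raise InvalidParameterError("bump_amplitude must be >= 0")
    half = size / 2.0
    cols = (np.arange(size) + 0.5 - half) / half
    rows = (half - np.arange(size) - 0.5) / half  # y up
    u, v = np.meshgrid(cols, rows, indexing="xy")
    r2 = u**2 + v**2
    mask = r2 < 1.0
    nz = np.sqrt(np.clip(1.0 - r2, 0.0, None))
    n = np.stack([u, v, nz], axis=-1)
    if bump_amplitude > 0:
        rng = np.random.default_rng(seed)
        du = _bandpass_noise(size, bump_freq, 0.5, rng) * bump_amplitude
        dv = _bandpass_noise(size, bump_freq, 0.5, rng) * bump_amplitude
        n[..., 0] += du
        n[..., 1] += dv
    n[~mask] = (0.0, 0.0, 1.0)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return NormalField(n, mask)
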