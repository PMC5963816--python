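"""Local shading under point lights: Lambertian, Ward, and asperity
(velvet-like) reflectance, diffuse/specular splitting, and derived stimuli
(inconsistent highlights, global intensity reversal).

All renderers are local: radiance at a pixel depends only on the surface
normal, the light direction and the material — no cast shadows, no
interreflection, no environment lighting.  Back-facing cosines clamp to 0,
which paints attached shadows black (there is no ambient term).

Each renderer returns an :class:`IntensityImage` whose values are the
radiances divided by their masked maximum (``white_point``), so raw
radiances round-trip via :meth:`IntensityImage.radiance`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .exceptions import InvalidParameterError
from .scene import LightConfig, NormalField

__all__ = [
    "MaterialParams",
    "IntensityImage",
    "RenderComponents",
    "render_lambert",
    "render_ward",
    "render_asperity",
    "render_material",
    "asperity_from_lambert",
    "compose_inconsistent_highlights",
    "reverse_intensity",
]

_VIEW = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class MaterialParams:
    """Parameters of one reflectance model.

    model one of {"lambertian", "ward", "asperity"}.  rho_d is the diffuse
    reflectance; rho_s and alpha are the Ward specular energy and lobe
    spread; a is the asperity edge-brightening factor; l_l / l_a are the
    light intensities paired with the Lambertian / asperity terms.
    """

    model: str
    rho_d: float = 0.0
    rho_s: float = 0.0
    alpha: float = 0.0
    a: float = 0.0
    l_l: float = math.pi
    l_a: float = math.pi
    name: str = ""

    def __post_init__(self):
        if self.model not in ("lambertian", "ward", "asperity"):
            raise InvalidParameterError(f"unknown model {self.model!r}")
        if self.model in ("lambertian", "ward") and self.rho_d < 0:
            raise InvalidParameterError("rho_d must be >= 0")
        if self.model == "ward":
            if self.rho_s < 0:
                raise InvalidParameterError("rho_s must be >= 0")
            if self.alpha <= 0:
                raise InvalidParameterError("alpha must be > 0")
        if self.model == "asperity" and self.a <= 0:
            raise InvalidParameterError("a must be > 0")
        if not self.name:
            object.__setattr__(self, "name", self._default_name())

    def _default_name(self) -> str:
        if self.model == "lambertian":
            return f"lambert(rho_d={self.rho_d:g})"
        if self.model == "ward":
            return f"ward(rho_s={self.rho_s:g},alpha={self.alpha:g})"
        return f"asperity(a={self.a:g})"

    @classmethod
    def lambertian(cls, rho_d: float = 0.6, l_l: float = math.pi) -> "MaterialParams":
        return cls(model="lambertian", rho_d=rho_d, l_l=l_l)

    @classmethod
    def ward(cls, rho_d: float = 0.5, rho_s: float = 0.25,
             alpha: float = 0.25) -> "MaterialParams":
        return cls(model="ward", rho_d=rho_d, rho_s=rho_s, alpha=alpha)

    @classmethod
    def asperity(cls, a: float = 0.2, l_a: float = math.pi) -> "MaterialParams":
        return cls(model="asperity", a=a, l_a=l_a)


@dataclass(frozen=True)
class IntensityImage:
    """H x W intensities in [0, 1] with a validity mask.

    ``white_point`` is the pre-normalization radiance maximum, so
    ``values * white_point`` recovers raw radiances.
    """

    values: np.ndarray
    mask: np.ndarray
    white_point: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if v.ndim != 2 or m.shape != v.shape:
            raise InvalidParameterError("values must be 2-D with matching mask")
        if m.any():
            inside = v[m]
            if not np.all(np.isfinite(inside)):
                raise InvalidParameterError("masked-in values must be finite")
            if inside.min() < -1e-12 or inside.max() > 1.0 + 1e-12:
                raise InvalidParameterError("masked-in values must lie in [0, 1]")
        if not self.white_point > 0:
            raise InvalidParameterError("white_point must be > 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)

    @classmethod
    def from_radiance(cls, radiance: np.ndarray, mask: np.ndarray) -> "IntensityImage":
        """Normalize a radiance map by its masked maximum."""
        radiance = np.asarray(radiance, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        wp = float(radiance[mask].max()) if mask.any() else 0.0
        if wp <= 0:
            wp = 1.0
        out = np.where(mask, radiance / wp, 0.0)
        return cls(np.clip(out, 0.0, 1.0), mask, white_point=wp)

    def radiance(self) -> np.ndarray:
        return self.values * self.white_point

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RenderComponents:
    """Diffuse/specular/combined split of one render.

    All three images share the combined image's white point, so
    diffuse.values + specular.values == combined.values over the mask.
    """

    diffuse: IntensityImage
    specular: IntensityImage
    combined: IntensityImage


def _cosines(normals: NormalField, light: LightConfig):
    """Clamped incidence and exitance cosines; back-facing pixels -> 0."""
    cos_i = np.clip(normals.normals @ light.direction, 0.0, None)
    cos_o = np.clip(normals.normals[..., 2], 0.0, None)
    return cos_i, cos_o


def render_lambert(normals: NormalField, light: LightConfig,
                   rho_d: float = 0.6, l_l: float | None = None) -> IntensityImage:
    """Lambertian radiance (rho_d / pi) * l * max(I.N, 0).

    l_l defaults to the light's own intensity.
    """
    if rho_d < 0:
        raise InvalidParameterError("rho_d must be >= 0")
    l = light.intensity if l_l is None else l_l
    cos_i, _ = _cosines(normals, light)
    radiance = (rho_d / math.pi) * l * cos_i
    radiance[~normals.mask] = 0.0
    return IntensityImage.from_radiance(radiance, normals.mask)


def render_ward(normals: NormalField, light: LightConfig,
                rho_d: float = 0.5, rho_s: float = 0.25, alpha: float = 0.25,
                denominator: str = "sqrt") -> RenderComponents:
    """Ward reflectance: diffuse lobe plus a Gaussian rough-specular lobe.

    The specular BRDF is rho_s * exp(-tan^2(d)/alpha^2) / (4 pi alpha^2 D)
    where d is the angle between the normal and the half vector of the
    light and view directions.  ``denominator`` selects the energy term D:
    "sqrt" (standard) uses sqrt(cos_i * cos_o); "printed" uses cos_i * cos_o.
    Pixels with non-positive incidence or exitance cosine get zero in both
    terms (no division by zero).
    """
    if denominator not in ("sqrt", "printed"):
        raise InvalidParameterError("denominator must be 'sqrt' or 'printed'")
    if alpha <= 0:
        raise InvalidParameterError("alpha must be > 0")
    l = light.intensity
    cos_i, cos_o = _cosines(normals, light)
    lit = (cos_i > 0) & (cos_o > 0) & normals.mask

    diffuse = (rho_d / math.pi) * l * cos_i
    diffuse = np.where(lit, diffuse, 0.0)

    half = light.direction + _VIEW
    half /= np.linalg.norm(half)
    cos_d = np.clip(normals.normals @ half, 1e-12, 1.0)
    tan2 = (1.0 - cos_d**2) / cos_d**2
    denom = np.sqrt(cos_i * cos_o) if denominator == "sqrt" else cos_i * cos_o
    spec = np.zeros_like(diffuse)
    np.divide(rho_s * np.exp(-tan2 / alpha**2) / (4.0 * math.pi * alpha**2),
              denom, out=spec, where=lit)
    spec = np.where(lit, spec * l * cos_i, 0.0)

    combined = IntensityImage.from_radiance(diffuse + spec, normals.mask)
    wp = combined.white_point
    diffuse_img = IntensityImage(np.clip(diffuse / wp, 0.0, 1.0), normals.mask, wp)
    spec_img = IntensityImage(np.clip(spec / wp, 0.0, 1.0), normals.mask, wp)
    return RenderComponents(diffuse_img, spec_img, combined)


def render_asperity(normals: NormalField, light: LightConfig,
                    a: float = 0.2, l_a: float | None = None) -> IntensityImage:
    """Asperity scattering: La = (a/pi) * la * (I.N) / (a + (I.N)(J.N)).

    Produces the velvet-like edge brightening: under frontal light La peaks
    at cos(theta) = sqrt(a) and falls toward the pole.
    """
    if a <= 0:
        raise InvalidParameterError("a must be > 0")
    l = light.intensity if l_a is None else l_a
    cos_i, cos_o = _cosines(normals, light)
    radiance = (a / math.pi) * l * cos_i / (a + cos_i * cos_o)
    radiance[~normals.mask] = 0.0
    return IntensityImage.from_radiance(radiance, normals.mask)


def render_material(material: MaterialParams, normals: NormalField,
                    light: LightConfig) -> IntensityImage:
    """Dispatch a material to its renderer; Ward returns the combined image."""
    if material.model == "lambertian":
        return render_lambert(normals, light, rho_d=material.rho_d, l_l=material.l_l)
    if material.model == "ward":
        return render_ward(normals, light, rho_d=material.rho_d,
                           rho_s=material.rho_s, alpha=material.alpha).combined
    return render_asperity(normals, light, a=material.a, l_a=material.l_a)


def asperity_from_lambert(L_l, a: float, l_a: float, rho_d: float, l_l: float):
    """The Lambertian-to-asperity intensity remapping (frontal light).

    La = a*la*Ll / (a*rho_d*ll + pi^2 * Ll^2 / (rho_d*ll)).  Valid for
    Lambertian radiances Ll in [0, rho_d*ll/pi]; rises to a peak at
    Ll = sqrt(a)*rho_d*ll/pi, then falls, so the intensity order is reversed
    on the top fraction 1 - sqrt(a) of the Lambertian range.
    """
    L = np.asarray(L_l, dtype=float)
    lmax = rho_d * l_l / math.pi
    if np.any(L < -1e-12) or np.any(L > lmax + 1e-12):
        raise InvalidParameterError(f"L_l must lie in [0, {lmax:g}]")
    out = a * l_a * L / (a * rho_d * l_l + math.pi**2 * L**2 / (rho_d * l_l))
    return out if out.ndim else float(out)


def compose_inconsistent_highlights(components: RenderComponents,
                                    rotation_deg: float = 90.0,
                                    shift_px: tuple[int, int] = (0, 0),
                                    interpolation: str = "nearest") -> IntensityImage:
    """Recombine the diffuse pattern with a rotated/displaced specular pattern.

    The specular radiance map is rotated about the image center, then shifted
    by ``shift_px`` = (dx, dy) pixels (x right, y up); pixels moved out of
    frame drop to zero.  The diffuse component and its mask are untouched.
    Nearest-neighbor resampling is the default so that a 180-degree rotation
    is an exact involution; "bilinear" is available.
    """
    if interpolation not in ("nearest", "bilinear"):
        raise InvalidParameterError("interpolation must be 'nearest' or 'bilinear'")
    order = 0 if interpolation == "nearest" else 1
    spec = transform_specular(components.specular.radiance(), rotation_deg,
                              shift_px, order)
    combined = components.diffuse.radiance() + spec
    return IntensityImage.from_radiance(combined, components.diffuse.mask)


def transform_specular(spec_radiance: np.ndarray, rotation_deg: float,
                       shift_px: tuple[int, int], order: int = 0) -> np.ndarray:
    """Rotate about the image center, then shift; out-of-frame pixels -> 0."""
    out = ndimage.rotate(spec_radiance, rotation_deg, reshape=False,
                         order=order, mode="constant", cval=0.0, prefilter=False)
    dx, dy = shift_px
    # y up: a positive dy moves content toward smaller row indices
    out = ndimage.shift(out, (-dy, dx), order=order, mode="constant",
                        cval=0.0, prefilter=False)
    return out


def reverse_intensity(img: IntensityImage) -> IntensityImage:
    """Reverse the intensity order: within the mask, v -> (max + min - v)."""
    if not img.mask.any():
        raise InvalidParameterError("cannot reverse an empty image")
    inside = img.values[img.mask]
    hi, lo = inside.max(), inside.min()
    out = np.where(img.mask, hi + lo - img.values, img.values)
    return IntensityImage(out, img.mask, img.white_point)
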