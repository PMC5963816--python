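"""Intensity-gradient fields and the material-correlation analysis.

The gradient is computed with a separable 5-tap matched prefilter /
derivative pair (Farid & Simoncelli optimal filters), whose rotation
equivariance keeps the direction estimate faithful on oriented structure.
Each per-pixel derivative vector is split into a magnitude map and a signed
direction map (radians, 0 = rightward, pi/2 = up).  Direction is kept modulo
2*pi; an "orientation" (modulo pi) reading is available for comparison.

Pairwise analysis: render a family of materials on shared geometries under a
shared light, compute gradient fields, pool valid pixels across geometries,
and correlate — circular correlation for the direction maps, Pearson for the
magnitude maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .exceptions import InvalidParameterError, UndefinedStatisticError
from .scene import LightConfig, NormalField
from .shading import IntensityImage, MaterialParams, render_material

__all__ = [
    "PREFILTER_5",
    "DERIVATIVE_5",
    "GradientField",
    "CorrelationRecord",
    "gradient_field",
    "mask_small_gradients",
    "circular_correlation",
    "direction_agreement",
    "pairwise_material_correlations",
    "cross_light_correlation",
    "correlation_density",
]

log = logging.getLogger(__name__)

# Farid & Simoncelli 5-tap interpolator/derivative pair; frozen so results
# are bit-stable across versions.
PREFILTER_5 = np.array([0.037659, 0.249153, 0.426375, 0.249153, 0.037659])
DERIVATIVE_5 = np.array([-0.109604, -0.276691, 0.0, 0.276691, 0.109604])


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient magnitude (>= 0) and direction (radians, (-pi, pi]).

    The mask marks pixels whose 5x5 support lies inside the silhouette (and
    inside the frame when border exclusion is on), optionally restricted to
    magnitudes above a threshold by :func:`mask_small_gradients`.
    """

    magnitude: np.ndarray
    direction: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        mag = np.asarray(self.magnitude, dtype=float)
        if not np.all(np.isfinite(mag)) or mag.min() < 0:
            raise InvalidParameterError("magnitude must be finite and >= 0")
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    def orientation(self) -> np.ndarray:
        """Unsigned orientation map: direction modulo pi, in [0, pi)."""
        return np.mod(self.direction, np.pi)


@dataclass(frozen=True)
class CorrelationRecord:
    """One material pair: circular direction correlation, Pearson magnitude
    correlation, and the pooled valid-pixel count."""

    id_a: str
    id_b: str
    dir_corr: float
    mag_corr: float
    n_pixels: int


def gradient_field(img: IntensityImage, exclude_border: bool = True) -> GradientField:
    """Gradient magnitude and signed direction of an intensity image.

    Horizontal/vertical derivatives come from the separable 5-tap pair;
    direction = atan2(gy, gx) with y up.  The validity mask shrinks the
    image mask by the 2-pixel kernel radius so no silhouette-crossing (or,
    with ``exclude_border``, frame-crossing) support enters the statistics.
    """
    v = img.values
    if min(v.shape) < 5:
        raise InvalidParameterError("image must be at least 5x5")
    gx = ndimage.correlate1d(
        ndimage.correlate1d(v, PREFILTER_5, axis=0, mode="reflect"),
        DERIVATIVE_5, axis=1, mode="reflect")
    gy = -ndimage.correlate1d(
        ndimage.correlate1d(v, DERIVATIVE_5, axis=0, mode="reflect"),
        PREFILTER_5, axis=1, mode="reflect")
    magnitude = np.hypot(gx, gy)
    direction = np.arctan2(gy, gx)
    direction[direction <= -np.pi] = np.pi
    border_value = 0 if exclude_border else 1
    mask = ndimage.binary_erosion(img.mask, structure=np.ones((5, 5), dtype=bool),
                                  border_value=border_value)
    return GradientField(magnitude, direction, mask)


def mask_small_gradients(gf: GradientField, threshold: float = 0.0002) -> GradientField:
    """Exclude pixels whose gradient magnitude falls below the threshold."""
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    return GradientField(gf.magnitude, gf.direction,
                         gf.mask & (gf.magnitude >= threshold))


def circular_correlation(alpha, beta, method: str = "mean") -> float:
    """Sample circular correlation of two paired angle series.

    ``method="mean"`` (Jammalamadaka–SenGupta):
    sum sin(a - abar) sin(b - bbar) / sqrt(sum sin^2(a - abar) *
    sum sin^2(b - bbar)) with circular means abar, bbar.

    ``method="pairwise"`` (Fisher–Lee): the same construction applied to all
    pairwise angle differences, evaluated in closed form.  Both are
    invariant to adding a constant angle to either series; the mean-based
    form is undefined-in-practice when a series is nearly uniform on the
    circle (its circular mean is then determined by noise), which is
    exactly the situation for gradient-direction maps of isotropic bumpy
    surfaces — the pairwise form is the stable choice there.
    """
    a = np.asarray(alpha, dtype=float).ravel()
    b = np.asarray(beta, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise InvalidParameterError("need two equal-length series of >= 3 angles")
    if method == "mean":
        abar = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
        bbar = np.arctan2(np.sin(b).mean(), np.cos(b).mean())
        sa = np.sin(a - abar)
        sb = np.sin(b - bbar)
        denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
        if denom == 0:
            raise UndefinedStatisticError("zero circular variance")
        return float(np.sum(sa * sb) / denom)
    if method == "pairwise":
        n = a.size
        ca, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        A = np.sum(ca * cb)
        B = np.sum(sa * sb)
        C = np.sum(ca * sb)
        D = np.sum(sa * cb)
        E = np.sum(np.cos(2 * a))
        F = np.sum(np.sin(2 * a))
        G = np.sum(np.cos(2 * b))
        H = np.sum(np.sin(2 * b))
        denom2 = (n**2 - E**2 - F**2) * (n**2 - G**2 - H**2)
        if denom2 <= 0:
            raise UndefinedStatisticError("zero circular variance")
        return float(4.0 * (A * B - C * D) / np.sqrt(denom2))
    raise InvalidParameterError("method must be 'mean' or 'pairwise'")


def direction_agreement(alpha, beta) -> float:
    """Mean cosine of the paired direction differences, in [-1, 1].

    1 when the directions agree everywhere, -1 when every direction is
    flipped by pi.  Unlike a circular correlation (which is invariant to a
    constant rotation, so an exact whole-map flip scores +1), this statistic
    detects the order-reversal flips produced by asperity scattering.
    """
    a = np.asarray(alpha, dtype=float).ravel()
    b = np.asarray(beta, dtype=float).ravel()
    if a.size != b.size or a.size == 0:
        raise InvalidParameterError("need two equal-length nonempty series")
    return float(np.mean(np.cos(a - b)))


def _material_fields(material, geometries, light, threshold, exclude_border):
    fields = []
    for geom in geometries:
        gf = gradient_field(render_material(material, geom, light),
                            exclude_border=exclude_border)
        if threshold is not None and threshold > 0:
            gf = mask_small_gradients(gf, threshold)
        fields.append(gf)
    return fields


def _correlate_fields(fields_a, fields_b, id_a, id_b, dir_method="pairwise"):
    dirs_a, dirs_b, mags_a, mags_b = [], [], [], []
    for fa, fb in zip(fields_a, fields_b):
        valid = fa.mask & fb.mask
        dirs_a.append(fa.direction[valid])
        dirs_b.append(fb.direction[valid])
        mags_a.append(fa.magnitude[valid])
        mags_b.append(fb.magnitude[valid])
    da = np.concatenate(dirs_a)
    db = np.concatenate(dirs_b)
    ma = np.concatenate(mags_a)
    mb = np.concatenate(mags_b)
    if da.size == 0:
        log.warning("empty pooled mask for pair (%s, %s); record skipped", id_a, id_b)
        return None
    if id_a == id_b:
        dir_corr = mag_corr = 1.0
    else:
        dir_corr = circular_correlation(da, db, method=dir_method)
        mag_corr = float(stats.pearsonr(ma, mb).statistic)
    return CorrelationRecord(id_a, id_b, dir_corr, mag_corr, int(da.size))


def pairwise_material_correlations(materials, geometries, light: LightConfig,
                                   threshold: float | None = 0.0002,
                                   exclude_border: bool = True,
                                   include_self: bool | None = None,
                                   dir_method: str = "pairwise"):
    """Correlate gradient maps between all material pairs on shared geometry.

    Each material is rendered on every geometry under the shared light; the
    per-geometry validity masks of the pair are intersected and the valid
    pixels pooled across geometries before correlating.  ``threshold=None``
    disables the small-gradient exclusion.  Self-pairs are included when
    ``include_self`` is True (default: only for a single-material family).
    ``dir_method`` selects the circular-correlation estimator; the pairwise
    (Fisher–Lee) form is the default because pooled direction maps are
    near-uniform on the circle (see :func:`circular_correlation`).

    Returns a list of :class:`CorrelationRecord`.
    """
    materials = list(materials)
    if include_self is None:
        include_self = len(materials) == 1
    fields = [_material_fields(m, geometries, light, threshold, exclude_border)
              for m in materials]
    records = []
    for i, mat_a in enumerate(materials):
        j0 = i if include_self else i + 1
        for j in range(j0, len(materials)):
            rec = _correlate_fields(fields[i], fields[j],
                                    mat_a.name, materials[j].name, dir_method)
            if rec is not None:
                records.append(rec)
    return records


def cross_light_correlation(material: MaterialParams, geometries,
                            light_a: LightConfig, light_b: LightConfig,
                            threshold: float | None = 0.0002,
                            exclude_border: bool = True,
                            dir_method: str = "pairwise") -> CorrelationRecord:
    """Correlate one material's gradient maps across two illuminations."""
    fa = _material_fields(material, geometries, light_a, threshold, exclude_border)
    fb = _material_fields(material, geometries, light_b, threshold, exclude_border)
    id_a = f"{material.name}@slant{light_a.slant_deg:g}"
    id_b = f"{material.name}@slant{light_b.slant_deg:g}"
    rec = _correlate_fields(fa, fb, id_a, id_b, dir_method)
    if rec is None:
        raise UndefinedStatisticError("empty pooled mask across illuminations")
    return rec


def correlation_density(records, n_bins: int = 40) -> pd.DataFrame:
    """Normalized histograms of the direction and magnitude correlations.

    Densities integrate to 1 over the bin width on [-1, 1].
    """
    records = list(records)
    if not records:
        raise InvalidParameterError("need at least one record")
    if n_bins < 1:
        raise InvalidParameterError("n_bins must be >= 1")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    dir_density, _ = np.histogram([r.dir_corr for r in records], bins=edges, density=True)
    mag_density, _ = np.histogram([r.mag_corr for r in records], bins=edges, density=True)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "dir_density": dir_density,
        "mag_density": mag_density,
    })
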