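"""Intensity remappings and order diagnostics.

Three families of tone curve are provided:

* rank-based histogram matching to an arbitrary reference sample, with a
  Beta-distribution reference generator for skewness control;
* the compressive map 1 - [(1 - x)^r + (1 - c)^r]^(1/r), a smooth minimum of
  x and the cut-off c that dims highlights without reordering the rest of
  the range;
* the linear-plus-sinusoid map s1*(x - m) + s2*sin(omega*(x - m) + phi) + m,
  which is order-preserving iff s1 >= |s2|*omega.

Diagnostics: analytic monotonicity classification, sample skewness, and a
rank-correlation order-preservation index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .exceptions import InvalidParameterError, StructureMismatchError, UndefinedStatisticError
from .shading import IntensityImage

__all__ = [
    "CompressiveCurve",
    "SinusoidCurve",
    "TableCurve",
    "BetaRef",
    "histogram_match",
    "beta_reference",
    "beta_skewness",
    "compressive_tonemap",
    "auto_cutoff",
    "sinusoid_remap",
    "is_monotone",
    "sample_skewness",
    "order_preservation_index",
    "apply_tone_curve",
]

DEFAULT_OMEGA = 2.857 * math.pi
DEFAULT_PHI = math.pi


@dataclass(frozen=True)
class CompressiveCurve:
    """Compressive tone map with cut-off c in (0, 1] and smoothing r > 0.

    ``as_printed`` evaluates the literal decreasing form
    [(1 - x)^r + (1 - c)^r]^(1/r) (kept for comparison); the default adds
    the leading "1 -" so the curve is nondecreasing and saturates at c.
    """

    c: float
    r: float = 30.0
    as_printed: bool = False
    kind: str = "compressive"

    def __post_init__(self):
        if not (0.0 < self.c <= 1.0):
            raise InvalidParameterError("c must lie in (0, 1]")
        if not self.r > 0:
            raise InvalidParameterError("r must be > 0")

    def __call__(self, x):
        return compressive_tonemap(x, self.c, self.r, as_printed=self.as_printed)


@dataclass(frozen=True)
class SinusoidCurve:
    """Linear tone curve of slope s1 with a sinusoidal modulation s2.

    f(x) = s1*(x - m) + s2*sin(omega*(x - m) + phi) + m, clipped to [0, 1].
    m is the mean intensity; omega is the angular velocity of the modulation
    (rad per unit intensity) and phi its phase.  f(m) = m when phi = pi.
    """

    m: float = 0.5
    s1: float = 1.0
    s2: float = 0.0
    omega: float = DEFAULT_OMEGA
    phi: float = DEFAULT_PHI
    kind: str = "sinusoid"

    def __call__(self, x):
        return sinusoid_remap(x, self)


@dataclass(frozen=True)
class TableCurve:
    """Piecewise-linear curve through sorted (input, output) pairs."""

    inputs: np.ndarray
    outputs: np.ndarray
    kind: str = "table"

    def __post_init__(self):
        xi = np.asarray(self.inputs, dtype=float)
        yi = np.asarray(self.outputs, dtype=float)
        if xi.ndim != 1 or xi.shape != yi.shape or xi.size < 2:
            raise InvalidParameterError("need matching 1-D input/output tables")
        if np.any(np.diff(xi) <= 0):
            raise InvalidParameterError("table inputs must be strictly increasing")
        object.__setattr__(self, "inputs", xi)
        object.__setattr__(self, "outputs", yi)

    def __call__(self, x):
        return np.interp(x, self.inputs, self.outputs)


@dataclass(frozen=True)
class BetaRef:
    """Beta(p, q) reference with q = 10 - p, rescaled to a target mean/SD.

    p in (0, 10) modulates skewness; the analytic skewness magnitude of
    Beta(8.5, 1.5) is ~1.13.  ``flip`` mirrors the distribution about 1/2,
    negating the skewness.
    """

    p: float
    target_mean: float = 0.5
    target_sd: float = 0.15
    flip: bool = False

    def __post_init__(self):
        if not (0.0 < self.p < 10.0):
            raise InvalidParameterError("p must lie in (0, 10)")
        if not (0.0 < self.target_mean < 1.0):
            raise InvalidParameterError("target_mean must lie in (0, 1)")
        if not self.target_sd > 0:
            raise InvalidParameterError("target_sd must be > 0")

    @property
    def q(self) -> float:
        return 10.0 - self.p


def beta_skewness(p: float, q: float) -> float:
    """Analytic skewness of Beta(p, q): 2(q-p)sqrt(p+q+1) / ((p+q+2)sqrt(pq))."""
    return 2.0 * (q - p) * math.sqrt(p + q + 1.0) / ((p + q + 2.0) * math.sqrt(p * q))


def beta_reference(ref: BetaRef, n: int) -> np.ndarray:
    """n deterministic quantile samples of the rescaled Beta reference.

    Quantiles are taken at probabilities (i - 0.5)/n, affinely rescaled to
    the target mean/SD (sample moments, exact before clipping), then clipped
    to [0, 1].
    """
    if n < 2:
        raise InvalidParameterError("n must be >= 2")
    probs = (np.arange(n) + 0.5) / n
    q = stats.beta.ppf(probs, ref.p, ref.q)
    if ref.flip:
        q = 1.0 - q[::-1]
    mu, sd = q.mean(), q.std()
    if sd > 0:
        q = (q - mu) / sd * ref.target_sd + ref.target_mean
    return np.clip(q, 0.0, 1.0)


def compressive_tonemap(x, c: float, r: float = 30.0, as_printed: bool = False):
    """Smooth-minimum compressive map saturating at the cut-off intensity c.

    Evaluated in log space, [(1-x)^r + (1-c)^r]^(1/r) =
    exp(logsumexp(r*log(1-x), r*log(1-c)) / r), so large r does not
    underflow (the direct power form collapses to 0 once (1-x)^r drops
    below the smallest normal float).
    """
    if not (0.0 < c <= 1.0):
        raise InvalidParameterError("c must lie in (0, 1]")
    if not r > 0:
        raise InvalidParameterError("r must be > 0")
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        log_x_term = r * np.log1p(-np.minimum(x, 1.0))
    log_c_term = r * math.log1p(-c) if c < 1.0 else -np.inf
    stacked = np.stack([log_x_term, np.full_like(log_x_term, log_c_term)])
    inner = np.exp(special.logsumexp(stacked, axis=0) / r)
    out = inner if as_printed else 1.0 - inner
    return out if out.ndim else float(out)


def auto_cutoff(img: IntensityImage) -> float:
    """Automatic cut-off: masked mean minus one SD, clamped into (0, 1]."""
    inside = img.values[img.mask]
    c = float(inside.mean() - inside.std())
    return min(max(c, 1e-6), 1.0)


def sinusoid_remap(x, curve: SinusoidCurve):
    """Evaluate the linear+sinusoid curve, then clip to [0, 1]."""
    x = np.asarray(x, dtype=float)
    u = x - curve.m
    out = curve.s1 * u + curve.s2 * np.sin(curve.omega * u + curve.phi) + curve.m
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def is_monotone(curve, domain: tuple[float, float] = (0.0, 1.0)) -> bool:
    """True iff the curve is nondecreasing on the domain.

    Sinusoid curves are decided analytically: when the modulation sweeps at
    least one full cycle over the domain the derivative minimum is exactly
    s1 - |s2|*omega; otherwise the derivative is minimized on a dense grid.
    Compressive curves (corrected form) are always nondecreasing; tables are
    checked pairwise.
    """
    lo, hi = domain
    if not hi > lo:
        raise InvalidParameterError("domain must be a nonempty interval")
    if isinstance(curve, SinusoidCurve):
        if abs(curve.omega) * (hi - lo) >= 2.0 * math.pi:
            return curve.s1 - abs(curve.s2) * abs(curve.omega) >= 0
        u = np.linspace(lo, hi, 4096) - curve.m
        deriv = curve.s1 + curve.s2 * curve.omega * np.cos(curve.omega * u + curve.phi)
        return bool(deriv.min() >= 0)
    if isinstance(curve, CompressiveCurve):
        return not curve.as_printed
    if isinstance(curve, TableCurve):
        return bool(np.all(np.diff(curve.outputs) >= 0))
    x = np.linspace(lo, hi, 4096)
    return bool(np.all(np.diff(curve(x)) >= -1e-12))


def histogram_match(src: IntensityImage, reference_sample) -> IntensityImage:
    """Match the masked intensity histogram of ``src`` to a reference sample.

    The pixel with rank k among the n masked-in pixels receives the k-th
    order statistic of the reference (resampled by quantile at (k - 0.5)/n
    when the reference size differs from n).  Tied input pixels receive the
    mean of their group's reference values, so ties — and hence the exact
    intensity order, midranks included — are preserved by construction.
    """
    ref = np.sort(np.asarray(reference_sample, dtype=float).ravel())
    if ref.size == 0:
        raise InvalidParameterError("reference sample is empty")
    vals = src.values[src.mask]
    n = vals.size
    if n == 0:
        raise InvalidParameterError("source image has an empty mask")
    if ref.size != n:
        ref = np.quantile(ref, (np.arange(n) + 0.5) / n)
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    # tie groups of the sorted input -> mean reference value per group
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    np.not_equal(sorted_vals[1:], sorted_vals[:-1], out=new_group[1:])
    group_id = np.cumsum(new_group) - 1
    n_groups = group_id[-1] + 1
    sums = np.bincount(group_id, weights=ref, minlength=n_groups)
    counts = np.bincount(group_id, minlength=n_groups)
    matched_sorted = (sums / counts)[group_id]
    matched = np.empty(n)
    matched[order] = matched_sorted
    out = np.zeros_like(src.values)
    out[src.mask] = np.clip(matched, 0.0, 1.0)
    return IntensityImage(out, src.mask, src.white_point)


def apply_tone_curve(img: IntensityImage, curve) -> IntensityImage:
    """Apply a tone curve to the masked-in pixels; clip to [0, 1]."""
    out = np.where(img.mask, np.clip(curve(img.values), 0.0, 1.0), 0.0)
    return IntensityImage(out, img.mask, img.white_point)


def sample_skewness(values) -> float:
    """Biased moment skewness m3 / m2^(3/2) (no small-sample correction)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise InvalidParameterError("need at least 3 values")
    d = v - v.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        raise UndefinedStatisticError("skewness undefined for zero variance")
    return float(np.mean(d**3) / m2**1.5)


def order_preservation_index(a: IntensityImage, b: IntensityImage) -> float:
    """Rank agreement of two images' masked pixels, in [-1, 1].

    Computed as the Goodman–Kruskal gamma: (concordant - discordant) /
    (concordant + discordant) over pixel pairs, ignoring pairs tied in
    either image.  It is exactly 1 for any nondecreasing remapping of ``a``
    (a saturating tone map collapses the top of the range into ties but
    reverses no pair, so the intensity order is intact), exactly -1 for a
    reversal, and near 0 for a random permutation.  A midrank rank
    correlation (Spearman) would charge saturation ties against order
    preservation, which is not what "disrupting the intensity order" means
    here — disruption is reversal.
    """
    if a.mask.shape != b.mask.shape or not np.array_equal(a.mask, b.mask):
        raise StructureMismatchError("images must share an identical mask")
    va, vb = a.values[a.mask], b.values[b.mask]
    if va.size < 3:
        raise UndefinedStatisticError("need at least 3 masked-in pixels")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise UndefinedStatisticError("rank correlation undefined for constant image")
    n = va.size
    n0 = n * (n - 1) / 2.0

    def tied_pairs(x) -> float:
        _, counts = np.unique(x, return_counts=True)
        return float(np.sum(counts * (counts - 1) / 2.0))

    tx = tied_pairs(va)
    ty = tied_pairs(vb)
    txy = tied_pairs(va + 1j * vb)
    untied = n0 - tx - ty + txy  # pairs tied in neither image
    if untied <= 0:
        raise UndefinedStatisticError("no untied pixel pairs")
    # kendalltau's tau-b = (C - D) / sqrt((n0 - tx)(n0 - ty)); recover C - D
    tau_b = stats.kendalltau(va, vb).statistic
    c_minus_d = tau_b * math.sqrt((n0 - tx) * (n0 - ty))
    return float(np.clip(c_minus_d / untied, -1.0, 1.0))
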