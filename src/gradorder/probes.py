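"""Gauge-probe shape-judgment statistics.

A gauge sample is one surface-orientation judgment, recorded as slant/tilt
at a probe location.  Two matched sets of samples (e.g. judgments on an
original and a tone-remapped image) are compared by the angular difference
between the corresponding gauge normals, aggregated hierarchically
(trials -> gauges -> observers) with a percentile bootstrap over observers
for the 95% confidence interval, or by tilt (circular) and slant (Pearson)
correlations of per-gauge trial means.

A simulated observer perturbs ground-truth normals with tangent-plane
Gaussian noise, providing synthetic judgment data; real gauge data in the
same CSV layout (observer_id, condition_id, gauge_index, trial, slant_deg,
tilt_deg) can replace it without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, StructureMismatchError, UndefinedStatisticError
from .gradients import circular_correlation
from .scene import NormalField

__all__ = [
    "GaugeSample",
    "AngularSummary",
    "gauge_to_normal",
    "normal_to_slant_tilt",
    "angular_difference",
    "aggregate_angular_difference",
    "tilt_slant_correlations",
    "simulate_observer",
    "samples_to_frame",
]


@dataclass(frozen=True)
class GaugeSample:
    """One gauge-probe setting: (slant, tilt) at a probe location."""

    observer_id: str
    condition_id: str
    gauge_index: int
    slant_deg: float
    tilt_deg: float
    trial: int = 1

    def __post_init__(self):
        if not (0.0 <= self.slant_deg <= 90.0):
            raise InvalidParameterError("slant_deg must lie in [0, 90]")
        if not (0.0 <= self.tilt_deg < 360.0):
            raise InvalidParameterError("tilt_deg must lie in [0, 360)")
        if self.gauge_index < 1 or self.trial < 1:
            raise InvalidParameterError("gauge_index and trial are 1-based")

    @property
    def normal(self) -> np.ndarray:
        return gauge_to_normal(self.slant_deg, self.tilt_deg)


@dataclass(frozen=True)
class AngularSummary:
    """Mean angular difference (radians) with a 95% bootstrap CI."""

    mean_diff_rad: float
    ci_low: float
    ci_high: float
    n_observers: int

    def __post_init__(self):
        if not (self.ci_low - 1e-12 <= self.mean_diff_rad <= self.ci_high + 1e-12):
            raise InvalidParameterError("CI must bracket the mean")

    @property
    def mean_diff_deg(self) -> float:
        return math.degrees(self.mean_diff_rad)


def gauge_to_normal(slant_deg: float, tilt_deg: float) -> np.ndarray:
    """Unit normal (sin s cos t, sin s sin t, cos s) of a gauge setting."""
    if not (0.0 <= slant_deg <= 90.0):
        raise InvalidParameterError("slant_deg must lie in [0, 90]")
    if not (0.0 <= tilt_deg < 360.0):
        raise InvalidParameterError("tilt_deg must lie in [0, 360)")
    s = math.radians(slant_deg)
    t = math.radians(tilt_deg)
    return np.array([math.sin(s) * math.cos(t), math.sin(s) * math.sin(t), math.cos(s)])


def normal_to_slant_tilt(n) -> tuple[float, float]:
    """Slant/tilt (degrees) of a unit normal; tilt wrapped into [0, 360)."""
    n = np.asarray(n, dtype=float)
    slant = math.degrees(math.acos(float(np.clip(n[2], -1.0, 1.0))))
    tilt = math.degrees(math.atan2(n[1], n[0])) % 360.0
    return slant, tilt


def angular_difference(g1: GaugeSample, g2: GaugeSample) -> float:
    """Angle (radians, in [0, pi]) between two gauge normals.

    Evaluated as 2*arcsin(|n1 - n2|/2), which is exactly 0 for identical
    settings and numerically stable for nearly parallel normals (the
    arccos-of-dot-product form loses ~1e-8 there).
    """
    n1, n2 = g1.normal, g2.normal
    half_chord = 0.5 * float(np.linalg.norm(n1 - n2))
    return 2.0 * math.asin(min(1.0, half_chord))


def samples_to_frame(samples) -> pd.DataFrame:
    """Tabulate gauge samples (the package's CSV layout)."""
    return pd.DataFrame([{
        "observer_id": s.observer_id,
        "condition_id": s.condition_id,
        "gauge_index": s.gauge_index,
        "trial": s.trial,
        "slant_deg": s.slant_deg,
        "tilt_deg": s.tilt_deg,
    } for s in samples])


def _matched_pairs(samples_a, samples_b):
    key = lambda s: (s.observer_id, s.gauge_index, s.trial)
    a = {key(s): s for s in samples_a}
    b = {key(s): s for s in samples_b}
    if len(a) != len(samples_a) or len(b) != len(samples_b):
        raise StructureMismatchError("duplicate (observer, gauge, trial) keys")
    if a.keys() != b.keys():
        raise StructureMismatchError("sample sets do not share (observer, gauge, trial) structure")
    return [(a[k], b[k]) for k in a]


def aggregate_angular_difference(samples_a, samples_b, n_boot: int = 10000,
                                 seed: int | None = None) -> AngularSummary:
    """Hierarchical mean angular difference with a percentile bootstrap CI.

    Differences are averaged over trials within each (observer, gauge),
    then over gauges within each observer; the grand mean is the mean of
    the per-observer means.  The 95% CI is a percentile bootstrap over
    observers with ``n_boot`` resamples, deterministic given ``seed``.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    pairs = _matched_pairs(samples_a, samples_b)
    df = pd.DataFrame([{
        "observer": sa.observer_id,
        "gauge": sa.gauge_index,
        "diff": angular_difference(sa, sb),
    } for sa, sb in pairs])
    per_gauge = df.groupby(["observer", "gauge"], sort=True)["diff"].mean()
    obs_means = per_gauge.groupby("observer").mean().to_numpy()
    mean = float(obs_means.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, obs_means.size, size=(n_boot, obs_means.size))
    boots = obs_means[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo = min(float(lo), mean)
    hi = max(float(hi), mean)
    return AngularSummary(mean, lo, hi, int(obs_means.size))


def tilt_slant_correlations(samples_a, samples_b) -> tuple[float, float]:
    """(circular correlation of tilts, Pearson correlation of slants).

    Points are per-(observer, gauge) trial means: circular means for tilt,
    arithmetic means for slant.
    """
    pairs = _matched_pairs(samples_a, samples_b)
    df = pd.DataFrame([{
        "observer": sa.observer_id,
        "gauge": sa.gauge_index,
        "tilt_a": math.radians(sa.tilt_deg),
        "tilt_b": math.radians(sb.tilt_deg),
        "slant_a": sa.slant_deg,
        "slant_b": sb.slant_deg,
    } for sa, sb in pairs])

    def circ_mean(x):
        return math.atan2(np.sin(x).mean(), np.cos(x).mean())

    g = df.groupby(["observer", "gauge"], sort=True)
    tilts_a = g["tilt_a"].agg(circ_mean).to_numpy()
    tilts_b = g["tilt_b"].agg(circ_mean).to_numpy()
    slants_a = g["slant_a"].mean().to_numpy()
    slants_b = g["slant_b"].mean().to_numpy()
    tilt_corr = circular_correlation(tilts_a, tilts_b)
    if np.ptp(slants_a) == 0 or np.ptp(slants_b) == 0:
        raise UndefinedStatisticError("slant correlation undefined: zero variance")
    slant_corr = float(np.corrcoef(slants_a, slants_b)[0, 1])
    return tilt_corr, slant_corr


def _tangent_basis(n: np.ndarray):
    z = np.array([0.0, 0.0, 1.0])
    t1 = np.cross(z, n)
    norm = np.linalg.norm(t1)
    if norm < 1e-12:
        t1 = np.array([1.0, 0.0, 0.0])
    else:
        t1 /= norm
    t2 = np.cross(n, t1)
    return t1, t2


def simulate_observer(normals: NormalField, gauge_positions, noise_deg: float,
                      n_trials: int, seed: int | None = None,
                      observer_id: str = "sim", condition_id: str = "sim"):
    """Synthetic gauge judgments: ground-truth normals plus angular noise.

    Each trial perturbs the true normal at a (row, col) probe position by a
    tangent-plane bivariate Gaussian with per-axis standard deviation
    ``noise_deg`` (the marginal angular SD), then renormalizes.  Noise 0
    reproduces the ground truth exactly; output is deterministic given the
    seed.
    """
    if noise_deg < 0:
        raise InvalidParameterError("noise_deg must be >= 0")
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    s = math.radians(noise_deg)
    samples = []
    for gauge_index, (row, col) in enumerate(gauge_positions, start=1):
        if not normals.mask[row, col]:
            raise InvalidParameterError(f"position ({row}, {col}) is outside the mask")
        n = normals.normals[row, col]
        t1, t2 = _tangent_basis(n)
        for trial in range(1, n_trials + 1):
            if s > 0:
                e1, e2 = rng.normal(0.0, s, size=2)
                perturbed = n + e1 * t1 + e2 * t2
                perturbed /= np.linalg.norm(perturbed)
            else:
                perturbed = n
            slant, tilt = normal_to_slant_tilt(perturbed)
            slant = min(slant, 90.0)
            samples.append(GaugeSample(observer_id, condition_id, gauge_index,
                                       slant, tilt, trial))
    return samples
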