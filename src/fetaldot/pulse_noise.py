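"""Fetal-pulse metrics and the distance-dependent measurement noise model.

Optical density change between cardiac phases, required detector dynamic
range, and a multiplicative Gaussian noise whose fractional standard
deviation grows exponentially with source-detector distance.  Noisy metrics
are formed by averaging the per-repetition noisy fluences (480 repetitions,
i.e. four minutes at a 2 Hz fetal heart rate) before taking ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: noise-model defaults: k(r) = amplitude * exp(rate * r), r in mm
DEFAULT_NOISE_AMPLITUDE = 0.0024
DEFAULT_NOISE_RATE = 0.0236
DEFAULT_REPETITIONS = 480


@dataclass(frozen=True)
class NoiseModel:
    amplitude: float = DEFAULT_NOISE_AMPLITUDE
    rate: float = DEFAULT_NOISE_RATE
    repetitions: int = DEFAULT_REPETITIONS

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def noise_std(r, model: NoiseModel = NoiseModel()):
    """Fractional noise standard deviation k(r) at SD distance r (mm)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("SD distance must be >= 0")
    out = model.amplitude * np.exp(model.rate * r)
    return float(out) if out.ndim == 0 else out


def delta_od(phi_diastole, phi_systole, base: float = 10.0):
    """Optical density change log_base(Phi_diastole / Phi_systole)."""
    phi_d = np.asarray(phi_diastole, dtype=float)
    phi_s = np.asarray(phi_systole, dtype=float)
    if np.any(phi_d <= 0) or np.any(phi_s <= 0):
        raise ValueError("fluences must be positive")
    out = np.log(phi_d / phi_s) / math.log(base)
    return float(out) if out.ndim == 0 else out


def dynamic_range(phi_diastole, phi_systole, strict: bool = True):
    """Required dynamic range Phi_diastole / (Phi_diastole - Phi_systole).

    With ``strict`` the degenerate case Phi_s >= Phi_d raises; otherwise it
    returns +inf (flagged overflow, possible for noisy long channels).
    """
    phi_d = np.asarray(phi_diastole, dtype=float)
    phi_s = np.asarray(phi_systole, dtype=float)
    if np.any(phi_d <= 0) or np.any(phi_s <= 0):
        raise ValueError("fluences must be positive")
    diff = phi_d - phi_s
    if np.any(diff <= 0):
        if strict:
            raise ValueError(
                "dynamic range undefined: systolic fluence >= diastolic"
            )
        with np.errstate(divide="ignore"):
            out = np.where(diff > 0, phi_d / np.where(diff > 0, diff, 1.0),
                           np.inf)
    else:
        out = phi_d / diff
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def apply_noise(phi, r, model: NoiseModel, rng: np.random.Generator):
    """Multiplicative Gaussian noise: Phi * (1 + N(0, k(r)^2))."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("fluences must be positive")
    k = noise_std(r, model)
    out = phi * (1.0 + rng.normal(0.0, 1.0, size=phi.shape) * k)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NoisyMetrics:
    delta_od: float
    dynamic_range: float
    finite: bool


def averaged_noisy_metrics(
    phi_diastole: float,
    phi_systole: float,
    r: float,
    model: NoiseModel,
    rng: np.random.Generator,
    base: float = 10.0,
) -> NoisyMetrics:
    """Noisy pulse metrics from repetition-averaged fluences.

    The systolic and diastolic states are drawn independently, averaged over
    ``model.repetitions`` repetitions, and the metrics are computed from the
    averages.  Deterministic for a fixed generator state.
    """
    if phi_diastole <= 0 or phi_systole <= 0:
        raise ValueError("fluences must be positive")
    k = noise_std(r, model)
    reps = model.repetitions
    avg_s = float(np.mean(phi_systole * (1.0 + rng.normal(0.0, k, size=reps))))
    avg_d = float(np.mean(phi_diastole * (1.0 + rng.normal(0.0, k, size=reps))))
    if avg_s <= 0 or avg_d <= 0:
        return NoisyMetrics(math.nan, math.inf, finite=False)
    dod = delta_od(avg_d, avg_s, base=base)
    if avg_s >= avg_d:
        return NoisyMetrics(dod, math.inf, finite=False)
    return NoisyMetrics(dod, dynamic_range(avg_d, avg_s), finite=True)
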