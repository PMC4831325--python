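"""Signal-curve conditioning and automated uptake-interval detection.

Raw ROI-averaged signal curves are converted to enhancement curves
(precontrast baseline subtracted), the postaortic rise is located on the
aortic curve, and the subject-specific end-of-uptake point is selected on
the smoothed renal curve.

A normal renal enhancement curve has three phases: a vascular first-pass
peak, a slowly ascending filtration (uptake) segment ending at a second
peak, and a slowly descending outflow segment. The end of the second peak
is the end-of-uptake point. Detection distinguishes two curve classes:

* ``outflow_defined`` — the derivative turns clearly negative after the
  filtration phase; the point of maximum enhancement before that descent
  is returned;
* ``plateau`` — the derivative merely flattens (plateau or very slow
  rise); the first sample of the flat run is returned, because a plateau
  already indicates that a significant amount of contrast is leaving the
  parenchyma.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .pk_models import DomainError, TimeSeriesCurve

__all__ = [
    "DetectionError",
    "ConfigError",
    "UptakeMode",
    "DetectionConfig",
    "UptakeDetectionResult",
    "enhancement_curve",
    "detect_postaortic_rise",
    "smooth_curve",
    "detect_end_of_uptake",
]


class DetectionError(RuntimeError):
    """A curve feature required by the pipeline could not be located."""


class ConfigError(ValueError):
    """A configuration value violates its constraints."""


class UptakeMode(str, Enum):
    OUTFLOW_DEFINED = "outflow_defined"
    PLATEAU = "plateau"


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables of rise and end-of-uptake detection.

    ``smoothing_window`` is a centered moving-average width in samples
    (odd); ``rise_sigma_k`` the baseline-SD multiplier of the aortic rise
    threshold; ``plateau_fraction`` the fraction of the maximum filtration
    slope below which the curve counts as flat (and above which, negative,
    as outflow); ``persistence`` the number of consecutive samples a
    condition must hold.
    """

    smoothing_window: int = 5
    rise_sigma_k: float = 3.0
    plateau_fraction: float = 0.1
    persistence: int = 3

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigError("smoothing_window must be odd and >= 1")
        if self.rise_sigma_k <= 0:
            raise ConfigError("rise_sigma_k must be positive")
        if not 0.0 < self.plateau_fraction < 1.0:
            raise ConfigError("plateau_fraction must lie in (0, 1)")
        if self.persistence < 1:
            raise ConfigError("persistence must be >= 1")


@dataclass(frozen=True)
class UptakeDetectionResult:
    postaortic_rise_index: int
    end_of_uptake_index: int
    uptake_interval: float  # seconds
    mode: UptakeMode


def enhancement_curve(raw: TimeSeriesCurve) -> TimeSeriesCurve:
    """Subtract the precontrast baseline; keep its mean and SD as metadata.

    At low concentrations signal change is proportional to gadolinium
    concentration, so the enhancement curve is the concentration proxy used
    by all downstream modelling.
    """
    base = raw.values[: raw.n_precontrast]
    mean = float(np.mean(base))
    sd = float(np.std(base, ddof=0))
    return raw.with_values(raw.values - mean, baseline_mean=mean, baseline_sd=sd)


def _first_run(mask: np.ndarray, m: int) -> int | None:
    """Index of the first run of ``m`` consecutive True values, else None."""
    if mask.size < m:
        return None
    if m == 1:
        hits = np.flatnonzero(mask)
        return int(hits[0]) if hits.size else None
    conv = np.convolve(mask.astype(int), np.ones(m, dtype=int), mode="valid")
    hits = np.flatnonzero(conv == m)
    return int(hits[0]) if hits.size else None


def detect_postaortic_rise(aorta_enh: TimeSeriesCurve, config: DetectionConfig) -> int:
    """Locate the postaortic rise on the aortic enhancement curve.

    Returns the index of the measurement *before* the first increase of the
    aortic signal after contrast injection: the sample preceding the first
    value above ``rise_sigma_k`` baseline SDs sustained for ``persistence``
    samples. With a noise-free baseline (SD = 0) any strictly positive
    value counts as supra-threshold.
    """
    if aorta_enh.baseline_sd is None:
        raise DetectionError("curve lacks baseline metadata; apply enhancement_curve first")
    thr = config.rise_sigma_k * aorta_enh.baseline_sd
    mask = aorta_enh.values > thr
    first = _first_run(mask, config.persistence)
    if first is None:
        raise DetectionError("no postaortic rise found")
    if first == 0:
        raise DetectionError("aortic signal is supra-threshold from the first sample")
    return first - 1


def smooth_curve(curve: TimeSeriesCurve, window: int) -> TimeSeriesCurve:
    """Centered moving average with edge shrinkage (length preserved)."""
    if window < 1 or window % 2 == 0:
        raise ConfigError("smoothing window must be odd and >= 1")
    if window > len(curve):
        raise ConfigError("smoothing window exceeds curve length")
    if window == 1:
        return curve
    kernel = np.ones(window)
    sums = np.convolve(curve.values, kernel, mode="same")
    counts = np.convolve(np.ones_like(curve.values), kernel, mode="same")
    return curve.with_values(sums / counts)


def detect_end_of_uptake(
    kidney_enh: TimeSeriesCurve,
    rise_index: int,
    config: DetectionConfig,
) -> UptakeDetectionResult:
    """Select the subject-specific end-of-uptake point on the renal curve.

    Works on the smoothed curve. The reference slope ``d_max`` is the
    maximum derivative of the filtration phase, i.e. after the vascular
    first-pass peak where one exists (a renewed sustained rise follows a
    local maximum); otherwise the whole post-rise segment is used. Outflow
    takes precedence over a plateau: a sustained descent steeper than
    ``plateau_fraction * d_max`` defines the end of uptake as the maximum
    enhancement before it, while a sustained flat run returns its first
    sample.
    """
    n = len(kidney_enh)
    if not 0 <= rise_index < n - 1:
        raise DetectionError("rise_index outside curve")
    sm = smooth_curve(kidney_enh, config.smoothing_window).values
    dt = kidney_enh.dt
    d = np.diff(sm) / dt  # d[i]: slope between samples i and i+1
    m = config.persistence

    # Locate the vascular first-pass peak: first non-positive slope after
    # an initial rise. If a sustained rise resumes afterwards, the
    # filtration phase starts there; otherwise the phases are merged.
    seg = d[rise_index:]
    f0 = rise_index
    pos = np.flatnonzero(seg > 0)
    if pos.size:
        nonpos = np.flatnonzero(seg[pos[0]:] <= 0)
        if nonpos.size:
            i_peak = rise_index + pos[0] + nonpos[0]
            renewed = _first_run(d[i_peak:] > 0, m)
            if renewed is not None:
                f0 = i_peak + renewed

    tail = d[f0:]
    if tail.size == 0:
        raise DetectionError("no samples after filtration-phase start")
    d_max = float(np.max(tail))
    if d_max <= 0:
        raise DetectionError("no rising filtration phase found")
    thr = config.plateau_fraction * d_max

    out = _first_run(tail <= -thr, m)
    if out is not None:
        descent = f0 + out
        end = rise_index + int(np.argmax(sm[rise_index : descent + 1]))
        mode = UptakeMode.OUTFLOW_DEFINED
    else:
        flat = _first_run(np.abs(tail) < thr, m)
        if flat is None:
            raise DetectionError(
                "neither outflow nor plateau found; curve truncated mid-uptake"
            )
        end = f0 + flat
        mode = UptakeMode.PLATEAU

    if end <= rise_index:
        raise DetectionError("end-of-uptake does not follow the postaortic rise")
    return UptakeDetectionResult(
        postaortic_rise_index=rise_index,
        end_of_uptake_index=end,
        uptake_interval=(end - rise_index) * dt,
        mode=mode,
    )
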