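"""Seeded synthetic renal DCE-MRI cohort generator.

Each synthetic subject consists of ground-truth kinetics (a two-gamma-
variate plasma AIF and inflow-outflow kidney parameters), raw aortic and
renal signal curves sampled on the study acquisition grid (dt = 1.7 s,
135 time points, 10 precontrast) with baseline offsets and Gaussian
noise, a hematocrit, a renal parenchymal volume, and a noisy reference
GFR emulating an independent clearance measurement.

Cohort heterogeneity emulates the study population: hematocrit uniform on
30-49%, parenchymal volume normal 241 +/- 52 mL truncated to 158-333 mL,
GFR_V uniform on 0.20-0.60 min^-1 (whole-kidney GFR roughly 57-134
mL/min), and subject-specific uptake intervals spanning the physiologic
64-141 s band after the postaortic rise.

The kidney ground truth is generated with the inflow-outflow forward
model, so fitting the uptake model to it is a genuine approximation; the
tubular mean transit time is drawn long (tens of minutes), so the end of
uptake is governed by vascular washout of the late AIF rather than by
tubular drainage. The true end-of-uptake point is defined as the argmax
of the noise-free kidney enhancement curve (the maximum parenchymal
enhancement).

Several kinetic draws are coupled rather than independent, because the
timing of the enhancement maximum is a joint property of filtration,
vascular fraction and AIF washout:

* the target uptake interval is drawn with a mild negative coupling to
  GFR_V (faster-filtering kidneys peak earlier),
* the washout ratio ``phi = (GFR_V/60) * c2 / v_p`` (filtration inflow
  over vascular washout at the late AIF decay rate ``1/c2``) is drawn in
  a band that places the enhancement maximum just past the late AIF hump
  and makes the post-maximum descent decisive,
* the recirculation lobe scale is then solved from the target interval.

Draws whose realized interval still falls outside 64-141 s (or whose
maximum is not comfortably inside the acquisition) are rejected and
redrawn, so every subject presents the well-defined uptake/outflow
morphology the detection stage is specified against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curve_processing import ConfigError
from .pk_models import (
    AifModel,
    KidneyModelParams,
    TimeSeriesCurve,
    eval_aif,
    forward_inflow_outflow,
)

__all__ = ["CohortConfig", "GroundTruth", "SubjectRecord", "simulate_subject", "simulate_cohort"]


def _check_bounds(lo: float, hi: float, name: str) -> None:
    if not lo <= hi:
        raise ConfigError(f"{name} bounds are not ordered")


@dataclass(frozen=True)
class CohortConfig:
    """Acquisition, distribution and noise settings of the simulator.

    Times are seconds, volumes mL, GFR_V min^-1. ``noise_sd`` is the
    Gaussian noise SD as a fraction of each curve's peak enhancement;
    ``reference_noise_sd`` (mL/min) emulates the cross-method variability
    of a reference GFR measurement taken days apart from the MRI.
    ``interval_bounds`` is the target band of the true uptake interval
    (postaortic rise to maximum enhancement); ``interval_gfr_coupling``
    shortens the upper end for high-GFR_V subjects (s per min^-1).
    """

    seed: int
    n_subjects: int = 29
    dt: float = 1.7
    n_timepoints: int = 135
    n_precontrast: int = 10
    gfr_v_bounds: tuple[float, float] = (0.20, 0.60)
    hct_bounds: tuple[float, float] = (0.30, 0.49)
    volume_mean: float = 241.0
    volume_sd: float = 52.0
    volume_bounds: tuple[float, float] = (158.0, 333.0)
    delay_bounds: tuple[float, float] = (0.5, 4.0)
    t_disp_bounds: tuple[float, float] = (2.0, 5.0)
    t_tub_bounds: tuple[float, float] = (4000.0, 9000.0)
    interval_bounds: tuple[float, float] = (68.0, 138.0)
    interval_gfr_coupling: float = 40.0
    washout_ratio_bounds: tuple[float, float] = (0.12, 0.20)
    v_p_limits: tuple[float, float] = (0.12, 0.40)
    recirc_b2_limits: tuple[float, float] = (3.5, 9.0)
    aif_onset_bounds: tuple[float, float] = (18.7, 23.8)
    aif_peak_bounds: tuple[float, float] = (0.9, 1.1)
    aif_b1_bounds: tuple[float, float] = (2.0, 4.0)
    aif_ttp_bounds: tuple[float, float] = (6.0, 9.0)
    recirc_delay_bounds: tuple[float, float] = (22.0, 30.0)
    recirc_peak_frac_bounds: tuple[float, float] = (0.25, 0.40)
    baseline_aorta_bounds: tuple[float, float] = (20.0, 40.0)
    baseline_kidney_bounds: tuple[float, float] = (10.0, 30.0)
    noise_sd: float = 0.02
    reference_noise_sd: float = 5.0
    refine: int = 10

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if not 1 <= self.n_precontrast < self.n_timepoints:
            raise ConfigError("need 1 <= n_precontrast < n_timepoints")
        if self.noise_sd < 0 or self.reference_noise_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        for name in (
            "gfr_v_bounds", "hct_bounds", "volume_bounds", "delay_bounds",
            "t_disp_bounds", "t_tub_bounds", "interval_bounds",
            "washout_ratio_bounds", "v_p_limits", "recirc_b2_limits",
            "aif_onset_bounds", "aif_peak_bounds", "aif_b1_bounds",
            "aif_ttp_bounds", "recirc_delay_bounds", "recirc_peak_frac_bounds",
            "baseline_aorta_bounds", "baseline_kidney_bounds",
        ):
            _check_bounds(*getattr(self, name), name)
        if self.aif_onset_bounds[0] <= self.n_precontrast * self.dt:
            raise ConfigError("AIF onset must fall after the precontrast phase")

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_timepoints)


@dataclass(frozen=True)
class GroundTruth:
    """True kinetic parameters and timing of one simulated subject."""

    aif: AifModel
    kidney: KidneyModelParams
    rise_index: int
    end_of_uptake_index: int
    end_of_uptake_time: float
    uptake_interval: float
    true_gfr_ml_min: float


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's raw curves plus covariates (and, for simulated
    subjects, the generating ground truth)."""

    subject_id: str
    aorta_curve: TimeSeriesCurve
    kidney_curve: TimeSeriesCurve
    hct: float
    parenchymal_volume: float
    reference_gfr: float | None = None
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if not np.array_equal(self.aorta_curve.times, self.kidney_curve.times):
            raise ConfigError("aorta and kidney curves must share the time axis")
        if not 0.0 < self.hct < 1.0:
            raise ConfigError(f"subject {self.subject_id}: hct must be in (0, 1)")
        if self.parenchymal_volume <= 0:
            raise ConfigError(f"subject {self.subject_id}: volume must be positive")


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _draw_kinetics(
    config: CohortConfig, rng: np.random.Generator, gfr_v: float
) -> tuple[AifModel, KidneyModelParams, np.ndarray, int, int]:
    """Draw a coupled (AIF, kidney) pair with an in-band uptake interval.

    ``gfr_v`` is drawn once per subject outside this loop so that
    rejection does not distort the cohort's filtration distribution.
    Returns the accepted draw together with the noise-free kidney
    enhancement curve and the true rise / end-of-uptake indices.
    """
    times = config.times
    u = rng.uniform
    lo_iv, hi_iv = config.interval_bounds
    gfr_lo = config.gfr_v_bounds[0]
    b2_lo, b2_hi = config.recirc_b2_limits
    vp_lo, vp_hi = config.v_p_limits
    g = gfr_v / 60.0
    for _ in range(500):
        t1 = u(*config.aif_onset_bounds)
        peak = u(*config.aif_peak_bounds)
        b1 = u(*config.aif_b1_bounds)
        c1 = u(*config.aif_ttp_bounds) / b1
        a1 = peak / ((b1 * c1) ** b1 * np.exp(-b1))
        dt2 = u(*config.recirc_delay_bounds)
        delay = u(*config.delay_bounds)
        t_disp = u(*config.t_disp_bounds)
        # target interval, mildly shorter for fast-filtering kidneys
        iv_hi = hi_iv - config.interval_gfr_coupling * (gfr_v - gfr_lo)
        if iv_hi <= lo_iv:
            iv_hi = lo_iv + 1.0
        target = u(lo_iv, iv_hi)
        # time from recirculation onset to the enhancement maximum
        span = target - dt2 - delay - 0.5 * t_disp
        if span <= 10.0:
            continue
        phi = u(*config.washout_ratio_bounds)
        c2_min = max(span * (1 - phi) / b2_hi, vp_lo * phi / g)
        c2_max = min(vp_hi * phi / g, span * (1 - phi) / b2_lo)
        if c2_min >= c2_max:
            continue
        c2 = u(c2_min, c2_max)
        b2 = span * (1 - phi) / c2
        v_p = g * c2 / phi
        a2 = peak * u(*config.recirc_peak_frac_bounds) / ((b2 * c2) ** b2 * np.exp(-b2))
        aif = AifModel(a1=a1, b1=b1, c1=c1, t1=t1, a2=a2, b2=b2, c2=c2, t2=t1 + dt2)
        kidney = KidneyModelParams(
            v_p=v_p,
            gfr_v=gfr_v,
            delay=delay,
            t_disp=t_disp,
            t_tub=u(*config.t_tub_bounds),
        )
        ck = forward_inflow_outflow(
            kidney, aif, times, refine=config.refine, n_precontrast=config.n_precontrast
        ).values
        rise = int(np.searchsorted(times, aif.t1, side="right") - 1)
        end = int(np.argmax(ck))
        interval = (end - rise) * config.dt
        # accept only the well-defined uptake/outflow morphology: interval
        # inside the physiologic band, maximum well before end of series
        if 64.0 + config.dt <= interval <= 141.0 - config.dt and end < times.size - 5:
            return aif, kidney, ck, rise, end
    raise ConfigError("could not draw an in-band subject; check cohort bounds")


def simulate_subject(
    config: CohortConfig, rng: np.random.Generator, subject_id: str = "S001"
) -> SubjectRecord:
    """Draw one subject: ground truth, sampled noisy curves, covariates.

    The stored aortic signal is the blood-equivalent curve, i.e. the plasma
    AIF scaled by ``(1 - hct)``, so that plasma correction inverts the
    scaling exactly. Baseline offsets are added to both curves and seeded
    Gaussian noise (SD = ``noise_sd`` x peak enhancement of each curve) on
    top of every sample, including the precontrast baseline.
    """
    times = config.times
    u = rng.uniform
    hct = float(u(*config.hct_bounds))
    volume = _truncated_normal(
        rng, config.volume_mean, config.volume_sd, *config.volume_bounds
    )
    gfr_v = float(u(*config.gfr_v_bounds))
    aif, kidney, kidney_enh, rise_index, end_index = _draw_kinetics(config, rng, gfr_v)
    plasma = eval_aif(aif, times, n_precontrast=config.n_precontrast)
    aorta_enh = plasma.values * (1.0 - hct)

    truth = GroundTruth(
        aif=aif,
        kidney=kidney,
        rise_index=rise_index,
        end_of_uptake_index=end_index,
        end_of_uptake_time=float(times[end_index]),
        uptake_interval=float((end_index - rise_index) * config.dt),
        true_gfr_ml_min=kidney.gfr_v * volume,
    )

    base_a = u(*config.baseline_aorta_bounds)
    base_k = u(*config.baseline_kidney_bounds)
    sd_a = config.noise_sd * float(np.max(aorta_enh))
    sd_k = config.noise_sd * float(np.max(kidney_enh))
    aorta_vals = base_a + aorta_enh + (rng.normal(0.0, sd_a, times.size) if sd_a > 0 else 0.0)
    kidney_vals = base_k + kidney_enh + (rng.normal(0.0, sd_k, times.size) if sd_k > 0 else 0.0)

    ref = truth.true_gfr_ml_min
    if config.reference_noise_sd > 0:
        ref += float(rng.normal(0.0, config.reference_noise_sd))

    def curve(vals):
        return TimeSeriesCurve(times=times, values=vals, n_precontrast=config.n_precontrast)

    return SubjectRecord(
        subject_id=subject_id,
        aorta_curve=curve(aorta_vals),
        kidney_curve=curve(kidney_vals),
        hct=hct,
        parenchymal_volume=volume,
        reference_gfr=ref,
        ground_truth=truth,
    )


def simulate_cohort(config: CohortConfig, out_dir=None) -> list[SubjectRecord]:
    """Simulate ``config.n_subjects`` independent subjects from one seed.

    Each subject gets an independent child stream of the cohort seed, so
    the cohort is reproducible bit-exact from ``(config, seed)``. When
    ``out_dir`` is given, curve and metadata files are written there via
    :mod:`mrgfr.workflow_io`.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    records = [
        simulate_subject(config, np.random.default_rng(s), subject_id=f"S{i + 1:03d}")
        for i, s in enumerate(streams)
    ]
    if out_dir is not None:
        from .workflow_io import write_cohort

        write_cohort(records, out_dir, config=config)
    return records
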