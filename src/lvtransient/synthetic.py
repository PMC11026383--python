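"""Synthetic post-infarction cohorts with known ground truth.

Generates parametric LV volume transients, ellipsoidal mask phantoms,
covariates, MACE outcomes and event times with the statistical structure
the downstream analysis assumes, so every stage is testable without
patient data.

The volume-time curve is a piecewise raised-cosine over one cardiac
cycle (C1-smooth joins), which gives every cardiac-phase landmark a
closed form:

* systole [0, Ts]            EDV -> ESV descent
* passive filling [Ts, Ts+Tp]  ESV -> ESV + P
* diastasis plateau, Td ms     flat at ESV + P
* active filling, Ta ms        back to EDV at t = RR

with Ts + Tp + Td + Ta = RR and P + A = SV = EDV - ESV. Patients
without detectable diastasis are generated by merging both filling
phases into a single raised cosine (plateau duration 0).

Class-conditional parameter distributions default to the published
MACE / No-MACE cohort medians and IQRs where available (RR-interval,
RR variability, diastasis duration); volumes and ejection fraction use
typical post-infarct values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .volumes import SegmentationStack, VolumeTransient

MACE_RATE_DEFAULT = 73 / 1021  # composite-event prevalence emulated


class ParameterError(ValueError):
    """Raised for infeasible generative parameters."""


# --------------------------------------------------------------- parameters

def _sigma_from_iqr(q25: float, q75: float) -> float:
    """Log-normal sigma matching a printed interquartile range."""
    return math.log(q75 / q25) / (2 * 0.6744897501960817)


@dataclass
class ClassParams:
    """Per-outcome-class generative distributions (median + spread).

    Log-normal draws for positively skewed quantities (RR, RR
    variability, EDV, diastasis plateau); truncated normal for bounded
    fractions (EF, passive-filling fraction, systolic-time fraction).
    """

    rr_median_ms: float
    rr_log_sigma: float
    rr_var_median_pct: float
    rr_var_log_sigma: float
    edv_median_ml: float
    edv_log_sigma: float
    ef_median_pct: float
    ef_sd_pct: float
    passive_frac_median: float
    passive_frac_sd: float
    diastasis_median_ms: float
    diastasis_log_sigma: float
    prob_no_diastasis: float
    noise_sd_ml: float
    systolic_frac_median: float = 0.355
    systolic_frac_sd: float = 0.03

    def validate(self) -> None:
        for name in ("rr_median_ms", "rr_log_sigma", "rr_var_median_pct",
                     "edv_median_ml", "ef_median_pct", "diastasis_median_ms"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be positive and finite")
        if not 0 <= self.prob_no_diastasis <= 1:
            raise ParameterError("prob_no_diastasis must lie in [0, 1]")
        if self.noise_sd_ml < 0:
            raise ParameterError("noise_sd_ml must be >= 0")


def default_no_mace_params() -> ClassParams:
    return ClassParams(
        rr_median_ms=845.0, rr_log_sigma=_sigma_from_iqr(741, 952),
        rr_var_median_pct=18.9, rr_var_log_sigma=_sigma_from_iqr(13.0, 25.6),
        edv_median_ml=150.0, edv_log_sigma=0.20,
        ef_median_pct=50.5, ef_sd_pct=9.0,
        passive_frac_median=0.665, passive_frac_sd=0.10,
        diastasis_median_ms=80.0, diastasis_log_sigma=0.60,
        prob_no_diastasis=0.20, noise_sd_ml=1.0,
    )


def default_mace_params() -> ClassParams:
    return ClassParams(
        rr_median_ms=780.0, rr_log_sigma=_sigma_from_iqr(674, 848),
        rr_var_median_pct=24.6, rr_var_log_sigma=_sigma_from_iqr(14.2, 36.7),
        edv_median_ml=160.0, edv_log_sigma=0.20,
        ef_median_pct=45.0, ef_sd_pct=9.0,
        passive_frac_median=0.67, passive_frac_sd=0.11,
        diastasis_median_ms=55.0, diastasis_log_sigma=0.60,
        prob_no_diastasis=0.30, noise_sd_ml=1.0,
    )


@dataclass
class CohortSpec:
    """Cohort-level generative specification."""

    n_patients: int = 1000
    mace_rate: float = MACE_RATE_DEFAULT
    seed: int = 0
    n_frames_range: tuple[int, int] = (25, 30)
    horizon_months: float = 12.0
    no_mace: ClassParams = field(default_factory=default_no_mace_params)
    mace: ClassParams = field(default_factory=default_mace_params)
    diastasis_threshold_frac: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.mace_rate < 1:
            raise ParameterError("mace_rate must lie strictly in (0, 1)")
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.n_frames_range[0] < 10:
            raise ParameterError("n_frames must be >= 10")
        if self.horizon_months <= 0:
            raise ParameterError("horizon must be positive")
        self.no_mace.validate()
        self.mace.validate()


@dataclass
class TransientParams:
    """Per-patient closed-form curve parameters (all times ms, volumes mL)."""

    rr_ms: float
    edv_ml: float
    esv_ml: float
    systole_ms: float
    passive_ms: float
    diastasis_ms: float
    active_ms: float
    passive_ml: float
    active_ml: float
    n_frames: int = 28
    noise_sd_ml: float = 0.0
    merged_filling: bool = False  # true for no-diastasis physiology

    def __post_init__(self) -> None:
        if not (self.edv_ml > self.esv_ml > 0):
            raise ParameterError("EDV > ESV > 0 required")
        durations = (self.systole_ms, self.passive_ms, self.active_ms)
        if min(durations) <= 0 or self.diastasis_ms < 0:
            raise ParameterError("phase durations must be positive")
        total = sum(durations) + self.diastasis_ms
        if abs(total - self.rr_ms) > 1e-6 * self.rr_ms:
            raise ParameterError("phase durations must sum to RR")
        if abs(self.passive_ml + self.active_ml - self.sv_ml) > 1e-6 * self.sv_ml:
            raise ParameterError("passive + active filling must equal SV")
        if self.merged_filling and self.diastasis_ms != 0:
            raise ParameterError("merged filling implies zero plateau")

    @property
    def sv_ml(self) -> float:
        return self.edv_ml - self.esv_ml


# -------------------------------------------------------- closed-form curve

def analytic_volume(params: TransientParams, t) -> np.ndarray:
    """Evaluate the noise-free curve at times t (ms), periodic in RR."""
    p = params
    t = np.asarray(t, dtype=float) % p.rr_ms
    v = np.empty_like(t)
    ts, tp, td = p.systole_ms, p.passive_ms, p.diastasis_ms
    esv, sv = p.esv_ml, p.sv_ml

    sys_m = t < ts
    v[sys_m] = esv + sv / 2 * (1 + np.cos(np.pi * t[sys_m] / ts))
    if p.merged_filling:
        tf = p.rr_ms - ts
        fil = ~sys_m
        v[fil] = esv + sv / 2 * (1 - np.cos(np.pi * (t[fil] - ts) / tf))
        return v
    pas = (t >= ts) & (t < ts + tp)
    v[pas] = esv + p.passive_ml / 2 * (1 - np.cos(np.pi * (t[pas] - ts) / tp))
    dia = (t >= ts + tp) & (t < ts + tp + td)
    v[dia] = esv + p.passive_ml
    act = t >= ts + tp + td
    t0 = ts + tp + td
    v[act] = (esv + p.passive_ml
              + p.active_ml / 2 * (1 - np.cos(np.pi * (t[act] - t0) / p.active_ms)))
    return v


def analytic_velocity(params: TransientParams, t) -> np.ndarray:
    """dV/dt of the noise-free curve, in mL/ms."""
    p = params
    t = np.asarray(t, dtype=float) % p.rr_ms
    v = np.zeros_like(t)
    ts, tp, td = p.systole_ms, p.passive_ms, p.diastasis_ms

    sys_m = t < ts
    v[sys_m] = -(np.pi * p.sv_ml) / (2 * ts) * np.sin(np.pi * t[sys_m] / ts)
    if p.merged_filling:
        tf = p.rr_ms - ts
        fil = ~sys_m
        v[fil] = (np.pi * p.sv_ml) / (2 * tf) * np.sin(np.pi * (t[fil] - ts) / tf)
        return v
    pas = (t >= ts) & (t < ts + tp)
    v[pas] = (np.pi * p.passive_ml) / (2 * tp) * np.sin(np.pi * (t[pas] - ts) / tp)
    act = t >= ts + tp + td
    t0 = ts + tp + td
    v[act] = (np.pi * p.active_ml) / (2 * p.active_ms) * np.sin(
        np.pi * (t[act] - t0) / p.active_ms)
    return v


@dataclass
class PlantedLandmarks:
    """Closed-form landmark times (ms) of the generated curve.

    Diastasis bounds follow the detection rule's operational definition:
    the times at which |dV/dt| crosses threshold_frac * SV per second
    around the flat plateau. For merged-filling (no-diastasis) patients
    the filling-phase landmarks are None and found is False.
    """

    t_ed: float
    t_sys_peak_vel: float
    t_es: float
    t_passive_peak_vel: float | None
    t_diastasis_begin: float | None
    t_mid_diastasis: float | None
    t_diastasis_end: float | None
    t_active_peak_vel: float | None
    diastasis_found: bool
    diastasis_duration_ms: float
    plateau_ms: float


def analytic_landmarks(params: TransientParams,
                       threshold_frac: float = 0.8) -> PlantedLandmarks:
    """All eight landmark times of the closed-form curve.

    The diastasis begin/end are the exact threshold crossings of the
    velocity around the plateau (threshold = threshold_frac * SV / s),
    i.e. the values the detection rule recovers on a noise-free curve.
    """
    p = params
    ts, tp, td, ta = p.systole_ms, p.passive_ms, p.diastasis_ms, p.active_ms
    if p.merged_filling:
        return PlantedLandmarks(
            t_ed=0.0, t_sys_peak_vel=ts / 2, t_es=ts,
            t_passive_peak_vel=None, t_diastasis_begin=None,
            t_mid_diastasis=None, t_diastasis_end=None,
            t_active_peak_vel=None, diastasis_found=False,
            diastasis_duration_ms=0.0, plateau_ms=0.0,
        )
    thr = threshold_frac * p.sv_ml / 1000.0  # mL/ms
    vpk_pas = np.pi * p.passive_ml / (2 * tp)
    vpk_act = np.pi * p.active_ml / (2 * ta)
    r_pas = min(thr / vpk_pas, 1.0)
    r_act = min(thr / vpk_act, 1.0)
    begin = ts + tp * (1 - math.asin(r_pas) / math.pi)
    end = ts + tp + td + ta * math.asin(r_act) / math.pi
    return PlantedLandmarks(
        t_ed=0.0, t_sys_peak_vel=ts / 2, t_es=ts,
        t_passive_peak_vel=ts + tp / 2,
        t_diastasis_begin=begin,
        t_mid_diastasis=(begin + end) / 2,
        t_diastasis_end=end,
        t_active_peak_vel=p.rr_ms - ta / 2,
        diastasis_found=True,
        diastasis_duration_ms=end - begin,
        plateau_ms=td,
    )


def generate_transient(params: TransientParams,
                       rng: np.random.Generator | None = None) -> VolumeTransient:
    """Sample the closed-form curve at n_frames trigger times.

    Optional i.i.d. Gaussian volume noise (params.noise_sd_ml) is added;
    trigger times are uniform over [0, RR).
    """
    t = np.arange(params.n_frames) * (params.rr_ms / params.n_frames)
    v = analytic_volume(params, t)
    if params.noise_sd_ml > 0:
        if rng is None:
            rng = np.random.default_rng()
        v = np.maximum(v + rng.normal(0.0, params.noise_sd_ml, v.size), 0.0)
    return VolumeTransient(trigger_times=t, volumes=v, rr_ms=params.rr_ms)


# ----------------------------------------------------------------- cohort

@dataclass
class SyntheticPatient:
    patient_id: str
    transient: VolumeTransient
    rr_ms: float
    rr_variability_pct: float
    rr_list_ms: list[float]
    covariates: dict[str, float]
    outcome: int
    event_time_months: float
    censored: bool
    params: TransientParams
    planted: PlantedLandmarks


def _draw_params(cls: ClassParams, rng: np.random.Generator,
                 n_frames_range: tuple[int, int]) -> TransientParams:
    def lognorm(median, sigma):
        return float(median * np.exp(rng.normal(0.0, sigma)))

    def truncnorm(mean, sd, lo, hi):
        for _ in range(100):
            x = rng.normal(mean, sd)
            if lo < x < hi:
                return float(x)
        return float(np.clip(mean, lo, hi))

    rr = lognorm(cls.rr_median_ms, cls.rr_log_sigma)
    edv = lognorm(cls.edv_median_ml, cls.edv_log_sigma)
    ef = truncnorm(cls.ef_median_pct, cls.ef_sd_pct, 20.0, 75.0)
    esv = edv * (1 - ef / 100.0)
    sv = edv - esv
    ts = truncnorm(cls.systolic_frac_median, cls.systolic_frac_sd, 0.25, 0.5) * rr
    merged = bool(rng.random() < cls.prob_no_diastasis)
    fill = rr - ts
    if merged:
        td = 0.0
        # a nominal 50/50 split keeps durations valid; passive/active
        # are not separable in a merged filling phase
        tp = ta = fill / 2
        p_ml = a_ml = sv / 2
    else:
        # atrial-kick duration ~16% of the cycle (~135 ms at RR 845,
        # consistent with printed active peak-velocity medians and
        # scaling with cycle length); diastasis capped so the passive
        # phase keeps a physiological minimum duration
        ta = truncnorm(0.16, 0.02, 0.12, 0.22) * rr
        tp_min = 0.18 * rr
        td = min(lognorm(cls.diastasis_median_ms, cls.diastasis_log_sigma),
                 fill - ta - tp_min)
        td = max(td, 1.0)
        tp = fill - td - ta
        p_frac = truncnorm(cls.passive_frac_median, cls.passive_frac_sd,
                           0.35, 0.90)
        p_ml = p_frac * sv
        a_ml = sv - p_ml
    n_frames = int(rng.integers(n_frames_range[0], n_frames_range[1] + 1))
    return TransientParams(
        rr_ms=rr, edv_ml=edv, esv_ml=esv, systole_ms=ts, passive_ms=tp,
        diastasis_ms=td, active_ms=ta, passive_ml=p_ml, active_ml=a_ml,
        n_frames=n_frames, noise_sd_ml=cls.noise_sd_ml, merged_filling=merged,
    )


def generate_cohort(spec: CohortSpec):
    """Draw a full synthetic cohort.

    Returns (patients, feature_table): the per-patient ground-truth
    carriers and a pandas feature table with baseline covariates (ESV,
    EDV, EF analogues plus two pure-noise covariates), the binary MACE
    outcome, event time and censor flag. Reproducible bit-for-bit under
    a fixed spec (including seed).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    patients: list[SyntheticPatient] = []
    rows = []
    for i in range(spec.n_patients):
        outcome = int(rng.random() < spec.mace_rate)
        cls = spec.mace if outcome else spec.no_mace
        params = _draw_params(cls, rng, spec.n_frames_range)
        transient = generate_transient(params, rng)
        pid = f"S{i:04d}"
        transient.patient_id = pid
        planted = analytic_landmarks(params, spec.diastasis_threshold_frac)

        rr_var = float(cls.rr_var_median_pct
                       * np.exp(rng.normal(0.0, cls.rr_var_log_sigma)))
        # a 3-beat RR metadata list realizing mean rr and (max-min)/mean
        half = params.rr_ms * rr_var / 200.0
        rr_list = [params.rr_ms - half, params.rr_ms, params.rr_ms + half]

        if outcome:
            event_time = float(rng.uniform(0.0, spec.horizon_months))
            event_time = max(event_time, 1e-6)
            censored = False
        else:
            event_time = spec.horizon_months
            censored = True
        cov = {
            "esv_ml": params.esv_ml,
            "edv_ml": params.edv_ml,
            "ef_pct": 100.0 * params.sv_ml / params.edv_ml,
            "noise_cov_1": float(rng.normal()),
            "noise_cov_2": float(rng.normal()),
        }
        patients.append(SyntheticPatient(
            patient_id=pid, transient=transient, rr_ms=params.rr_ms,
            rr_variability_pct=rr_var, rr_list_ms=rr_list, covariates=cov,
            outcome=outcome, event_time_months=event_time, censored=censored,
            params=params, planted=planted,
        ))
        rows.append({"patient_id": pid, **cov, "mace": outcome,
                     "time_months": event_time, "censored": censored})
    return patients, pd.DataFrame(rows)


def planted_truth_records(patients: list[SyntheticPatient]) -> list[dict]:
    """JSON-serializable planted ground truth for a cohort."""
    out = []
    for p in patients:
        out.append({
            "patient_id": p.patient_id,
            "params": asdict(p.params),
            "landmarks": asdict(p.planted),
            "outcome": p.outcome,
            "event_time_months": p.event_time_months,
            "censored": p.censored,
            "rr_variability_pct": p.rr_variability_pct,
        })
    return out


# ----------------------------------------------------------- mask phantom

def generate_mask_stack(semi_axes_mm: np.ndarray,
                        pixel_mm: float = 1.25,
                        slice_spacing_mm: float = 8.0,
                        n_slices: int = 12,
                        grid_shape: tuple[int, int] = (96, 96),
                        trigger_times: np.ndarray | None = None,
                        rr_ms: float | None = None,
                        patient_id: str = "phantom") -> SegmentationStack:
    """Ellipsoidal cavity phantom for testing volume reconstruction.

    semi_axes_mm has shape (frames, 3): per-frame ellipsoid semi-axes
    (a, b, c) with c along the slice direction. Slices are taken at
    slice centers symmetric about the ellipsoid equator; the analytic
    volume 4/3*pi*a*b*c per frame is attached as ground truth (mL).
    """
    semi = np.atleast_2d(np.asarray(semi_axes_mm, dtype=float))
    if semi.shape[1] != 3 or np.any(semi < 0):
        raise ParameterError("semi_axes_mm must be (frames, 3), non-negative")
    n_frames = semi.shape[0]
    rows, cols = grid_shape
    half_extent_z = slice_spacing_mm * (n_slices - 1) / 2
    if np.any(semi[:, 0] > pixel_mm * rows / 2) or \
       np.any(semi[:, 1] > pixel_mm * cols / 2) or \
       np.any(semi[:, 2] > half_extent_z + slice_spacing_mm / 2):
        raise ParameterError("ellipsoid exceeds the sampling grid")

    y = (np.arange(rows) - (rows - 1) / 2) * pixel_mm
    x = (np.arange(cols) - (cols - 1) / 2) * pixel_mm
    z = (np.arange(n_slices) - (n_slices - 1) / 2) * slice_spacing_mm
    yy, xx = np.meshgrid(y, x, indexing="ij")

    masks = np.zeros((n_frames, n_slices, rows, cols), dtype=np.uint8)
    true_ml = np.zeros(n_frames)
    for f in range(n_frames):
        a, b, c = semi[f]
        true_ml[f] = 4.0 / 3.0 * np.pi * a * b * c / 1000.0
        if a == 0 or b == 0 or c == 0:
            continue
        for k, zk in enumerate(z):
            if abs(zk) >= c:
                continue
            shrink = math.sqrt(1 - (zk / c) ** 2)
            masks[f, k] = ((yy / (a * shrink)) ** 2
                           + (xx / (b * shrink)) ** 2 <= 1.0)
    if trigger_times is None:
        trigger_times = np.arange(n_frames, dtype=float) * 30.0
    if rr_ms is None:
        rr_ms = float(trigger_times[-1] + (trigger_times[1] - trigger_times[0]
                                           if n_frames > 1 else 30.0))
    return SegmentationStack(
        masks=masks, pixel_spacing=(pixel_mm, pixel_mm),
        slice_spacing=slice_spacing_mm, trigger_times=trigger_times,
        rr_ms=rr_ms, patient_id=patient_id, true_volumes_ml=true_ml,
    )
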