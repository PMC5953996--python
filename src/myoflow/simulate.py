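"""Synthetic rest/stress dynamic perfusion studies with known ground truth.

Emulates, at the time-activity-curve level, a two-modality flow study:
a 30-patient cohort, three coronary territories per patient, rest plus
pharmacological stress, a trapped-tracer (sestamibi-like) SPECT arm on a
32-frame schedule and a freely diffusible (water-like) PET arm on a
24-frame schedule, with an invasive FFR value linked to each territory.

The arterial input function is a gamma-variate bolus with an optional
recirculation tail; tissue curves follow a one-tissue compartment model
(washout rate zero for the trapped tracer), contaminated by blood-pool
spillover and partial-volume scaling; frame values are averaged from a
0.1 s grid.  Noise is Gaussian with Poisson-like variance scaling
(variance proportional to signal and inversely proportional to frame
duration) — a count-statistics surrogate appropriate for concentration
units.  Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import truncnorm

from .retention import renkin_crone_forward
from .tac import (BLOOD, GLOBAL, MYO_REGIONS, TERRITORIES, FrameSchedule,
                  TimeActivityCurve, total_duration)

FINE_DT = 0.1  # seconds; simulation grid


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a realistic bolus (15 s rise, small recirculation
    tail), a resting flow near 1 mL/min/g, hyperemic reserve 2.4-3.6 in
    normal territories and 1.2-1.9 in diseased ones, and the cohort
    prevalence of 12 FFR-abnormal territories out of 90.
    """

    seed: int = 0
    n_patients: int = 30
    # arterial input function
    aif_peak: float = 100.0            # kBq/mL, continuous-peak amplitude
    aif_time_to_peak: float = 15.0     # s from injection to bolus peak
    aif_alpha: float = 2.0             # gamma-variate shape
    aif_tail_fraction: float = 0.02    # recirculation amplitude relative to peak
    aif_tail_halflife: float = 40.0    # s
    injection_delay: float = 5.0       # s after acquisition start
    aif_stress_scale: float = 3.0      # stress/rest activity ratio, SPECT arm
    # measurement model
    spillover_sm_true: float = 0.30    # blood->myocardium spillover
    pv_true: float = 1.0               # partial-volume recovery of tissue signal
    noise_scale: float = 0.15          # Gaussian count-surrogate amplitude
    # cohort
    prevalence_abnormal_ffr: float = 12.0 / 90.0
    rest_mbf_mean: float = 1.0         # mL/min/g
    rest_mbf_sd: float = 0.2
    mfr_normal_range: tuple[float, float] = (2.4, 3.6)
    mfr_diseased_range: tuple[float, float] = (1.2, 1.9)
    ffr_normal_mean: float = 0.87
    ffr_normal_sd: float = 0.06
    ffr_diseased_mean: float = 0.72
    ffr_diseased_sd: float = 0.06
    ffr_perfectly_linked: bool = False  # if True, FFR is set deterministically by disease status
    partition_coefficient: float = 0.91  # mL/g, water tissue/blood partition

    def __post_init__(self) -> None:
        if self.aif_time_to_peak <= 0:
            raise ValueError("aif_time_to_peak must be positive")
        if not (0 <= self.aif_tail_fraction < 1):
            raise ValueError("aif_tail_fraction must be in [0, 1)")
        if not (0 < self.prevalence_abnormal_ffr < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if not (0 < self.pv_true <= 1.5):
            raise ValueError("pv_true must be in (0, 1.5]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        data = json.loads(text)
        for key in ("mfr_normal_range", "mfr_diseased_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def aif_continuous(config: SimConfig, t: np.ndarray,
                   peak_scale: float = 1.0) -> np.ndarray:
    """Continuous arterial input function, kBq/mL, at times ``t`` (s).

    A gamma-variate bolus ``((t-d)/tp)^alpha * exp(alpha*(1-(t-d)/tp))``
    whose mode is exactly at ``d + tp``, plus a recirculation tail that
    tracks the bolus up to the peak and then decays with the configured
    half-life; the sum is normalized so its maximum equals ``aif_peak``.
    """
    t = np.asarray(t, dtype=float)
    d, tp, a = config.injection_delay, config.aif_time_to_peak, config.aif_alpha
    x = (t - d) / tp
    h = np.zeros_like(t)
    pos = x > 0
    h[pos] = x[pos] ** a * np.exp(a * (1.0 - x[pos]))
    tf = config.aif_tail_fraction
    tail = np.where(x <= 1.0, h,
                    np.power(2.0, -(t - d - tp) / config.aif_tail_halflife))
    tail[~pos] = 0.0
    return peak_scale * config.aif_peak / (1.0 + tf) * (h + tf * tail)


def aif_arrival_time(config: SimConfig, fraction: float = 0.10) -> float:
    """Ground-truth arrival: first time the continuous AIF crosses
    ``fraction`` of its peak (the landmark the detector estimates)."""
    t = np.arange(0.0, config.injection_delay + 3 * config.aif_time_to_peak, 0.001)
    ca = aif_continuous(config, t)
    idx = np.argmax(ca > fraction * ca.max())
    return float(t[idx])


def _fine_grid(schedule: FrameSchedule, dt: float = FINE_DT) -> np.ndarray:
    t0 = float(schedule.frame_start[0])
    n = int(round(total_duration(schedule) / dt))
    return t0 + dt * np.arange(n + 1)


def _frame_average(schedule: FrameSchedule, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Average ``y(t)`` over each frame by exact trapezoid on the fine grid.

    Frame boundaries must lie on grid nodes (all printed protocols are
    multiples of the 0.1 s grid)."""
    cum = cumulative_trapezoid(y, t, initial=0.0)
    dt = t[1] - t[0]
    i_start = np.round((schedule.frame_start - t[0]) / dt).astype(int)
    i_end = np.round((schedule.frame_end - t[0]) / dt).astype(int)
    return (cum[i_end] - cum[i_start]) / schedule.frame_duration


def make_aif(config: SimConfig, schedule: FrameSchedule,
             peak_scale: float = 1.0) -> TimeActivityCurve:
    """Frame-averaged blood-pool TAC on ``schedule``."""
    t = _fine_grid(schedule)
    return TimeActivityCurve(schedule, _frame_average(schedule, t, aif_continuous(config, t, peak_scale)),
                             label=BLOOD)


def one_compartment_tissue(t: np.ndarray, ca: np.ndarray,
                           k1: float, k2: float) -> np.ndarray:
    """Tissue concentration Ct(t) = k1 * int_0^t Ca(u) exp(-k2 (t-u)) du.

    ``t`` in seconds, ``k1`` in mL/min/g, ``k2`` in 1/min; the convolution
    is evaluated in minutes so Ct carries the AIF's concentration unit.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("rate constants must be nonnegative")
    tm = np.asarray(t, dtype=float) / 60.0
    if k2 == 0.0:
        return k1 * cumulative_trapezoid(ca, tm, initial=0.0)
    g = np.exp(k2 * tm)  # k2*t stays < ~45 for in-bounds flows; no overflow
    inner = cumulative_trapezoid(ca * g, tm, initial=0.0)
    return k1 * inner / g


def make_tissue_tac(aif, k1: float, k2: float, sm: float, pv: float,
                    schedule: FrameSchedule, label: str = GLOBAL) -> TimeActivityCurve:
    """Observed myocardial TAC: P(t) = pv*Ct(t) + sm*Ca(t), frame-averaged.

    ``aif`` is either a callable ``t -> Ca`` (seconds -> kBq/mL) or an array
    of Ca values on the fine grid of ``schedule``.
    """
    t = _fine_grid(schedule)
    ca = aif(t) if callable(aif) else np.asarray(aif, dtype=float)
    if ca.shape != t.shape:
        raise ValueError("AIF array must match the fine grid of the schedule")
    ct = one_compartment_tissue(t, ca, k1, k2)
    return TimeActivityCurve(schedule, _frame_average(schedule, t, pv * ct + sm * ca),
                             label=label)


def add_noise(tac: TimeActivityCurve, noise_scale: float,
              seed: int | None = None,
              rng: np.random.Generator | None = None) -> TimeActivityCurve:
    """Count-statistics surrogate noise.

    Each frame value gets Gaussian noise with
    ``SD = noise_scale * sqrt(max(value, v_floor) / duration_min)`` where
    ``v_floor`` is 1% of the TAC maximum and the duration is in minutes —
    variance proportional to the signal and inversely proportional to frame
    length, as for counting statistics.  Results are clamped at zero.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be nonnegative")
    if noise_scale == 0:
        return tac
    if rng is None:
        rng = np.random.default_rng(seed)
    v = tac.values
    v_floor = 0.01 * float(np.max(v)) if np.max(v) > 0 else 0.0
    dur_min = tac.schedule.frame_duration / 60.0
    sd = noise_scale * np.sqrt(np.maximum(v, v_floor) / dur_min)
    noisy = v + rng.normal(0.0, 1.0, size=v.shape) * sd
    return TimeActivityCurve(tac.schedule, np.maximum(noisy, 0.0), label=tac.label)


@dataclass
class PatientStudy:
    """All four TAC sets for one patient: (state, modality) -> {region: TAC}."""
    patient_id: str
    tacs: dict = field(default_factory=dict)  # (state, modality) -> {label: TAC}


@dataclass
class StudyData:
    config: SimConfig
    patients: list
    truth: pd.DataFrame


def _draw_ffr(rng: np.random.Generator, mean: float, sd: float) -> float:
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_study(config: SimConfig) -> StudyData:
    """Draw the cohort truth and synthesize every TAC set.

    Per territory: disease status ~ Bernoulli(prevalence); rest MBF normal
    around ``rest_mbf_mean``; MFR uniform within the status-specific range;
    stress MBF = rest * MFR; FFR from a truncated normal conditioned on
    status (or set deterministically when ``ffr_perfectly_linked``).  True
    MBF maps to sestamibi uptake K1 through the forward Renkin-Crone
    relation (washout zero) and to water kinetics via k2 = MBF / p.
    The GLOBAL tissue curve is the mean of the three territory curves.
    """
    rng = np.random.default_rng(config.seed)
    spect_sched = FrameSchedule.spect_32frame()
    pet_sched = FrameSchedule.pet_24frame()
    grids = {"spect": _fine_grid(spect_sched), "pet": _fine_grid(pet_sched)}

    patients: list[PatientStudy] = []
    truth_rows = []
    for i in range(config.n_patients):
        pid = f"{i + 1:03d}"
        terr_truth = {}
        for terr in TERRITORIES:
            diseased = bool(rng.random() < config.prevalence_abnormal_ffr)
            rest = float(np.clip(rng.normal(config.rest_mbf_mean, config.rest_mbf_sd),
                                 0.4, 2.5))
            lo, hi = (config.mfr_diseased_range if diseased
                      else config.mfr_normal_range)
            mfr = float(rng.uniform(lo, hi))
            stress = rest * mfr
            if config.ffr_perfectly_linked:
                ffr = 0.75 if diseased else 0.90
            elif diseased:
                ffr = _draw_ffr(rng, config.ffr_diseased_mean, config.ffr_diseased_sd)
            else:
                ffr = _draw_ffr(rng, config.ffr_normal_mean, config.ffr_normal_sd)
            terr_truth[terr] = (rest, stress, mfr, ffr, diseased)
            truth_rows.append(dict(patient_id=pid, territory=terr,
                                   true_rest_mbf=rest, true_stress_mbf=stress,
                                   true_mfr=mfr, ffr=ffr, diseased=diseased))

        patient = PatientStudy(patient_id=pid)
        for state in ("rest", "stress"):
            mbf_of = {t: terr_truth[t][0 if state == "rest" else 1]
                      for t in TERRITORIES}
            for modality, sched in (("spect", spect_sched), ("pet", pet_sched)):
                scale = (config.aif_stress_scale
                         if (state == "stress" and modality == "spect") else 1.0)
                t = grids[modality]
                ca = aif_continuous(config, t, peak_scale=scale)
                region_tacs = {BLOOD: TimeActivityCurve(
                    sched, _frame_average(sched, t, ca), label=BLOOD)}
                terr_curves = {}
                for terr in TERRITORIES:
                    mbf = mbf_of[terr]
                    if modality == "spect":
                        k1, _ = renkin_crone_forward(mbf)
                        k2 = 0.0
                    else:
                        k1 = mbf
                        k2 = mbf / config.partition_coefficient
                    terr_curves[terr] = make_tissue_tac(
                        ca, k1, k2, config.spillover_sm_true, config.pv_true,
                        sched, label=terr)
                glob = TimeActivityCurve(
                    sched, np.mean([terr_curves[t_].values for t_ in TERRITORIES], axis=0),
                    label=GLOBAL)
                region_tacs[GLOBAL] = glob
                region_tacs.update(terr_curves)
                for label in (BLOOD,) + tuple(MYO_REGIONS):
                    region_tacs[label] = add_noise(region_tacs[label],
                                                   config.noise_scale, rng=rng)
                patient.tacs[(state, modality)] = region_tacs
        patients.append(patient)

    truth = pd.DataFrame(truth_rows)
    return StudyData(config=config, patients=patients, truth=truth)


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write the TAC CSV files, truth.csv and sim_config.json."""
    from .io import write_tac_file  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for patient in study.patients:
        for (state, modality), tacs in patient.tacs.items():
            path = outdir / f"P{patient.patient_id}_{state}_{modality}.csv"
            write_tac_file(tacs, path)
    truth = study.truth.copy()
    for col in ("true_rest_mbf", "true_stress_mbf", "true_mfr", "ffr"):
        truth[col] = truth[col].map(lambda x: f"{x:.6f}")
    truth.to_csv(outdir / "truth.csv", index=False)
    (outdir / "sim_config.json").write_text(study.config.to_json() + "\n")
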