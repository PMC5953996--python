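"""Net-retention quantification of the dynamic SPECT arm.

For a tracer that is trapped in myocardium (negligible washout over the
acquisition), the net retention rate

    R = [ 1/(PV*(t3-t2)) * int_{t2}^{t3} (P(t) - S_m*Ca(t)) dt ]
        / [ CF * int_0^{t1} (Ca(t) - S_b*P(t)) dt ]

ratios the late myocardial concentration (blood-free, partial-volume
corrected) against the integrated arterial input during the bolus phase.
R is identified with the uptake rate K1 (mL/min/g); myocardial blood flow
follows by inverting the Renkin-Crone relation

    K1 = MBF * (1 - A * exp(-B / MBF)),   A = 0.874, B = 0.443,

which corrects for the flow-dependent first-pass extraction of a
sestamibi-like tracer.  The integration windows are anchored to the
detected bolus (default: t1 = arrival + 90 s, tissue window arrival +
90..150 s, i.e. the conventional 1.5 min blood-pool phase and the
1.5-2.5 min tissue plateau when injection starts at time zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import bisect

from .tac import (MYO_REGIONS, TimeActivityCurve, _integrate_values,
                  detect_bolus_landmarks, integrate_tac, total_duration)

RENKIN_A = 0.874
RENKIN_B = 0.443  # mL/min/g inside the exponent
MBF_MAX = 10.0    # upper bracket for inversion, mL/min/g


@dataclass(frozen=True)
class RetentionParams:
    """All constants of the retention equation and its extraction correction.

    ``sm=None`` requests least-squares estimation of the blood-to-myocardium
    spillover from the blood-pool phase.  MBF scales as 1/pv, so the
    partial-volume default of 1.0 simply reports uncorrected flow.
    """

    pv: float = 1.0
    cf: float = 1.0
    sm: float | None = None
    sb: float = 0.0
    t1_offset: float = 90.0   # s after bolus arrival: end of blood-pool phase
    t2_offset: float = 90.0   # s: start of tissue window
    t3_offset: float = 150.0  # s: end of tissue window
    renkin_A: float = RENKIN_A
    renkin_B: float = RENKIN_B
    anchor: str = "arrival"   # "arrival" or "peak" of the blood TAC

    def __post_init__(self) -> None:
        if not (0 < self.pv <= 1.5):
            raise ValueError("pv must be in (0, 1.5]")
        if self.sm is not None and self.sm < 0:
            raise ValueError("sm must be nonnegative")
        if not (self.t1_offset <= self.t2_offset < self.t3_offset):
            raise ValueError("need t1_offset <= t2_offset < t3_offset")
        if not (0 < self.renkin_A < 1):
            raise ValueError("renkin_A must be in (0, 1)")
        if self.anchor not in ("arrival", "peak"):
            raise ValueError("anchor must be 'arrival' or 'peak'")


@dataclass(frozen=True)
class FlowEstimate:
    """Flow quantities for one region/state; r_retention == k1 by model."""
    region: str
    state: str
    r_retention: float   # 1/min
    extraction: float    # E = K1/MBF
    k1: float            # mL/min/g
    mbf: float           # mL/min/g
    sm_used: float
    window: tuple        # (t0, t1, t2, t3) seconds


@dataclass(frozen=True)
class MfrResult:
    region: str
    rest_mbf: float
    stress_mbf: float
    mfr: float


def renkin_crone_forward(mbf: float, A: float = RENKIN_A,
                         B: float = RENKIN_B) -> tuple[float, float]:
    """K1 and extraction fraction E for a given MBF (all mL/min/g)."""
    if mbf <= 0:
        raise ValueError("mbf must be positive")
    e = 1.0 - A * np.exp(-B / mbf)
    return float(mbf * e), float(e)


def renkin_crone_invert(k1: float, A: float = RENKIN_A,
                        B: float = RENKIN_B) -> float:
    """MBF solving k1 = MBF*(1 - A*exp(-B/MBF)).

    K1 is strictly increasing in MBF (dK1/dMBF = 1 - A e^{-B/M}(1+B/M) > 0
    for A < 1), so the root on (0, MBF_MAX] is unique; bisection to 1e-9.
    """
    if k1 <= 0:
        raise ValueError("k1 must be positive")
    k1_max, _ = renkin_crone_forward(MBF_MAX, A, B)
    if k1 > k1_max:
        raise ValueError(
            f"k1={k1:.4g} exceeds the maximum attainable uptake "
            f"{k1_max:.4g} mL/min/g at MBF={MBF_MAX}")
    return float(bisect(lambda m: renkin_crone_forward(m, A, B)[0] - k1,
                        1e-6, MBF_MAX, xtol=1e-9))


def estimate_spillover(myo: TimeActivityCurve, blood: TimeActivityCurve,
                       window: tuple[float, float]) -> float:
    """Blood-to-myocardium spillover S_m from the blood-pool phase.

    Fits P(t) ~ sm*Ca(t) + k*int_0^t Ca over frames whose midtimes fall in
    ``window`` (two-basis linear least squares; the second basis absorbs
    genuine uptake).  The estimate is clamped to [0, 1].
    """
    t_lo, t_hi = window
    mid = blood.midtimes
    in_win = (mid >= t_lo) & (mid <= t_hi)
    if int(np.sum(in_win)) < 3:
        raise ValueError("spillover window must contain at least 3 frames")
    ca = blood.values[in_win]
    if np.ptp(ca) <= 1e-9 * max(np.max(np.abs(ca)), 1e-300):
        raise ValueError(
            "blood TAC is constant over the spillover window (singular "
            "design); supply sm manually via RetentionParams(sm=...)")
    cum = np.array([integrate_tac(blood, float(blood.schedule.frame_start[0]), float(t))
                    if t > blood.schedule.frame_start[0] else 0.0
                    for t in mid[in_win]])
    X = np.column_stack([ca, cum])
    y = myo.values[in_win]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.clip(coef[0], 0.0, 1.0))


def retention_rate(myo: TimeActivityCurve, blood: TimeActivityCurve,
                   params: RetentionParams) -> FlowEstimate:
    """Net retention rate R (1/min) for one myocardial region.

    Returns a FlowEstimate with R identified with K1 and MBF from the
    Renkin-Crone inversion.  A negative tissue numerator clamps R to 0
    with a warning; a non-positive input integral raises.
    """
    t_arrival, t_peak = detect_bolus_landmarks(blood)
    t0 = t_arrival if params.anchor == "arrival" else t_peak
    t1, t2, t3 = (t0 + params.t1_offset, t0 + params.t2_offset,
                  t0 + params.t3_offset)
    t_end = float(blood.schedule.frame_start[0]) + total_duration(blood.schedule)
    if t3 > t_end + 1e-9:
        raise ValueError(
            f"acquisition ends at {t_end:.1f} s but the tissue window needs "
            f"{t3:.1f} s; bolus arrived too late for these offsets")

    sm = params.sm
    if sm is None:
        sm = estimate_spillover(myo, blood, (t0, t1))

    # numerator: mean blood-free tissue concentration over [t2, t3], kBq/mL
    num = _integrate_values(myo.schedule, myo.values - sm * blood.values,
                            t2, t3) / (params.pv * (t3 - t2) / 60.0)
    # denominator: integrated arterial input over the bolus phase, kBq/mL*min
    den = params.cf * _integrate_values(blood.schedule,
                                        blood.values - params.sb * myo.values,
                                        float(blood.schedule.frame_start[0]), t1)
    if den <= 0:
        raise ValueError("input-function integral is not positive: no usable bolus")
    r = num / den
    if r < 0:
        warnings.warn("negative tissue numerator; clamping retention rate to 0",
                      stacklevel=2)
        r = 0.0
    if r > 0:
        mbf = renkin_crone_invert(r, params.renkin_A, params.renkin_B)
        _, extraction = renkin_crone_forward(mbf, params.renkin_A, params.renkin_B)
    else:
        mbf, extraction = 0.0, 1.0
    return FlowEstimate(region=myo.label, state="", r_retention=float(r),
                        extraction=extraction, k1=float(r), mbf=mbf,
                        sm_used=float(sm), window=(t0, t1, t2, t3))


def quantify_spect(rest_tacs: dict, stress_tacs: dict,
                   params: RetentionParams = RetentionParams()
                   ) -> tuple[dict, dict]:
    """Run the retention pipeline on both states for every myocardial region.

    ``rest_tacs``/``stress_tacs`` map region labels (incl. BLOOD) to TACs.
    Returns ``(mfr_results, flow_estimates)`` keyed by region and
    (region, state) respectively.
    """
    tac_sets = {"rest": rest_tacs, "stress": stress_tacs}
    for state, tacs in tac_sets.items():
        if tacs is None:
            raise ValueError(f"missing TAC set for state '{state}'")
        if "BLOOD" not in tacs:
            raise ValueError(f"state '{state}' has no BLOOD input TAC")
    regions = [r for r in MYO_REGIONS if r in rest_tacs]
    if set(regions) != {r for r in MYO_REGIONS if r in stress_tacs}:
        raise ValueError("rest and stress must provide the same region set")
    if not regions:
        raise ValueError("no myocardial regions present")

    flows: dict[tuple[str, str], FlowEstimate] = {}
    for state, tacs in tac_sets.items():
        blood = tacs["BLOOD"]
        for region in regions:
            try:
                est = retention_rate(tacs[region], blood, params)
            except ValueError as exc:
                raise ValueError(f"region {region}, state {state}: {exc}") from exc
            flows[(region, state)] = replace(est, state=state)

    mfr: dict[str, MfrResult] = {}
    for region in regions:
        rest_mbf = flows[(region, "rest")].mbf
        stress_mbf = flows[(region, "stress")].mbf
        if rest_mbf <= 0:
            raise ValueError(f"region {region}: non-positive rest MBF; cannot form MFR")
        mfr[region] = MfrResult(region=region, rest_mbf=rest_mbf,
                                stress_mbf=stress_mbf,
                                mfr=stress_mbf / rest_mbf)
    return mfr, flows
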