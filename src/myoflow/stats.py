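"""Diagnostic-concordance statistics: thresholding, 2x2 agreement vs FFR,
Cohen's kappa, ROC/AUC with Youden cutoff, Bland-Altman and Pearson r.

Conventions fixed by the study design: flow indices (MFR, stress MBF) are
abnormal when strictly below their cutoff; FFR is abnormal at or below
0.8.  Rates are percentages; ratios with a zero denominator are reported
as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr as _scipy_pearsonr

from .tac import TERRITORIES

STRICTLY_BELOW = "strictly_below"
AT_OR_BELOW = "at_or_below"


@dataclass(frozen=True)
class Thresholds:
    """Abnormality cutoffs: PET MFR < 2, CZT MFR < 2.1 (ROC-derived),
    stress MBF < 2.5 mL/min/g, FFR <= 0.8."""

    pet_mfr_cutoff: float = 2.0
    czt_mfr_cutoff: float = 2.1
    stress_mbf_cutoff: float = 2.5
    ffr_cutoff: float = 0.8

    def __post_init__(self) -> None:
        if min(self.pet_mfr_cutoff, self.czt_mfr_cutoff,
               self.stress_mbf_cutoff, self.ffr_cutoff) <= 0:
            raise ValueError("cutoffs must be positive")
        if self.ffr_cutoff >= 1:
            raise ValueError("ffr_cutoff must be below 1")


def classify(value: float, cutoff: float, rule: str = STRICTLY_BELOW) -> bool:
    """True when the value is abnormal under the given tie rule."""
    if not math.isfinite(value):
        raise ValueError("value must be finite")
    if rule == STRICTLY_BELOW:
        return value < cutoff
    if rule == AT_OR_BELOW:
        return value <= cutoff
    raise ValueError(f"unknown rule {rule!r}")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts, index test x reference, both coded abnormal=positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_labels(cls, index_abnormal, ref_abnormal) -> "ContingencyTable":
        idx = np.asarray(index_abnormal, dtype=bool)
        ref = np.asarray(ref_abnormal, dtype=bool)
        if idx.shape != ref.shape:
            raise ValueError("label arrays must have equal length")
        return cls(tp=int(np.sum(idx & ref)), fp=int(np.sum(idx & ~ref)),
                   fn=int(np.sum(~idx & ref)), tn=int(np.sum(~idx & ~ref)))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def discordant(self) -> int:
        return self.fp + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/accuracy/PPV/NPV as percentages; NaN when
    the defining denominator is zero."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float


def _rate(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def diagnostic_metrics(table: ContingencyTable) -> DiagnosticMetrics:
    if table.total == 0:
        raise ValueError("empty contingency table")
    return DiagnosticMetrics(
        sensitivity=_rate(table.tp, table.tp + table.fn),
        specificity=_rate(table.tn, table.tn + table.fp),
        accuracy=_rate(table.tp + table.tn, table.total),
        ppv=_rate(table.tp, table.tp + table.fp),
        npv=_rate(table.tn, table.tn + table.fn),
    )


def cohen_kappa(table: ContingencyTable) -> float:
    """Unweighted Cohen's kappa of the 2x2 table."""
    n = table.total
    if n == 0:
        raise ValueError("empty contingency table")
    po = (table.tp + table.tn) / n
    pe = ((table.tp + table.fp) * (table.tp + table.fn)
          + (table.fn + table.tn) * (table.fp + table.tn)) / n ** 2
    if pe == 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def roc_curve(scores, truth) -> tuple[np.ndarray, np.ndarray, float, float]:
    """ROC for scores where LOWER means more abnormal.

    Sweeps thresholds over the unique scores plus a +inf sentinel, calling
    abnormal iff score < threshold.  Returns (fpr, tpr, auc, youden_cutoff);
    the cutoff maximizes Youden's J, ties resolved to the smallest cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos, n_neg = int(np.sum(y)), int(np.sum(~y))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    thresholds = np.concatenate((np.unique(s), [np.inf]))
    tpr = np.array([np.sum((s < th) & y) / n_pos for th in thresholds])
    fpr = np.array([np.sum((s < th) & ~y) / n_neg for th in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = float(thresholds[int(np.argmax(j))])  # argmax returns first max
    return fpr, tpr, auc, best


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of paired measurements.

    bias = mean(x - y); limits = bias +- 1.96 * SD(x - y) with the sample
    (n-1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length arrays with at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(_scipy_pearsonr(x, y)[0])


def _table_block(table: ContingencyTable) -> dict:
    m = diagnostic_metrics(table)
    return {
        "counts": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "n": table.total,
        "discordant": table.discordant,
        "sensitivity_pct": m.sensitivity,
        "specificity_pct": m.specificity,
        "accuracy_pct": m.accuracy,
        "ppv_pct": m.ppv,
        "npv_pct": m.npv,
        "kappa": cohen_kappa(table),
    }


def concordance_report(spect_results: pd.DataFrame, pet_results: pd.DataFrame,
                       ffr_table: pd.DataFrame,
                       thresholds: Thresholds = Thresholds()) -> dict:
    """The study's statistical layer over per-region flow tables.

    Inputs are DataFrames with columns ``patient_id, region, rest_mbf,
    stress_mbf, mfr`` (regions include GLOBAL and the three territories)
    and ``patient_id, territory, ffr``.  Builds both MFR-vs-FFR 2x2 tables
    over territories, Bland-Altman and Pearson agreement between the
    modalities for global MBF (rest and stress pooled) and global MFR, and
    ROC of the SPECT indices against PET-defined abnormality.
    """
    key = ["patient_id", "territory"]
    spect_t = spect_results[spect_results["region"].isin(TERRITORIES)].rename(
        columns={"region": "territory"})
    pet_t = pet_results[pet_results["region"].isin(TERRITORIES)].rename(
        columns={"region": "territory"})

    def _keyset(df, cols=("patient_id", "territory")):
        return set(map(tuple, df[list(cols)].itertuples(index=False)))

    ks, kp, kf = _keyset(spect_t), _keyset(pet_t), _keyset(ffr_table)
    if not (ks == kp == kf):
        mismatch = sorted((ks | kp | kf) - (ks & kp & kf))
        raise ValueError(f"unmatched patient/territory keys: {mismatch}")

    merged = (spect_t.merge(pet_t, on=key, suffixes=("_czt", "_pet"))
              .merge(ffr_table, on=key).sort_values(key).reset_index(drop=True))

    ffr_abn = merged["ffr"].map(
        lambda v: classify(v, thresholds.ffr_cutoff, AT_OR_BELOW))
    czt_abn = merged["mfr_czt"].map(
        lambda v: classify(v, thresholds.czt_mfr_cutoff, STRICTLY_BELOW))
    pet_abn = merged["mfr_pet"].map(
        lambda v: classify(v, thresholds.pet_mfr_cutoff, STRICTLY_BELOW))

    czt_table = ContingencyTable.from_labels(czt_abn, ffr_abn)
    pet_table = ContingencyTable.from_labels(pet_abn, ffr_abn)

    glob_s = spect_results[spect_results["region"] == "GLOBAL"].sort_values("patient_id")
    glob_p = pet_results[pet_results["region"] == "GLOBAL"].sort_values("patient_id")
    mbf_czt = np.concatenate([glob_s["rest_mbf"].to_numpy(),
                              glob_s["stress_mbf"].to_numpy()])
    mbf_pet = np.concatenate([glob_p["rest_mbf"].to_numpy(),
                              glob_p["stress_mbf"].to_numpy()])
    mfr_czt = glob_s["mfr"].to_numpy()
    mfr_pet = glob_p["mfr"].to_numpy()

    def _agreement(a, b):
        bias, lo, hi = (bland_altman(a, b) if len(a) >= 2
                        else (float("nan"),) * 3)
        r = pearson_r(a, b) if len(a) >= 3 else float("nan")
        return {"bias": bias, "loa_low": lo, "loa_high": hi,
                "pearson_r": r, "n": int(len(a))}

    # ROC of SPECT indices against PET-defined abnormality (global level)
    def _roc(scores, ref_abnormal):
        try:
            fpr, tpr, auc, cutoff = roc_curve(scores, ref_abnormal)
        except ValueError as exc:
            return {"auc": None, "youden_cutoff": None, "note": str(exc)}
        return {"auc": auc, "youden_cutoff": cutoff,
                "fpr": fpr.tolist(), "tpr": tpr.tolist()}

    pet_mfr_abn = [classify(v, thresholds.pet_mfr_cutoff, STRICTLY_BELOW)
                   for v in mfr_pet]
    pet_smbf_abn = [classify(v, thresholds.stress_mbf_cutoff, STRICTLY_BELOW)
                    for v in glob_p["stress_mbf"]]

    return {
        "thresholds": {"pet_mfr": thresholds.pet_mfr_cutoff,
                       "czt_mfr": thresholds.czt_mfr_cutoff,
                       "stress_mbf": thresholds.stress_mbf_cutoff,
                       "ffr": thresholds.ffr_cutoff},
        "czt_vs_ffr": _table_block(czt_table),
        "pet_vs_ffr": _table_block(pet_table),
        "discordant_territories": {
            "czt": sorted(map(tuple, merged.loc[czt_abn != ffr_abn, key]
                              .itertuples(index=False))),
            "pet": sorted(map(tuple, merged.loc[pet_abn != ffr_abn, key]
                              .itertuples(index=False))),
        },
        "global_mbf_agreement": _agreement(mbf_czt, mbf_pet),
        "global_mfr_agreement": _agreement(mfr_czt, mfr_pet),
        "roc_czt_mfr_vs_pet": _roc(mfr_czt, pet_mfr_abn),
        "roc_czt_stress_mbf_vs_pet": _roc(glob_s["stress_mbf"].to_numpy(),
                                          pet_smbf_abn),
    }
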