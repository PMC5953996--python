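"""Figures for the modality comparison: Bland-Altman and ROC.

Reads the cohort report and flow tables produced by 02_quantify_flows.py
and writes bland_altman_mbf.png / roc_czt_mfr.png under
results/cohort/figures.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

BASE = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    out = BASE / "figures"
    out.mkdir(parents=True, exist_ok=True)
    report = json.loads((BASE / "out" / "report.json").read_text())
    spect = pd.read_csv(BASE / "out" / "flows_spect.csv", dtype={"patient_id": str})
    pet = pd.read_csv(BASE / "out" / "flows_pet.csv", dtype={"patient_id": str})

    gs = spect[spect.region == "GLOBAL"].sort_values("patient_id")
    gp = pet[pet.region == "GLOBAL"].sort_values("patient_id")
    x = np.concatenate([gs.rest_mbf, gs.stress_mbf])
    y = np.concatenate([gp.rest_mbf, gp.stress_mbf])
    ag = report["global_mbf_agreement"]

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2, x - y, s=18, alpha=0.7)
    for level, style in ((ag["bias"], "-"), (ag["loa_low"], "--"),
                         (ag["loa_high"], "--")):
        ax.axhline(level, color="k", ls=style, lw=1)
    ax.set_xlabel("mean global MBF (mL/min/g)")
    ax.set_ylabel("SPECT - PET (mL/min/g)")
    ax.set_title("Global MBF agreement, rest + stress")
    fig.tight_layout()
    fig.savefig(out / "bland_altman_mbf.png", dpi=120)

    roc = report["roc_czt_mfr_vs_pet"]
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.plot(roc["fpr"], roc["tpr"], marker="o", ms=3)
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"SPECT MFR vs PET-defined abnormality\n"
                 f"AUC {roc['auc']:.2f}, Youden cutoff {roc['youden_cutoff']:.2f}")
    fig.tight_layout()
    fig.savefig(out / "roc_czt_mfr.png", dpi=120)
    print(f"figures written to {out}")
    print(f"MBF bias {ag['bias']:.3f} mL/min/g; "
          f"SPECT-MFR AUC {roc['auc']:.2f} at cutoff {roc['youden_cutoff']:.2f}")


if __name__ == "__main__":
    main()
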