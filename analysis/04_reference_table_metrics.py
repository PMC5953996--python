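"""Diagnostic rates implied by the study's published 2x2 concordance counts.

Feeds the printed MFR-vs-FFR contingency counts (90 territories; SPECT
index 7/12/5/66, PET index 8/9/4/69) through the metric layer and writes
results/reference_table_metrics.csv.  Also reports Cohen's kappa of those
counts, which differs from the published kappa values — the published
agreement statistic is not reproducible from the printed table alone.
"""

from pathlib import Path

import pandas as pd

from myoflow import ContingencyTable, cohen_kappa, diagnostic_metrics

OUT = Path(__file__).resolve().parents[1] / "results"

TABLES = {
    "SPECT_MFR_lt_2.1": ContingencyTable(tp=7, fp=12, fn=5, tn=66),
    "PET_MFR_lt_2.0": ContingencyTable(tp=8, fp=9, fn=4, tn=69),
}


def main() -> None:
    rows = []
    for name, table in TABLES.items():
        m = diagnostic_metrics(table)
        rows.append(dict(index_test=name, tp=table.tp, fp=table.fp,
                         fn=table.fn, tn=table.tn,
                         discordant=table.discordant,
                         sensitivity_pct=round(m.sensitivity, 1),
                         specificity_pct=round(m.specificity, 1),
                         accuracy_pct=round(m.accuracy, 1),
                         ppv_pct=round(m.ppv, 1), npv_pct=round(m.npv, 1),
                         cohen_kappa=round(cohen_kappa(table), 3)))
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "reference_table_metrics.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
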