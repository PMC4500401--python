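#!/usr/bin/env python
"""Summary tables and figures of the sensitivity experiment.

Reads the per-subject changes written by 03_sensitivity_grid.py and
produces (i) the O2-delay dose-response table (mean LCI change vs delay
step, both directions), (ii) a Bland-Altman plot for the strongest delay
perturbation, and (iii) the direction-summary arrow table printed to the
terminal.  Figures go to results/figures/ as PDFs.
"""
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

BASE = Path(__file__).resolve().parents[1] / "results"
SENS = BASE / "sensitivity"
FIGS = BASE / "figures"


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    per = pd.read_csv(SENS / "per_subject_changes.csv")
    arrows = pd.read_csv(SENS / "arrows.csv")

    dose = per[per["perturbation"].str.startswith("o2_delay_")]
    table = (dose.groupby("perturbation")["pct_lci"]
             .agg(["mean", "std"]).round(2)
             .reindex([f"o2_delay_{s:+.0f}" for s in
                       (-60, -40, -20, 20, 40, 60)]))
    print("O2 delay dose-response (mean +/- SD % LCI change):")
    print(table)
    table.to_csv(FIGS / "o2_delay_dose_response.csv")

    steps = [-60, -40, -20, 20, 40, 60]
    means = [table.loc[f"o2_delay_{s:+.0f}", "mean"] for s in steps]
    sds = [table.loc[f"o2_delay_{s:+.0f}", "std"] for s in steps]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(steps, means, yerr=sds, fmt="o-", capsize=3)
    ax.axhline(0, color="k", lw=0.5)
    ax.axhspan(-10, 10, alpha=0.08, color="grey")
    ax.set_xlabel("O2 delay change (ms)")
    ax.set_ylabel("LCI change (%)")
    ax.set_title("LCI bias vs flow-O2 misalignment")
    fig.tight_layout()
    fig.savefig(FIGS / "o2_delay_dose_response.pdf")

    ba = pd.read_csv(SENS / "bland_altman_o2_delay_-40.csv")
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(ba["mean_lci"], ba["diff_lci"], s=18)
    ax.axhline(ba["diff_lci"].mean(), color="k")
    sd = ba["diff_lci"].std(ddof=1)
    for k in (-1.96, 1.96):
        ax.axhline(ba["diff_lci"].mean() + k * sd, color="k", ls=":")
    ax.set_xlabel("mean LCI (baseline, perturbed)")
    ax.set_ylabel("LCI difference (perturbed - baseline)")
    ax.set_title("O2 delay -40 ms")
    fig.tight_layout()
    fig.savefig(FIGS / "bland_altman_o2_delay_-40.pdf")

    print("\nDirection summary (LCI / FRC / Sacin):")
    print(arrows[["setting", "group", "lci", "frc_mL", "sacin"]]
          .to_string(index=False))
    print(f"\nfigures written to {FIGS}")


if __name__ == "__main__":
    main()
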