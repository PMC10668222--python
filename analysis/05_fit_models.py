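#!/usr/bin/env python
"""Fit the trilateration and boundary-truncation models and compare by BIC.

Reads the cohort written by 04_generate_behavior.py, normalizes responses
into % tool space, runs the accuracy regression, fits both variance-law
models to each participant's variable errors, and tabulates dBIC evidence.
Writes results/cohort_fits.csv and results/evidence_table.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from tooltouch.analysis import fit_accuracy_regression, fit_cohort, normalize_trials, summarize_localization
from tooltouch.behavior import ParticipantParams, StudyDesign, TruncationGenParams
from tooltouch.io import read_trials
from tooltouch.trilateration import TrilaterationParams

OUT = Path(__file__).resolve().parent.parent / "results"


def load_roster(path):
    roster = []
    for r in json.loads(Path(path).read_text()):
        roster.append(
            ParticipantParams(
                participant=r["participant"],
                trilateration=TrilaterationParams(**r["trilateration"]),
                judged_tip_cm=r["judged_tip_cm"],
                pixels_per_cm=r["pixels_per_cm"],
                generative_model=r["generative_model"],
                truncation=TruncationGenParams(**r["truncation"]) if r.get("truncation") else None,
            )
        )
    return roster


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0, help="multistart seed")
    args = ap.parse_args()

    design = StudyDesign()
    trials = read_trials(OUT / "trials.csv")
    roster = load_roster(OUT / "participants.json")
    norm = normalize_trials(trials, roster, design)

    reg = fit_accuracy_regression(summarize_localization(norm))
    print(f"accuracy: slope {reg.slope_mean:.3f} 95% CI [{reg.slope_ci[0]:.3f}, {reg.slope_ci[1]:.3f}], "
          f"intercept {reg.intercept_mean:.2f}% CI [{reg.intercept_ci[0]:.2f}, {reg.intercept_ci[1]:.2f}]")

    tab = fit_cohort(norm, seed=args.seed)
    tab.to_csv(OUT / "cohort_fits.csv", index=False)
    print(f"trilateration fit R2: median {tab['R2_tri'].median():.2f} "
          f"(range {tab['R2_tri'].min():.2f}-{tab['R2_tri'].max():.2f})")
    print(f"truncation fit R2:    median {tab['R2_trunc'].median():.2f}")
    n = len(tab)
    print(f"BIC favors trilateration in {(tab['dBIC'] > 0).sum()}/{n}; "
          f"dBIC>2 in {(tab['dBIC'] > 2).sum()}, dBIC>6 in {(tab['dBIC'] > 6).sum()}")

    evid = tab.groupby(["winner", "evidence"]).size().reset_index(name="n_participants")
    evid.to_csv(OUT / "evidence_table.csv", index=False)
    print(f"wrote {OUT / 'cohort_fits.csv'} and {OUT / 'evidence_table.csv'}")


if __name__ == "__main__":
    main()
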