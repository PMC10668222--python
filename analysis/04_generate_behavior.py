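#!/usr/bin/env python
"""Generate the synthetic behavioral cohort (study design, trilateration law).

38 participants x 2 tasks x 6 locations x 10 trials, with judgment noise
following each participant's trilateration variance law and task-specific
response units (pixels on the 20-cm drawing; cm against the judged tip).
Writes results/trials.csv and results/participants.json.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from tooltouch.behavior import ParticipantPriors, StudyDesign, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--model", choices=["trilateration", "truncation"], default="trilateration")
    args = ap.parse_args()

    OUT.mkdir(exist_ok=True)
    design = StudyDesign()
    df, roster = generate_cohort(design, ParticipantPriors(), seed=args.seed, generative_model=args.model)
    df.to_csv(OUT / "trials.csv", index=False)
    (OUT / "participants.json").write_text(json.dumps([asdict(p) for p in roster], indent=2))

    tips = [p.judged_tip_cm for p in roster]
    print(f"{len(roster)} participants, {len(df)} trials ({args.model} generative law)")
    print(f"judged tip: mean {sum(tips)/len(tips):.1f} cm (true rod length {design.rod_length_cm:.0f} cm)")
    print(f"wrote {OUT / 'trials.csv'} and {OUT / 'participants.json'}")


if __name__ == "__main__":
    main()
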