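"""Simulate the study-design cohort: 22 observers, three conditions each.

19 observers follow the exponential-decay (leaking) weight with k drawn
uniformly from (0.05, 0.95); 3 follow the Ricker (lateral-inhibition) weight
with k = 0.3 s, i.e. repulsion for every distractor in the design.  Each
observer contributes 360 distractors, 360 ensemble and 180 control trials.

Writes results/cohort/trials.csv and results/cohort/truth.csv.
"""

import argparse
import pathlib

from durleak.simulate import study_cohort, write_trials


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=5)
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results/cohort"))
    args = ap.parse_args()

    trials, truth = study_cohort(seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    write_trials(trials, args.out / "trials.csv")
    truth.to_csv(args.out / "truth.csv", index=False)
    print(
        f"simulated {truth.shape[0]} observers "
        f"({(truth.variant == 'leaking').sum()} leaking, "
        f"{(truth.variant == 'ricker').sum()} ricker), "
        f"{len(trials)} trials -> {args.out}"
    )


if __name__ == "__main__":
    main()
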