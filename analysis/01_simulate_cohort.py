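#!/usr/bin/env python
"""Simulate the study-scale diary cohort used by the downstream analyses.

7 patients, 4 calendar weeks each, ~90% hourly compliance, planted
category pleasure effects, a lagged diurnal-adherence effect crossing zero
at JAC = 0.44, and a concave social dose-response peaking at 2 h/day.
Writes results/cohort/diaries.csv and truth.json.
"""

import argparse
from pathlib import Path

from badiary.io import write_diary_csv
from badiary.synthetic import CohortConfig, generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    out = ROOT / "results" / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    diaries, truth = generate_cohort(CohortConfig(), seed=args.seed)
    write_diary_csv(diaries, out / "diaries.csv")
    truth.to_json(out / "truth.json")
    n_entries = sum(d.n_activities for d in diaries)
    print(f"simulated {len(diaries)} patients, {n_entries} hourly activities "
          f"(seed {args.seed}) -> {out / 'diaries.csv'}")


if __name__ == "__main__":
    main()
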