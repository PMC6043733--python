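#!/usr/bin/env python
"""Good/worse-day contrasts: which categories fill the better days?

Median-splits each patient's scored days on daily average pleasure,
weights category hours by distance from the median, and runs the
per-category signed-rank contrast (uncorrected for multiple comparisons).
"""

import importlib
from pathlib import Path

import pandas as pd

from badiary import descriptives, goodworse

ROOT = Path(__file__).resolve().parents[1]
load_diaries = importlib.import_module("02_descriptives").load_diaries  # noqa


def main() -> None:
    diaries = load_diaries()
    rows = []
    for pid, diary in diaries.items():
        table = goodworse.category_goodworse_table(diary)
        if table.skipped:
            print(f"{pid}: skipped ({table.skipped_reason})")
            continue
        summaries = descriptives.daily_summaries(diary)
        for cat, res in table.results.items():
            good, worse = goodworse.weighted_category_hours(
                table.split, summaries, cat
            )
            rows.append(
                {
                    "patient_id": pid,
                    "category": cat.name,
                    "mean_weighted_good": pd.Series(good).mean(),
                    "mean_weighted_worse": pd.Series(worse).mean(),
                    "z": res.z,
                    "p": res.p,
                    "significant": res.significant(),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "goodworse.csv", index=False)
    sig = df[df.significant]
    print(f"{len(sig)} of {len(df)} patient-category contrasts significant "
          "at alpha=.05 (uncorrected):")
    for _, r in sig.iterrows():
        side = "worse" if r.z < 0 else "good"
        print(f"  {r.patient_id} {r.category}: z={r.z:.3f}, p={r.p:.3f} "
              f"(more weighted hours on {side} days)")


if __name__ == "__main__":
    main()
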