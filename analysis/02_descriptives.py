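#!/usr/bin/env python
"""Descriptive layer: compliance, category shares, pleasure by category.

Reads results/cohort/diaries.csv (run 01_simulate_cohort.py first) and
writes the demographics/compliance table, the per-patient and pooled
category distributions, and the pleasure-by-category table.
"""

from pathlib import Path

import pandas as pd

from badiary import descriptives
from badiary.diary import compliance_rate
from badiary.io import parse_diary_table

ROOT = Path(__file__).resolve().parents[1]


def load_diaries():
    path = ROOT / "results" / "cohort" / "diaries.csv"
    if not path.exists():
        raise SystemExit(f"{path} missing; run analysis/01_simulate_cohort.py")
    diaries, report = parse_diary_table(path)
    assert not report.errors, report.errors
    return diaries


def main() -> None:
    diaries = load_diaries()
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    demo = pd.DataFrame(
        [
            {
                "patient_id": pid,
                "days": len(d.reporting_days),
                "activities": d.n_activities,
                "compliance_pct": round(100 * compliance_rate(d)),
            }
            for pid, d in diaries.items()
        ]
    ).set_index("patient_id")
    demo.to_csv(out / "demographics.csv")

    dist = {
        pid: {c.name: v for c, v in
              descriptives.category_distribution(d).rounded().items()}
        for pid, d in diaries.items()
    }
    pooled = descriptives.pooled_category_distribution(diaries.values())
    dist["pooled"] = {c.name: v for c, v in pooled.rounded().items()}
    dist_df = pd.DataFrame.from_dict(dist, orient="index")
    dist_df.to_csv(out / "category_distribution.csv")

    ps = descriptives.ps_by_category(diaries.values())
    ps.to_csv(out / "ps_by_category.csv")

    print("compliance range:",
          f"{demo.compliance_pct.min()}-{demo.compliance_pct.max()}%")
    best = ps["mean"].idxmax()
    print(f"highest-pleasure category: {best} "
          f"(mean {ps.loc[best, 'mean']:.2f}, n={int(ps.loc[best, 'n'])})")
    print(f"pooled shares written to {out / 'category_distribution.csv'}")


if __name__ == "__main__":
    main()
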