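#!/usr/bin/env python
"""Condition comparison with the normality-gated test-selection flow.

Takes the per-cell pre/post densities from 05_shock_density.py (re-deriving
them if the CSV is absent), compares pre vs post with the paired branch of
the decision flow (KS normality → paired t or Wilcoxon), and an unpaired
mock control-vs-treated comparison with Mann–Whitney U.  Box-plot summaries
(median, quartiles, min–max whiskers) accompany each group.

Writes results/group_comparisons.json.
"""

import argparse
import dataclasses
import json
import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import punctakit as pk


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    results = Path("results")
    per_cell = results / "shock_density_per_cell.csv"
    if not per_cell.exists():
        subprocess.run([sys.executable, "analysis/05_shock_density.py",
                        "--seed", str(args.seed)], check=True)
    df = pd.read_csv(per_cell)

    paired = pk.compare_groups(df.pre_dots_per_um2, df.post_dots_per_um2,
                               design="paired")
    print(f"pre vs post (paired, n={len(df)}): {paired.test_used}, "
          f"p = {paired.p_value:.4g} → {paired.significance_code}")

    rng = np.random.default_rng(args.seed)
    control = rng.normal(0.05, 0.01, 12).clip(min=0)
    treated = rng.normal(0.05, 0.01, 12).clip(min=0)
    null = pk.compare_groups(control, treated, design="unpaired")
    print(f"control vs mock-treated (unpaired, null): {null.test_used}, "
          f"p = {null.p_value:.4g} → {null.significance_code}")

    report = {
        "pre_vs_post_paired": paired.to_dict(),
        "null_unpaired": null.to_dict(),
        "box_pre": dataclasses.asdict(pk.box_summary(df.pre_dots_per_um2)),
        "box_post": dataclasses.asdict(pk.box_summary(df.post_dots_per_um2)),
    }
    (results / "group_comparisons.json").write_text(
        json.dumps(report, indent=2, default=str)
    )
    print("wrote results/group_comparisons.json")


if __name__ == "__main__":
    main()
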