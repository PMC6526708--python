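#!/usr/bin/env python
"""Temporal cross-correlation: recovering the programmed recruitment order.

For each programmed inter-channel lag (−2 … +2 frames at 1 s/frame) this
script simulates several fully coupled movies ("cells"), builds dual-channel
ROIs, extracts per-ROI intensity traces from the raw stacks, and aggregates
the per-ROI normalized cross-correlations.  The aggregated profile must peak
at the programmed lag with the field's sign convention: the reference channel
leading gives a peak at positive lag.

Writes results/lag_profiles.csv (one profile per programmed lag) and
results/lag_recovery.csv, plus a figure of the +1 s profile — the analysis
that times one protein's recruitment relative to another.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import punctakit as pk

N_CELLS = 4


def pooled_profile(lag_frames: int, base_seed: int) -> pk.LagCorrelationProfile:
    profiles = []
    for rep in range(N_CELLS):
        p = pk.SimulationParams(seed=base_seed + rep, n_frames=120,
                                field_height_px=160, field_width_px=160,
                                coloc_fraction=1.0, lag_s=float(lag_frames))
        ma, mb, _ = pk.simulate_two_channel_movie(p)
        det_a, det_b = pk.detect_stack(ma), pk.detect_stack(mb)
        roiset = pk.build_rois(det_a.masks, det_b.masks)
        for tr in pk.extract_traces(roiset, ma, mb):
            try:
                profiles.append(pk.temporal_cross_correlation(tr, 10))
            except ValueError:
                continue
    return pk.aggregate_lag_profiles(profiles)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    results = Path("results")
    results.mkdir(exist_ok=True)

    all_rows, recovery = [], []
    plus_one = None
    for lag in (-2, -1, 0, 1, 2):
        prof = pooled_profile(lag, args.seed * 1000 + 100 * (lag + 2))
        df = prof.to_dataframe()
        df.insert(0, "programmed_lag_s", float(lag))
        all_rows.append(df)
        recovery.append({"programmed_lag_s": float(lag),
                         "recovered_peak_lag_s": prof.peak_lag_s,
                         "n_rois": prof.n_rois})
        print(f"programmed {lag:+d} s → recovered peak {prof.peak_lag_s:+.0f} s "
              f"({prof.n_rois} ROIs pooled over {N_CELLS} cells)")
        if lag == 1:
            plus_one = prof
    pd.concat(all_rows).to_csv(results / "lag_profiles.csv", index=False)
    pd.DataFrame(recovery).to_csv(results / "lag_recovery.csv", index=False)
    print("a +1 s peak with the reference channel leading reproduces the "
          "reference-recruited-first signature")

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(plus_one.lags_s, plus_one.mean_r, yerr=plus_one.sem_r,
                fmt="o-", ms=3, lw=1)
    ax.axvline(plus_one.peak_lag_s, ls="--", c="red", lw=0.8)
    ax.set_xlabel("lag (s); positive = reference leads")
    ax.set_ylabel("mean cross-correlation ± s.e.m.")
    ax.set_title(f"programmed +1 s, n = {plus_one.n_rois} ROIs")
    fig.tight_layout()
    fig.savefig(results / "lag_profile_plus1s.png", dpi=150)


if __name__ == "__main__":
    main()
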