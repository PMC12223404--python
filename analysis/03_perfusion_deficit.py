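#!/usr/bin/env python
"""Perfusion-deficit recovery: slope and threshold criteria vs ground truth.

Sweeps true ischemic fractions of 10-40 %LV, noise-free and at SNR 40
(5 seeds each), and reports the error of the nonpositive-slope metric and
of the septal mean-2SD hypo-enhancement metric at the end of ischemia.
Writes results/deficit_recovery.csv.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from memriq.enhancement import septal_reference, threshold_fraction
from memriq.perfusion import deficit_from_slopes, pixel_slope_map, split_windows
from memriq.phantom import PhantomSpec, sector_width_for_fraction, simulate_memri_dynamics


def measure(spec):
    series, truth = simulate_memri_dynamics(spec)
    labels = truth.extras["labels"]
    isch, _ = split_windows(series, 30.0)
    slope_pct = deficit_from_slopes(pixel_slope_map(isch, labels), labels).deficit_pct_lv
    end = isch.frames[-1]
    thr_pct = threshold_fraction(
        end, labels, septal_reference(end, labels), 2.0, "below", "MEMRI"
    ).fraction_pct_lv
    return slope_pct, thr_pct, truth.deficit_fraction_true


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    rows = []
    for target in (10.0, 20.0, 30.0, 40.0):
        spec = PhantomSpec(ischemic_sector_deg=sector_width_for_fraction(target))
        s_nf, t_nf, truth = measure(spec)
        s_noisy, t_noisy = [], []
        for k in range(5):
            nspec = replace(spec, noise_sigma=100.0 / 40.0, seed=args.seed + k)
            s, t, _ = measure(nspec)
            s_noisy.append(s)
            t_noisy.append(t)
        rows.append(
            dict(
                true_pct_lv=truth,
                slope_noise_free=s_nf,
                slope_snr40_mean=float(np.mean(s_noisy)),
                threshold_noise_free=t_nf,
                threshold_snr40_mean=float(np.mean(t_noisy)),
            )
        )
    df = pd.DataFrame(rows)
    df["slope_snr40_err"] = df.slope_snr40_mean - df.true_pct_lv
    df["threshold_snr40_err"] = df.threshold_snr40_mean - df.true_pct_lv
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "deficit_recovery.csv", index=False, float_format="%.6g")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(
        f"\nnoise-free recovery exact: {bool((df.slope_noise_free == df.true_pct_lv).all())}; "
        f"worst SNR-40 slope error {df.slope_snr40_err.abs().max():.2f} points"
    )


if __name__ == "__main__":
    main()
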