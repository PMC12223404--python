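#!/usr/bin/env python
"""Area-at-risk vs scar: the structural overestimation of threshold LGE.

Builds cohorts in which the LGE-enhanced territory strictly contains the
scar-designated subregion (15° margin per side) and shows that (i) the
measured AAR exceeds the scar fraction in every subject and (ii) the
regression of AAR on the MEMRI threshold deficit has a positive offset.
Writes results/aar_structure.csv.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from memriq.enhancement import septal_reference, threshold_fraction
from memriq.perfusion import split_windows
from memriq.phantom import PhantomSpec, sector_width_for_fraction, simulate_lge_volume, simulate_memri_dynamics
from memriq.stats import simple_regression


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cohorts", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    spec0 = PhantomSpec(grid_shape=(60, 56, 6), voxel_size=(28 / 120, 25 / 110, 0.8))
    rng = np.random.default_rng(args.seed)
    rows = []
    seed = args.seed * 1000
    for cohort in range(args.n_cohorts):
        aar_v, memri_v, scar_v = [], [], []
        for _ in range(7):
            frac = rng.uniform(15.0, 40.0)
            scar = sector_width_for_fraction(frac)
            spec = replace(spec0, ischemic_sector_deg=scar, noise_sigma=2.5, seed=seed)
            seed += 1
            vol, truth = simulate_lge_volume(spec, (scar[0] - 15.0, scar[1] + 15.0), 2.0)
            labels = truth.extras["labels"]
            aar_v.append(threshold_fraction(
                vol, labels, septal_reference(vol, labels), 2.0, "above").fraction_pct_lv)
            series, dtruth = simulate_memri_dynamics(spec)
            end = split_windows(series, 30.0)[0].frames[-1]
            memri_v.append(threshold_fraction(
                end, labels, septal_reference(end, labels), 2.0, "below").fraction_pct_lv)
            scar_v.append(dtruth.deficit_fraction_true)
        reg = simple_regression(np.asarray(memri_v), np.asarray(aar_v))
        rows.append(
            dict(
                cohort=cohort,
                aar_mean=float(np.mean(aar_v)),
                scar_mean=float(np.mean(scar_v)),
                n_aar_gt_scar=int((np.asarray(aar_v) > np.asarray(scar_v)).sum()),
                offset_pct_lv=reg.intercept,
                slope=reg.slope,
            )
        )
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "aar_structure.csv", index=False, float_format="%.6g")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(
        f"\nAAR > scar in {df.n_aar_gt_scar.sum()}/{7 * len(df)} subjects; "
        f"positive offset in {(df.offset_pct_lv > 0).sum()}/{len(df)} cohorts "
        f"(mean offset {df.offset_pct_lv.mean():.2f} %LV)"
    )


if __name__ == "__main__":
    main()
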