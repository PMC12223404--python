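#!/usr/bin/env python
"""Generate the synthetic study cohort and its per-subject metrics table.

Cohort: 7 IRI (lateral ischemic sector, true extent drawn uniformly from
15-40 %LV, LGE-enhanced sector 15° wider per side), 6 sham and 3 naive
subjects, imaged at SNR 40.  Writes results/cohort_metrics.csv and the
reproducibility manifest.
"""

import argparse
import json
from pathlib import Path

from memriq import io as mio
from memriq.pipeline import RunConfig, run_synthetic_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = RunConfig(seed=args.seed, snr=40.0)
    df, manifest = run_synthetic_cohort(config)
    args.out.mkdir(parents=True, exist_ok=True)
    mio.save_metrics(df, args.out / "cohort_metrics.csv")
    (args.out / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))

    iri = df[df.group == "IRI"]
    sham = df[df.group == "sham"]
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    print(
        f"\nIRI (n={len(iri)}): slope deficit {iri.deficit_slope_pct_lv.mean():.2f} %LV, "
        f"threshold {iri.deficit_threshold_pct_lv.mean():.2f} %LV, "
        f"AAR {iri.aar_pct_lv.mean():.2f} %LV (true scar {iri.scar_pct_lv.mean():.2f} %LV)"
    )
    print(
        f"EF: IRI {iri.ef_pct.mean():.2f} % vs sham {sham.ef_pct.mean():.2f} %; "
        f"T1: IRI {iri.t1_mean_ms.mean():.0f} ms vs sham {sham.t1_mean_ms.mean():.0f} ms"
    )


if __name__ == "__main__":
    main()
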