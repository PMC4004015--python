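#!/usr/bin/env python
"""Assemble the evaluation datasets: per-sensor column subsets of the phone
table, the watch accelerometer table, and balanced (equal instances per
class) variants of each.

Writes dataset shapes to results/dataset_summary.csv and an ARFF export of
the balanced fused phone set to scratch/ for interoperability checks.
"""

import sys
from pathlib import Path

import pandas as pd

from actifuse import balance_dataset, build_dataset, write_table
from actifuse.dataset import PHONE_SUBSETS, feature_columns

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    rows = []
    for device, subsets in (("phone", PHONE_SUBSETS), ("watch", ("accelerometer",))):
        src = ROOT / "scratch" / f"features_{device}.csv"
        if not src.exists():
            raise SystemExit(f"{src} missing; run 02_extract_features.py first")
        full = pd.read_csv(src)
        for subset in subsets:
            table = build_dataset(full, device, subset)
            balanced = balance_dataset(table, seed=SEED)
            rows.append({
                "device": device, "subset": subset,
                "n_features": len(feature_columns(table)),
                "unbalanced_rows": len(table),
                "balanced_rows": len(balanced),
                "per_class_balanced": balanced["label"].value_counts().iloc[0],
            })
            if device == "phone" and subset == "fused":
                write_table(balanced,
                            ROOT / "scratch" / "phone_fused_balanced.arff",
                            "arff")
    summary = pd.DataFrame(rows)
    summary.to_csv(ROOT / "results" / "dataset_summary.csv", index=False)
    print(summary.to_string(index=False))
    print("\nSubset widths follow the sensor attribution of the feature "
          "schema (accelerometer 21, magnetometer 19, gyro 11, pressure 2, "
          "fused 53; watch accelerometer 17).")


if __name__ == "__main__":
    main()
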