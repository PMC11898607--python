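#!/usr/bin/env python
"""Prepare the colonoscopy-lesion dataset for the real-data analysis.

NOT part of the tested core: this is a documented convenience script that
turns the public UCI "Gastrointestinal Lesions in Regular Colonoscopy"
archive (https://archive.ics.uci.edu/dataset/408/) into the prepared CSV
consumed by the library and the real-data tests
(``data/gastro_prepared.csv``).

The study uses N=76 lesions described by 5 standardized variables selected
upstream from the 698 raw video features -- V113, V173, V475, V489, V603,
where the V-index counts columns of the raw feature table in reading order
(V1 is the first feature column) -- together with the class assessments of
7 clinicians (columns ``ann1..ann7``, 4 experts then 3 novices) and the
ground-truth histology (``truth``), with classes 1=hyperplastic,
2=serrated adenoma, 3=adenoma.

Expected inputs (extracted from the UCI zip):
  * a feature table with one row per recording and the 698 feature columns
    (recordings of the same lesion under white light and NBI are averaged);
  * a label table with one row per lesion: ground truth plus the seven
    clinicians' labels.
Because the archive's internal layout has varied, the script takes both
tables as explicit CSV paths rather than guessing; transpose your export
if lesions are columns. Features are standardized to zero mean and unit
variance over the 76 lesions after averaging.

Usage:
  python scripts/prepare_gastro.py --features features.csv \
      --labels labels.csv --out data/gastro_prepared.csv
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

SELECTED = [113, 173, 475, 489, 603]  # 1-based V-indices into the 698 features


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path, required=True,
                        help="CSV of raw video features, one row per recording")
    parser.add_argument("--labels", type=Path, required=True,
                        help="CSV with columns truth,ann1..ann7, one row per lesion")
    parser.add_argument("--lesion-col", default=None,
                        help="optional column in --features identifying the lesion "
                             "(recordings sharing it are averaged); default: "
                             "consecutive pairs of rows are one lesion")
    parser.add_argument("--out", type=Path, default=Path("data/gastro_prepared.csv"))
    args = parser.parse_args()

    feats = pd.read_csv(args.features)
    labels = pd.read_csv(args.labels)

    if args.lesion_col is not None:
        groups = feats.groupby(args.lesion_col, sort=False)
        feature_block = groups.mean(numeric_only=True)
    else:
        numeric = feats.select_dtypes("number")
        feature_block = numeric.groupby(np.arange(len(numeric)) // 2).mean()

    if feature_block.shape[1] < max(SELECTED):
        raise SystemExit(f"feature table has {feature_block.shape[1]} columns; "
                         f"expected at least {max(SELECTED)} raw features")
    X = feature_block.iloc[:, [i - 1 for i in SELECTED]].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    if len(labels) != len(X):
        raise SystemExit(f"{len(labels)} label rows but {len(X)} lesions "
                         f"after averaging recordings")
    out = pd.DataFrame(X, columns=[f"V{i}" for i in SELECTED])
    for col in ["ann1", "ann2", "ann3", "ann4", "ann5", "ann6", "ann7", "truth"]:
        if col not in labels.columns:
            raise SystemExit(f"label table is missing column {col!r}")
        out[col] = labels[col].to_numpy(dtype=int)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out, index=False)
    print(f"wrote {len(out)} lesions x {len(SELECTED)} features to {args.out}")


if __name__ == "__main__":
    main()
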