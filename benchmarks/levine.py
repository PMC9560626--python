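"""Optional benchmark on the Levine bone-marrow CyTOF reference datasets.

These two hand-gated benchmark datasets (Levine-13: 81,747 BMMC cells x 13
surface markers; Levine-32: 104,184 BMMC cells x 32 markers) are external
downloads and are NOT bundled or fetched here; supply your own copies as
CSV with a ``label`` column holding the expert phenotype assignments.
This script is not part of the test suite.

Usage:
    python benchmarks/levine.py --in levine13.csv --downsample 100000 --seed 0

It fits the full pipeline on the labeled cells and reports the
Hungarian-matched weighted F1 of the predicted clusters against the expert
labels over a sweep of cv-scores.
"""

from __future__ import annotations

import argparse
import sys

import numpy as np


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in", dest="input_path", required=True,
                        help="CSV with marker columns and a 'label' column")
    parser.add_argument("--downsample", type=int, default=100_000)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--cv-scores", default="0.5,0.6,0.7,0.8,0.9")
    args = parser.parse_args()

    from halclust import RunConfig, fit_pipeline, sweep_cv_scores
    from halclust.io import read_matrix
    from halclust.validation import weighted_f1_hungarian

    try:
        ds = read_matrix(args.input_path)
    except FileNotFoundError:
        print(
            f"error: {args.input_path!r} not found.\n"
            "This benchmark needs a user-supplied copy of a Levine reference "
            "dataset (external download); see the module docstring.",
            file=sys.stderr,
        )
        return 2
    if ds.y is None:
        print("error: input has no 'label' column with expert phenotypes",
              file=sys.stderr)
        return 2
    labeled = ds.y >= 0
    X, y = ds.X[labeled], ds.y[labeled]
    print(f"fitting on {X.shape[0]} labeled cells x {X.shape[1]} markers")
    cfg = RunConfig(seed=args.seed, downsample_size=min(args.downsample, X.shape[0]))
    model = fit_pipeline(X, cfg)
    cvs = sorted(float(c) for c in args.cv_scores.split(","))
    res = sweep_cv_scores(model, X, cvs)
    print("cv_score\tn_clusters\tweighted_f1")
    for c in cvs:
        f1 = weighted_f1_hungarian(res.labels[c], y).weighted_f1
        print(f"{c:g}\t{res.cluster_counts[c]}\t{f1:.3f}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
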