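#!/usr/bin/env python
"""Run the full methodology on a user-supplied real omics dataset.

The published real-data summaries (left-censorship tests, outlier lists,
network partitioning ratios on RNA-seq / metabolomics / lipidomics matrices)
require datasets that must be downloaded and normalized separately; nothing
here ships with the package.  Given a normalized abundance matrix (features
in rows, TSV/CSV, zeros or blanks for non-detections) and a sample metadata
table, this script reproduces the same pipeline on that data:

  1. binomial left-censorship test + median-rank profiles per group,
  2. sample-sample correlations under each method and outlier reports,
  3. optionally (with --annotations) feature-feature networks and Q.

Usage:
    python scripts/external_data.py --matrix data.tsv --metadata meta.tsv \
        [--annotations ann.tsv] [--zeros-as-missing] [--out-dir results_real]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--matrix", type=Path,
                    help="abundance matrix TSV/CSV, features in rows")
    ap.add_argument("--metadata", type=Path,
                    help="TSV with sample_id and group columns")
    ap.add_argument("--annotations", type=Path, default=None,
                    help="optional TSV with feature_id and label columns")
    ap.add_argument("--zeros-as-missing", action="store_true")
    ap.add_argument("--methods", nargs="+",
                    default=["IK", "IKC", "Kt", "PB", "PN0", "PL1", "PL"])
    ap.add_argument("--presence-fraction", type=float, default=0.25)
    ap.add_argument("--cores", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results_real"))
    args = ap.parse_args()

    if args.matrix is None or args.metadata is None:
        ap.print_usage(sys.stderr)
        sys.exit("error: --matrix and --metadata are required; this script "
                 "analyses a user-supplied real dataset and ships no data")

    from icitau import (AnnotatedNetwork, correlate_all, filter_by_presence,
                        left_censorship_test, median_group_correlations,
                        median_rank_profile, detect_outliers,
                        partial_correlation, partition_ratio, read_annotations,
                        read_matrix, read_metadata, select_edges)
    from icitau.io import write_table

    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    data = read_matrix(args.matrix, zeros_as_missing=args.zeros_as_missing)
    groups = read_metadata(args.metadata)

    res = left_censorship_test(data, groups)
    write_table(pd.DataFrame([vars(res)]), out / "censorship_test.tsv",
                index=False, float_format="%.6g")
    for gname, prof in median_rank_profile(data, groups).items():
        write_table(prof.by_n_missing, out / f"rank_profile_{gname}.tsv")

    rows = []
    for method in args.methods:
        mats = correlate_all(data, method=method, cores=args.cores)
        med = median_group_correlations(mats, groups)
        report = detect_outliers(med, groups, method=method)
        t = report.samples.copy()
        t.insert(0, "method", method)
        rows.append(t)
        if args.annotations is not None:
            feats = filter_by_presence(data, args.presence_fraction,
                                       groups=groups)
            fmats = correlate_all(feats, method=method, axis="features",
                                  cores=args.cores)
            edges = select_edges(partial_correlation(fmats.tau))
            net = AnnotatedNetwork(edges, read_annotations(args.annotations))
            score = partition_ratio(net)
            write_table(score.per_label, out / f"partition_{method}.tsv",
                        index=False, float_format="%.6g")
            print(f"{method}: Q = {score.Q:.4g} ({len(edges)} edges)")
    write_table(pd.concat(rows), out / "outlier_reports.tsv",
                float_format="%.6g")
    print(f"wrote results to {out}")


if __name__ == "__main__":
    main()
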