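"""Integrate differential binding with differential expression.

Joins the gene/BR pairs with the two differential tables, classifies each
pair, tabulates the four direction quadrants of the dually significant
pairs, computes the concordance chi-square against genome-wide direction
marginals, applies the on/off rule, prepares the clustering matrix, and
writes the result bundle.
"""

import argparse
from pathlib import Path

import pandas as pd

from bindexpr.integrate import (
    concordance_chi2,
    cluster_prep,
    direction_marginal,
    join_pairs,
    onoff_classify,
    quadrant_counts,
    report,
)
from bindexpr.io import read_count_table, read_results, read_sample_sheet


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--fdr", type=float, default=0.05)
    ap.add_argument("--onoff-threshold", type=float, default=5.0)
    args = ap.parse_args()

    diff_b = read_results(args.outdir / "differential_binding.tsv")
    diff_e = read_results(args.outdir / "differential_expression.tsv")
    pairs = pd.read_csv(args.outdir / "gene_br_pairs.tsv", sep="\t")

    pair_table = join_pairs(pairs, diff_b, diff_e, q=args.fdr)
    quad = quadrant_counts(pair_table)
    n_both = sum(quad.values())
    print(f"{len(pair_table)} gene/BR pairs; {n_both} significant in both "
          f"binding and expression at FDR < {args.fdr}")

    concordance = None
    if n_both:
        concordance = concordance_chi2(
            quad, direction_marginal(diff_b), direction_marginal(diff_e)
        )
        print(f"quadrant counts {quad}")
        print(f"concordance chi2 = {concordance.chi2:.2f} (df = 3), "
              f"P = {concordance.p_value:.2e}")

    onoff = onoff_classify(diff_e, threshold=args.onoff_threshold)
    n_a, n_b = int((onoff == "A").sum()), int((onoff == "B").sum())
    print(f"on/off genes (minor-group mean < {args.onoff_threshold:g}): "
          f"{n_a} expressed in group A only, {n_b} in group B only")

    sheet = read_sample_sheet(args.outdir / "data" / "sample_sheet.tsv")
    counts_b = read_count_table(args.outdir / "binding_counts.tsv",
                                sheet.subset("binding"))
    sig = diff_b.loc[diff_b["fdr"] < args.fdr, "feature"]
    cluster = cluster_prep(counts_b.counts.loc[sig]) if len(sig) >= 2 else None

    bundle_dir = args.outdir / "bundle"
    report(
        bundle_dir,
        diff_binding=diff_b,
        diff_expression=diff_e,
        pair_table=pair_table,
        concordance=concordance,
        onoff=onoff,
        cluster_matrix=cluster,
        manifest={"seed": args.seed, "fdr": args.fdr,
                  "onoff_threshold": args.onoff_threshold},
    )
    print(f"result bundle written under {bundle_dir}")


if __name__ == "__main__":
    main()
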