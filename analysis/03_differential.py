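"""Two-group NB differential testing of binding and expression counts.

Reads the BR count table from 02 and the expression counts from 01, runs
median-of-ratios normalization, dispersion estimation and the conditioned
exact test on each, and writes the two differential tables.
"""

import argparse
from pathlib import Path

from bindexpr.differential import run_differential
from bindexpr.io import read_count_table, read_sample_sheet, write_results


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)  # kept for interface parity
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--fdr", type=float, default=0.05)
    args = ap.parse_args()

    sheet = read_sample_sheet(args.outdir / "data" / "sample_sheet.tsv")

    for assay, path in (
        ("binding", args.outdir / "binding_counts.tsv"),
        ("expression", args.outdir / "data" / "expression_counts.tsv"),
    ):
        counts = read_count_table(path, sheet.subset(assay))
        table = run_differential(counts, q=args.fdr)
        sig = table["fdr"] < args.fdr
        a_up = (table["direction"] == "A-up").sum()
        b_up = (table["direction"] == "B-up").sum()
        pct_b = 100 * b_up / max(int(sig.sum()), 1)
        print(f"{assay}: {int(sig.sum())} of {len(table)} features "
              f"differential at FDR < {args.fdr} "
              f"({a_up} group-A up, {b_up} group-B up; {pct_b:.0f}% B-enriched)")
        out = args.outdir / f"differential_{assay}.tsv"
        write_results(table, out)
        print(f"  table written to {out}")


if __name__ == "__main__":
    main()
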