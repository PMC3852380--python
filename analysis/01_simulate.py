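"""Generate the synthetic two-group study dataset.

Writes per-cell-line peak calls (BED), the gene annotation, the sample
sheet, planted binding and expression count tables, the ground-truth ledger
and a synthetic ontology under <outdir>/data/. Fragment-level data are
regenerated deterministically from the seed by downstream steps instead of
being written (they run to millions of intervals).
"""

import argparse
from pathlib import Path

import pandas as pd

from bindexpr.io import write_annotation, write_bed, write_count_table, \
    write_sample_sheet
from bindexpr.simulate import (
    SimulationConfig,
    plan_binding_regions,
    plan_genes,
    simulate_annotation,
    simulate_counts,
    simulate_ontology,
    simulate_peaks,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    data = args.outdir / "data"
    data.mkdir(parents=True, exist_ok=True)

    annotation = simulate_annotation(cfg)
    write_annotation(annotation, data / "annotation.tsv")

    gene_truth = plan_genes(cfg)
    plan = plan_binding_regions(cfg, annotation)
    peaks = simulate_peaks(cfg, plan)
    for line, ivs in peaks.items():
        write_bed([(iv, f"{line}_pk{i}", 0.0) for i, iv in enumerate(ivs)],
                  data / f"peaks_{line}.bed")

    binding, expression, sheet, truth, _ = simulate_counts(cfg, plan, gene_truth)
    write_sample_sheet(sheet, data / "sample_sheet.tsv")
    write_count_table(binding, data / "binding_counts_planted.tsv")
    write_count_table(expression, data / "expression_counts.tsv")
    truth.to_csv(data / "truth.tsv", sep="\t", index=False)

    ontology = simulate_ontology(cfg, gene_truth)
    pd.DataFrame(
        [(t, g) for t, genes in ontology.items() for g in sorted(genes)],
        columns=["term", "gene_id"],
    ).to_csv(data / "ontology.tsv", sep="\t", index=False)

    n_diff_g = int(gene_truth["is_differential"].sum())
    n_diff_b = int(plan["is_differential"].sum())
    print(f"simulated {len(annotation)} genes ({n_diff_g} differential), "
          f"{len(plan)} planted binding regions ({n_diff_b} differential)")
    print("peaks per cell line: " +
          ", ".join(f"{line}={len(v)}" for line, v in peaks.items()))
    print(f"dataset written under {data}")


if __name__ == "__main__":
    main()
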