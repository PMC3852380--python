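"""Region-based binomial ontology enrichment of differential binding regions.

For each ontology term, the null probability that a region hits the term is
the fraction of the genome covered by extended regulatory domains of genes
carrying it; the enrichment p-value is the upper binomial tail of the
observed midpoint hits. Run separately for group-A-up and group-B-up
regions, mirroring the per-subtype enrichment readout.
"""

import argparse
from pathlib import Path

import pandas as pd

from bindexpr.domains import build_domains, enrich
from bindexpr.intervals import BindingRegion
from bindexpr.io import read_annotation, read_bed, read_results
from bindexpr.simulate import SimulationConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--fdr", type=float, default=0.05)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    annotation = read_annotation(args.outdir / "data" / "annotation.tsv")
    domains = build_domains(annotation, chrom_sizes=cfg.chrom_sizes)

    onto = pd.read_csv(args.outdir / "data" / "ontology.tsv", sep="\t")
    ontology = {t: set(g["gene_id"]) for t, g in onto.groupby("term")}

    brs = {
        name: BindingRegion(name, iv, frozenset({"_"}), int(score))
        for iv, name, score in read_bed(args.outdir / "binding_regions.bed")
    }
    diff_b = read_results(args.outdir / "differential_binding.tsv")

    tables = []
    for direction in ("A-up", "B-up"):
        sel = diff_b.loc[diff_b["direction"] == direction, "feature"]
        regions = [brs[f] for f in sel if f in brs]
        table = enrich(regions, domains, ontology, cfg.chrom_sizes)
        table.insert(0, "direction", direction)
        tables.append(table)
        top = table.sort_values("p").iloc[0]
        print(f"{direction}: {len(regions)} regions; top term "
              f"{top['term']} (hits {top['hits']}, P = {top['p']:.2e})")

    out = args.outdir / "enrichment.tsv"
    pd.concat(tables).to_csv(out, sep="\t", index=False, float_format="%.6g")
    print(f"enrichment table written to {out}")


if __name__ == "__main__":
    main()
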