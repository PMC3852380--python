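"""Associate binding regions with genes through regulatory domains.

Builds basal-plus-extension regulatory domains (5 kb up / 1 kb down,
extension to 1 Mb truncated at neighboring basal domains) around every TSS,
pairs each binding region with the genes whose extended domain it overlaps,
and records signed TSS-relative positions of the region midpoints.
"""

import argparse
from collections import Counter
from pathlib import Path

from bindexpr.domains import add_tss_distances, associate, build_domains, \
    domains_to_bed
from bindexpr.intervals import BindingRegion
from bindexpr.io import read_annotation, read_bed, write_bed
from bindexpr.simulate import SimulationConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    annotation = read_annotation(args.outdir / "data" / "annotation.tsv")
    brs = [
        BindingRegion(name, iv, frozenset({"_"} ), int(score))
        for iv, name, score in read_bed(args.outdir / "binding_regions.bed")
    ]

    domains = build_domains(annotation, chrom_sizes=cfg.chrom_sizes)
    write_bed(domains_to_bed(domains), args.outdir / "regulatory_domains.bed")

    pairs = add_tss_distances(associate(brs, domains), brs, annotation)
    pairs.to_csv(args.outdir / "gene_br_pairs.tsv", sep="\t", index=False)

    per_br = Counter(Counter(pairs["br_id"]).values())
    n_orphan = len(brs) - pairs["br_id"].nunique()
    print(f"{len(pairs)} gene/BR pairs from {len(brs)} BRs and "
          f"{len(annotation)} genes")
    print(f"BRs by number of associated genes: "
          + ", ".join(f"{k} gene(s): {v}" for k, v in sorted(per_br.items()))
          + f"; unassociated: {n_orphan}")
    within_1kb = (pairs["tss_distance"].abs() <= 1000).mean()
    print(f"{within_1kb:.0%} of pair midpoints lie within 1 kb of the TSS")


if __name__ == "__main__":
    main()
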