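"""Regulatory-domain gene association (basal-plus-extension) and the
region-based binomial enrichment test.

Each gene receives a basal domain (default 5 kb upstream / 1 kb downstream of
its TSS, strand-aware) extended outward up to a maximum (default 1 Mb) per
side, truncated at the nearest neighboring gene's basal domain and at
chromosome bounds. A binding region is associated with every gene whose
extended domain it overlaps by >= 1 bp. TSS-relative positions are measured
from the BR midpoint with upstream negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .intervals import BindingRegion, GeneModel, GenomicInterval

log = logging.getLogger(__name__)

BASAL_UP = 5_000
BASAL_DOWN = 1_000
MAX_EXTENSION = 1_000_000


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    basal_start: int
    basal_end: int
    ext_start: int
    ext_end: int

    def __post_init__(self) -> None:
        if not (self.ext_start <= self.basal_start < self.basal_end <= self.ext_end):
            raise ValueError(
                f"{self.gene_id}: extended domain must contain the basal domain"
            )


def _basal(gene: GeneModel, basal_up: int, basal_down: int) -> tuple[int, int]:
    t = gene.tss
    if gene.strand == "+":
        return t - basal_up, t + basal_down
    return t - basal_down + 1, t + basal_up + 1


def build_domains(
    annotation: Sequence[GeneModel],
    basal_up: int = BASAL_UP,
    basal_down: int = BASAL_DOWN,
    max_ext: int = MAX_EXTENSION,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains.

    The extension reaches ``max_ext`` bp beyond each basal edge but stops at
    the nearest neighboring basal domain; basal domains themselves may
    overlap. Domains are clamped to ``[0, chrom length)``; with unknown
    chromosome length only the 0 bound applies (warned once).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)

    warned = False
    domains: list[RegulatoryDomain] = []
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: g.tss)
        basal = [_basal(g, basal_up, basal_down) for g in genes]
        if chrom_sizes is not None and chrom in chrom_sizes:
            chrom_len = chrom_sizes[chrom]
        else:
            chrom_len = None
            if chrom_sizes is not None and not warned:
                log.warning("build_domains: unknown length for %s; clamping at 0 only", chrom)
                warned = True
        # running extremes of neighboring basal edges
        n = len(genes)
        prev_end = np.empty(n)   # max basal end among genes before i
        next_start = np.empty(n)  # min basal start among genes after i
        run = -np.inf
        for i in range(n):
            prev_end[i] = run
            run = max(run, basal[i][1])
        run = np.inf
        for i in range(n - 1, -1, -1):
            next_start[i] = run
            run = min(run, basal[i][0])

        for i, g in enumerate(genes):
            b0, b1 = basal[i]
            e0 = max(b0 - max_ext, prev_end[i])
            e1 = min(b1 + max_ext, next_start[i])
            e0 = min(e0, b0)  # extension never shrinks below the basal domain
            e1 = max(e1, b1)
            e0 = max(e0, 0)
            b0c = max(b0, 0)
            if chrom_len is not None:
                e1 = min(e1, chrom_len)
                b1 = min(b1, chrom_len)
            domains.append(
                RegulatoryDomain(
                    gene_id=g.gene_id,
                    chrom=chrom,
                    basal_start=int(b0c),
                    basal_end=int(b1),
                    ext_start=int(e0),
                    ext_end=int(e1),
                )
            )
    log.info("build_domains: %d genes -> %d domains", len(annotation), len(domains))
    return domains


def associate(
    brs: Sequence[BindingRegion], domains: Sequence[RegulatoryDomain]
) -> pd.DataFrame:
    """Pair each BR with every gene whose extended domain it overlaps.

    Returns a DataFrame with columns ``gene_id``, ``br_id``,
    ``tss_distance`` (signed, strand-aware, from the BR midpoint). A BR may
    pair with 0, 1 or many genes.
    """
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.chrom, IntervalTree()).addi(d.ext_start, d.ext_end, d)
    rows = []
    for br in brs:
        tree = trees.get(br.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(br.interval.start, br.interval.end):
            rows.append({"gene_id": hit.data.gene_id, "br_id": br.br_id})
    pairs = pd.DataFrame(rows, columns=["gene_id", "br_id"]).drop_duplicates()
    pairs = pairs.sort_values(["gene_id", "br_id"]).reset_index(drop=True)
    log.info("associate: %d BRs x %d domains -> %d pairs",
             len(brs), len(domains), len(pairs))
    return pairs


def tss_distance(br: BindingRegion, gene: GeneModel) -> int:
    """Signed BR-midpoint-to-TSS distance; negative = upstream of the TSS."""
    d = br.interval.midpoint - gene.tss
    return -d if gene.strand == "-" else d


def add_tss_distances(
    pairs: pd.DataFrame,
    brs: Sequence[BindingRegion],
    annotation: Sequence[GeneModel],
) -> pd.DataFrame:
    br_map = {br.br_id: br for br in brs}
    gene_map = {g.gene_id: g for g in annotation}
    out = pairs.copy()
    out["tss_distance"] = [
        tss_distance(br_map[r.br_id], gene_map[r.gene_id])
        for r in pairs.itertuples()
    ]
    return out


# ---------------------------------------------------------------------------
# Binomial region enrichment
# ---------------------------------------------------------------------------

def binomial_enrichment(
    n_regions: int, hit_count: int, annotated_fraction: float
) -> float:
    """Upper-tail binomial p-value for region hits in annotated domains.

    ``P(X >= hit_count)`` with ``X ~ Binomial(n_regions, annotated_fraction)``
    where the fraction is the share of the genome covered by extended domains
    of genes carrying the term.
    """
    if not 0 <= hit_count <= n_regions:
        raise ValueError("need 0 <= hit_count <= n_regions")
    if not 0.0 <= annotated_fraction <= 1.0:
        raise ValueError("annotated_fraction must lie in [0, 1]")
    if annotated_fraction == 0.0 and hit_count > 0:
        log.warning("binomial_enrichment: zero annotated fraction with hits")
        return 0.0
    if hit_count == 0:
        return 1.0
    return float(stats.binom.sf(hit_count - 1, n_regions, annotated_fraction))


def _union_bp(spans: list[tuple[int, int]]) -> int:
    spans = sorted(spans)
    total, cur_s, cur_e = 0, None, None
    for s, e in spans:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def enrich(
    brs: Sequence[BindingRegion],
    domains: Sequence[RegulatoryDomain],
    ontology: Mapping[str, set],
    genome: Mapping[str, int],
) -> pd.DataFrame:
    """Region-based binomial enrichment over an ontology.

    A region hits a term if its midpoint lies inside the extended domain of
    any gene annotated with the term; the null hit probability is the
    fraction of genome bp covered by those domains.
    """
    genome_bp = sum(genome.values())
    dom_by_gene: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        dom_by_gene.setdefault(d.gene_id, []).append(d)
    mids = [(br.interval.chrom, br.interval.midpoint) for br in brs]

    rows = []
    for term, genes in sorted(ontology.items()):
        spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for gid in genes:
            for d in dom_by_gene.get(gid, []):
                spans_by_chrom.setdefault(d.chrom, []).append(
                    (d.ext_start, d.ext_end)
                )
        covered = sum(_union_bp(v) for v in spans_by_chrom.values())
        frac = covered / genome_bp
        trees = {
            chrom: IntervalTree.from_tuples(spans)
            for chrom, spans in spans_by_chrom.items()
        }
        hits = sum(
            1
            for chrom, mid in mids
            if chrom in trees and trees[chrom].overlaps_point(mid)
        )
        p = binomial_enrichment(len(brs), hits, frac)
        rows.append(
            {
                "term": term,
                "n_regions": len(brs),
                "hits": hits,
                "annotated_fraction": frac,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def domains_to_bed(
    domains: Sequence[RegulatoryDomain],
) -> list[tuple[GenomicInterval, str, float]]:
    return [
        (GenomicInterval(d.chrom, d.ext_start, d.ext_end), d.gene_id, 0.0)
        for d in domains
    ]
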