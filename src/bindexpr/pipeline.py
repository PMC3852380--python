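"""End-to-end orchestration of the synthetic study.

``run_pipeline`` generates a synthetic two-group dataset, rebuilds binding
regions from the per-cell-line peaks, rescores fragments, runs the NB
differential tests on both assays, associates BRs with genes through
regulatory domains, integrates the two axes into the concordance statistic,
and scores recovery of the planted truth. Everything is driven by one seed
and is byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import run_differential
from .domains import add_tss_distances, associate, build_domains, enrich
from .integrate import (
    concordance_chi2,
    cluster_prep,
    direction_marginal,
    join_pairs,
    onoff_classify,
    quadrant_counts,
    report,
)
from .regions import filter_by_support, merge_peaks, rescore_fragments
from .simulate import (
    SimulationConfig,
    plan_binding_regions,
    plan_genes,
    simulate_annotation,
    simulate_counts,
    simulate_fragments,
    simulate_ontology,
    simulate_peaks,
)

log = logging.getLogger(__name__)


def match_planted(brs, plan: pd.DataFrame) -> pd.Series:
    """Map merged BR ids to planted BR ids by >= 1 bp overlap.

    Planted regions keep >= 100 bp clearance and peak jitter is +-20 bp, so
    each merged BR overlaps at most one planted region.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for row in plan.itertuples():
        by_chrom.setdefault(row.chrom, []).append(
            (row.start, row.end, row.planted_id)
        )
    for spans in by_chrom.values():
        spans.sort()
    mapping = {}
    for br in brs:
        spans = by_chrom.get(br.interval.chrom, [])
        starts = np.array([s for s, _, _ in spans])
        ends = np.array([e for _, e, _ in spans])
        lo = np.searchsorted(ends, br.interval.start, side="right")
        hi = np.searchsorted(starts, br.interval.end, side="left")
        if hi > lo:
            mapping[br.br_id] = spans[lo][2]
    return pd.Series(mapping, name="planted_id")


def recovery_metrics(
    diff: pd.DataFrame, truth: pd.DataFrame, id_map: pd.Series | None = None,
    q: float = 0.05,
) -> dict:
    """Sensitivity and realized false-discovery proportion vs planted truth."""
    table = diff.copy()
    if id_map is not None:
        table["truth_id"] = table["feature"].map(id_map)
        table = table[table["truth_id"].notna()]
    else:
        table["truth_id"] = table["feature"]
    t = truth.set_index("feature_id")
    table["true_diff"] = t.loc[table["truth_id"], "is_differential"].to_numpy()
    called = table["fdr"] < q
    n_true = int(table["true_diff"].sum())
    tp = int((called & table["true_diff"]).sum())
    fp = int((called & ~table["true_diff"]).sum())
    return {
        "n_tested": int(len(table)),
        "n_true_differential": n_true,
        "n_called": int(called.sum()),
        "sensitivity": tp / n_true if n_true else float("nan"),
        "false_discovery_proportion": fp / max(tp + fp, 1),
    }


def run_pipeline(
    cfg: SimulationConfig,
    outdir=None,
    q: float = 0.05,
    onoff_threshold: float = 5.0,
    min_lines: int = 2,
) -> dict:
    """Run the full synthetic analysis; return a summary dict.

    If ``outdir`` is given, the result bundle (tables, concordance summary,
    cluster matrix, manifest) is written there.
    """
    # --- simulate
    annotation = simulate_annotation(cfg)
    gene_truth = plan_genes(cfg)
    plan = plan_binding_regions(cfg, annotation)
    peaks = simulate_peaks(cfg, plan)
    binding_planted, expression, sheet, truth, planted_sf = simulate_counts(
        cfg, plan, gene_truth
    )
    fragments = simulate_fragments(cfg, plan, binding_planted)
    ontology = simulate_ontology(cfg, gene_truth)

    # --- binding regions
    brs = merge_peaks(peaks)
    brs = filter_by_support(brs, min_lines=min_lines)
    bind_groups = binding_planted.groups.copy()
    bind_groups.index = binding_planted.libraries
    binding = rescore_fragments(brs, fragments, groups=bind_groups)

    # --- differential testing
    diff_binding = run_differential(binding, q=q)
    diff_expression = run_differential(expression, q=q)

    # --- association
    domains = build_domains(annotation, chrom_sizes=cfg.chrom_sizes)
    pairs = associate(brs, domains)
    pairs = add_tss_distances(pairs, brs, annotation)

    # --- integration
    pair_table = join_pairs(pairs, diff_binding, diff_expression, q=q)
    quad = quadrant_counts(pair_table)
    concordance = None
    if sum(quad.values()) > 0:
        p_bind = direction_marginal(diff_binding)
        p_expr = direction_marginal(diff_expression)
        concordance = concordance_chi2(quad, p_bind, p_expr)

    onoff = onoff_classify(diff_expression, threshold=onoff_threshold)

    sig_bind = diff_binding.loc[diff_binding["fdr"] < q, "feature"]
    cluster_matrix = None
    if len(sig_bind) >= 2:
        cluster_matrix = cluster_prep(binding.counts.loc[sig_bind])

    # --- recovery vs planted truth
    id_map = match_planted(brs, plan)
    rec_bind = recovery_metrics(diff_binding, truth, id_map, q=q)
    rec_expr = recovery_metrics(diff_expression, truth, q=q)

    enrichment = enrich(brs, domains, ontology, cfg.chrom_sizes)

    summary = {
        "n_planted_brs": int(len(plan)),
        "n_merged_brs_prefilter": None,  # filled below for the log
        "n_brs": len(brs),
        "n_genes": int(cfg.n_genes),
        "n_diff_brs": int((diff_binding["fdr"] < q).sum()),
        "n_diff_genes": int((diff_expression["fdr"] < q).sum()),
        "binding_recovery": rec_bind,
        "expression_recovery": rec_expr,
        "enrichment_top_term": (
            enrichment.sort_values("p").iloc[0]["term"] if len(enrichment) else ""
        ),
        "enrichment_top_p": (
            float(enrichment["p"].min()) if len(enrichment) else float("nan")
        ),
    }
    del summary["n_merged_brs_prefilter"]

    if outdir is not None:
        outdir = Path(outdir)
        manifest = {
            "package_version": __version__,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(cfg).items()
            },
            "fdr_threshold": q,
            "onoff_threshold": onoff_threshold,
            "min_lines": min_lines,
        }
        bundle = report(
            outdir,
            diff_binding=diff_binding,
            diff_expression=diff_expression,
            pair_table=pair_table,
            concordance=concordance,
            onoff=onoff,
            cluster_matrix=cluster_matrix,
            manifest=manifest,
        )
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                          float_format="%.6g")
        summary["bundle"] = bundle

    summary["quadrant_counts"] = quad
    if concordance is not None:
        summary["chi2"] = concordance.chi2
        summary["chi2_p"] = concordance.p_value
        summary["p_bind_marginal"] = concordance.p_bind
        summary["p_expr_marginal"] = concordance.p_expr
    summary["n_both_significant"] = int(
        (pair_table["pair_class"] == "both-significant").sum()
    )
    summary["onoff_count_A"] = int((onoff == "A").sum())
    summary["onoff_count_B"] = int((onoff == "B").sum())
    return summary
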