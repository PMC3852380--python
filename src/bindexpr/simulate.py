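"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a two-group cell-line panel (default 4 + 4 lines,
mirroring a GCB-like vs ABC-like lymphoma design): a gene annotation with
strand-aware TSSs, planted transcription-factor binding regions (a share of
them parked inside gene basal domains so binding and expression changes are
linked), per-cell-line peak calls with group-specific occupancy and edge
jitter, and negative-binomial fragment/read counts

    k_ij ~ NB(mean = s_j * q_i * f_i(group_j),  var = mean + alpha_i * mean^2)

with library size factors ``s_j``, baseline concentrations ``q_i`` drawn
log-normally, a mean-linked dispersion ``alpha_i = alpha0 + alpha1 / q_i``,
planted fold changes ``f_i`` for the differential fraction, and "on/off"
genes whose minor-group mean sits below 1 so observed counts are typically
below 5. A truth table records every planted feature for recovery tests.

Randomness comes from a single seed; each stage draws from its own
deterministic sub-stream so outputs are byte-identical across reruns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval
from .io import CountMatrix, SampleSheet

log = logging.getLogger(__name__)

_STAGES = {
    "annotation": 0,
    "gene_plan": 1,
    "br_plan": 2,
    "peaks": 3,
    "counts_binding": 4,
    "counts_expression": 5,
    "fragments": 6,
    "ontology": 7,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults emulate the target study at reduced scale: 8 cell lines in two
    groups of four, one ChIP library per line and two RNA replicates per
    line, ~a third of binding regions and ~7.5% of genes differential, an
    A-skewed direction split (56% / 81% A-up), and half of the A-up
    differential genes silent in group B.
    """

    seed: int = 0
    n_genes: int = 1600
    n_brs: int = 1200
    n_lines_per_group: int = 4
    binding_replicates: int = 1
    expression_replicates: int = 2
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 40_000_000),
        ("chr2", 40_000_000),
        ("chr3", 40_000_000),
        ("chr4", 40_000_000),
    )
    min_gene_spacing: int = 20_000
    # baseline mean q_i ~ LogNormal(meanlog, sdlog)
    baseline_meanlog: float = 5.0
    baseline_sdlog: float = 1.2
    # dispersion alpha_i = alpha0 + alpha1 / q_i
    alpha0: float = 0.05
    alpha1: float = 5.0
    frac_differential_binding: float = 0.34
    frac_differential_expression: float = 0.075
    frac_a_up_binding: float = 0.56
    frac_a_up_expression: float = 0.81
    # planted |log2 fold change| ~ Uniform(lfc_low, lfc_high)
    lfc_low: float = 2.0
    lfc_high: float = 6.0
    frac_onoff: float = 0.5          # of A-up differential genes
    onoff_minor_mean: tuple[float, float] = (0.05, 0.8)
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    # binding-region placement
    frac_linked: float = 0.7          # BRs planted inside a gene basal domain
    frac_linked_to_differential: float = 0.5
    frac_singleton: float = 0.05      # extra BRs emitted in exactly one line
    br_width: tuple[int, int] = (200, 800)
    peak_jitter: int = 20
    occupancy_shared: float = 0.9     # per-line peak probability, non-diff BRs
    occupancy_major: float = 0.95     # up-group, differential BRs
    occupancy_minor: float = 0.5      # down-group, differential BRs
    background_fragments_per_mb: float = 0.0
    fragment_length: int = 200
    n_ontology_terms: int = 12
    ontology_term_size: tuple[int, int] = (20, 120)

    def __post_init__(self) -> None:
        fracs = (
            self.frac_differential_binding, self.frac_differential_expression,
            self.frac_a_up_binding, self.frac_a_up_expression,
            self.frac_onoff, self.frac_linked,
            self.frac_linked_to_differential, self.frac_singleton,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.baseline_meanlog <= 0 or self.alpha0 < 0 or self.alpha1 < 0:
            raise ValueError("means must be positive and dispersions nonnegative")
        if self.size_factor_range[0] <= 0:
            raise ValueError("size factors must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage random stream."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(_STAGES[stage],))
        return np.random.default_rng(ss)

    @property
    def cell_lines(self) -> dict[str, str]:
        lines = {}
        for g in ("A", "B"):
            for i in range(self.n_lines_per_group):
                lines[f"{g}{i + 1}"] = g
        return lines

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.genome)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimulationConfig) -> list[GeneModel]:
    """Non-overlapping genes with TSSs at least ``min_gene_spacing`` apart.

    TSS positions per chromosome are uniform under the spacing constraint
    (order statistics of a uniform draw, shifted by the spacing); gene
    bodies are kept shorter than half the spacing so neighbors never touch.
    """
    if cfg.n_genes == 0:
        return []
    rng = cfg.rng("annotation")
    sizes = np.array([length for _, length in cfg.genome], dtype=float)
    margin = cfg.min_gene_spacing
    # apportion genes by chromosome length (largest remainders)
    share = sizes / sizes.sum() * cfg.n_genes
    per_chrom = np.floor(share).astype(int)
    for i in np.argsort(-(share - per_chrom))[: cfg.n_genes - per_chrom.sum()]:
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    gid = 0
    max_body = max(1_000, cfg.min_gene_spacing // 2 - 100)
    for (chrom, length), n in zip(cfg.genome, per_chrom):
        if n == 0:
            continue
        usable = length - 2 * margin - (n - 1) * cfg.min_gene_spacing
        if usable <= 0:
            raise ValueError(
                f"{chrom}: cannot place {n} genes with spacing "
                f"{cfg.min_gene_spacing} on {length} bp"
            )
        slack = np.sort(rng.integers(0, usable + 1, size=n))
        tss = margin + slack + np.arange(n) * cfg.min_gene_spacing
        strands = rng.choice(["+", "-"], size=n)
        bodies = rng.integers(1_000, max_body + 1, size=n)
        for t, strand, body in zip(tss, strands, bodies):
            gid += 1
            t = int(t)
            body = int(body)
            if strand == "+":
                iv = GenomicInterval(chrom, t, t + body, "+")
            else:
                iv = GenomicInterval(chrom, t - body + 1, t + 1, "-")
            genes.append(GeneModel(f"g{gid:05d}", iv))
    log.info("simulate_annotation: %d genes on %d chromosomes",
             len(genes), len(cfg.genome))
    return genes


# ---------------------------------------------------------------------------
# Binding-region plan (locations, linkage, differential flags)
# ---------------------------------------------------------------------------

def plan_binding_regions(
    cfg: SimulationConfig, annotation: list[GeneModel]
) -> pd.DataFrame:
    """Plant BR locations and their differential structure.

    Linked BRs are placed inside a gene's basal promoter window (between 4 kb
    upstream and 0.8 kb downstream of the TSS, strand-aware) so that
    regulatory-domain association recovers the link; a configurable share of
    links points specifically at differential genes, which is what makes
    binding and expression changes concordant downstream. Planted regions
    keep >= 100 bp of clearance so that peak merging cannot fuse two of them.

    Returns a frame with one row per planted BR: location, linked gene,
    differential flag/direction/log2 fold change, occupancy probability per
    group, and a singleton flag. Gene-level truth must be planted first (see
    :func:`plan_genes`).
    """
    gene_truth = plan_genes(cfg)
    rng = cfg.rng("br_plan")
    genes = {g.gene_id: g for g in annotation}
    gene_ids = np.array([g.gene_id for g in annotation])
    diff_genes = gene_truth.loc[gene_truth["is_differential"], "feature_id"]
    diff_genes = np.array([g for g in diff_genes if g in genes])

    n_linked = int(round(cfg.n_brs * cfg.frac_linked))
    n_single = int(round(cfg.n_brs * cfg.frac_singleton))

    rows = []
    occupied: dict[str, list[tuple[int, int]]] = {}

    def _place(chrom: str, start: int, end: int) -> bool:
        """Reserve [start,end) if it keeps >=100 bp from planted BRs."""
        spans = occupied.setdefault(chrom, [])
        for s, e in spans:
            if start < e + 100 and s < end + 100:
                return False
        spans.append((start, end))
        return True

    widths = rng.integers(cfg.br_width[0], cfg.br_width[1] + 1, size=cfg.n_brs * 4)
    w_iter = iter(widths.tolist())

    # linked BRs in basal promoter windows
    placed = 0
    attempts = 0
    while placed < n_linked and attempts < n_linked * 20:
        attempts += 1
        if len(diff_genes) and rng.random() < cfg.frac_linked_to_differential:
            gid = str(rng.choice(diff_genes))
        else:
            gid = str(rng.choice(gene_ids))
        g = genes[gid]
        w = next(w_iter)
        offset = int(rng.integers(-4_000, 800 - w + 1))
        mid = g.tss + (offset if g.strand == "+" else -offset)
        start, end = mid - w // 2, mid - w // 2 + w
        chrom_len = cfg.chrom_sizes[g.chrom]
        if start < 0 or end > chrom_len:
            continue
        if _place(g.chrom, start, end):
            rows.append({"chrom": g.chrom, "start": start, "end": end,
                         "linked_gene": gid, "singleton": False})
            placed += 1

    # unlinked BRs uniform on the genome
    chroms = [c for c, _ in cfg.genome]
    lens = np.array([length for _, length in cfg.genome], dtype=float)
    probs = lens / lens.sum()
    n_rest = cfg.n_brs - placed + n_single
    placed_rest = 0
    attempts = 0
    while placed_rest < n_rest and attempts < n_rest * 20:
        attempts += 1
        ci = int(rng.choice(len(chroms), p=probs))
        w = next(w_iter)
        start = int(rng.integers(1_000, int(lens[ci]) - w - 1_000))
        if _place(chroms[ci], start, start + w):
            rows.append({"chrom": chroms[ci], "start": start, "end": start + w,
                         "linked_gene": "", "singleton": placed_rest < n_single})
            placed_rest += 1

    plan = pd.DataFrame(rows)
    plan = plan.sort_values(["chrom", "start"]).reset_index(drop=True)
    plan["planted_id"] = [f"pbr{i + 1:05d}" for i in range(len(plan))]

    # differential structure: BRs linked to a differential gene mostly share
    # its direction (that linkage is what makes binding and expression
    # changes concordant); the remaining BRs pick up the residual
    # differential probability so the overall differential fraction matches
    # the configured study-level value
    gt = gene_truth.set_index("feature_id")
    is_diff = np.zeros(len(plan), dtype=bool)
    direction = np.full(len(plan), "", dtype=object)
    lfc = np.zeros(len(plan))
    residual_idx = []
    for i, row in enumerate(plan.itertuples()):
        if row.singleton:
            continue
        linked_diff = row.linked_gene and bool(gt.loc[row.linked_gene, "is_differential"])
        if linked_diff:
            if rng.random() < 0.8:
                is_diff[i] = True
                gene_dir = gt.loc[row.linked_gene, "direction"]
                if rng.random() < 0.85:
                    direction[i] = gene_dir
                else:
                    direction[i] = "B" if gene_dir == "A" else "A"
        else:
            residual_idx.append(i)
    target = cfg.frac_differential_binding * (~plan["singleton"]).sum()
    deficit = max(0.0, target - is_diff.sum())
    p_resid = min(1.0, deficit / len(residual_idx)) if residual_idx else 0.0
    for i in residual_idx:
        if rng.random() < p_resid:
            is_diff[i] = True
            direction[i] = "A" if rng.random() < cfg.frac_a_up_binding else "B"
    for i in np.nonzero(is_diff)[0]:
        lfc[i] = rng.uniform(cfg.lfc_low, cfg.lfc_high)
        if direction[i] == "B":
            lfc[i] = -lfc[i]
    plan["is_differential"] = is_diff
    plan["direction"] = direction
    plan["log2fc"] = lfc
    plan["occ_A"] = np.select(
        [~is_diff, direction == "A"], [cfg.occupancy_shared, cfg.occupancy_major],
        default=cfg.occupancy_minor,
    )
    plan["occ_B"] = np.select(
        [~is_diff, direction == "B"], [cfg.occupancy_shared, cfg.occupancy_major],
        default=cfg.occupancy_minor,
    )
    plan.loc[plan["singleton"], ["occ_A", "occ_B"]] = 0.0
    log.info(
        "plan_binding_regions: %d planted BRs (%d gene-linked, %d singleton, "
        "%d differential)", len(plan), int((plan["linked_gene"] != "").sum()),
        int(plan["singleton"].sum()), int(is_diff.sum()),
    )
    return plan


def plan_genes(cfg: SimulationConfig) -> pd.DataFrame:
    """Gene-level truth: differential flags, directions, fold changes, on/off."""
    rng = cfg.rng("gene_plan")
    n = cfg.n_genes
    ids = [f"g{i + 1:05d}" for i in range(n)]
    is_diff = rng.random(n) < cfg.frac_differential_expression
    a_up = rng.random(n) < cfg.frac_a_up_expression
    direction = np.where(is_diff, np.where(a_up, "A", "B"), "")
    lfc = np.where(
        is_diff,
        rng.uniform(cfg.lfc_low, cfg.lfc_high, size=n) * np.where(a_up, 1, -1),
        0.0,
    )
    onoff = is_diff & (direction == "A") & (rng.random(n) < cfg.frac_onoff)
    return pd.DataFrame(
        {
            "feature_id": ids,
            "kind": "gene",
            "is_differential": is_diff,
            "direction": direction,
            "log2fc": lfc,
            "onoff": onoff,
        }
    )


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    cfg: SimulationConfig, plan: pd.DataFrame
) -> dict[str, list[GenomicInterval]]:
    """Per-cell-line peak sets from the BR plan.

    Every planted BR is emitted, with uniformly jittered edges, in each cell
    line where a Bernoulli occupancy draw succeeds; singletons appear in
    exactly one randomly chosen line.
    """
    rng = cfg.rng("peaks")
    lines = cfg.cell_lines
    peaks: dict[str, list[GenomicInterval]] = {line: [] for line in lines}
    j = cfg.peak_jitter
    for row in plan.itertuples():
        if row.singleton:
            chosen = [list(lines)[int(rng.integers(len(lines)))]]
        else:
            chosen = [
                line
                for line, grp in lines.items()
                if rng.random() < (row.occ_A if grp == "A" else row.occ_B)
            ]
        for line in chosen:
            ds, de = int(rng.integers(-j, j + 1)), int(rng.integers(-j, j + 1))
            start = max(0, row.start + ds)
            end = max(start + 50, row.end + de)
            peaks[line].append(GenomicInterval(row.chrom, start, end))
    for line in peaks:
        peaks[line].sort()
    log.info("simulate_peaks: %s",
             ", ".join(f"{line}={len(p)}" for line, p in peaks.items()))
    return peaks


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, var = mean + alpha mean^2) draws; alpha = 0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = alpha <= 0
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def _library_params(
    cfg: SimulationConfig,
    q: np.ndarray,
    lfc: np.ndarray,
    onoff_minor: np.ndarray | None,
    groups: np.ndarray,
    size_factors: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature, per-library NB means and dispersions.

    ``q`` is the group-B baseline concentration; group A gets
    ``q * 2**lfc``. On/off features override the minor-group mean with a
    sub-unit value. The dispersion follows the mean-linked trend
    ``alpha0 + alpha1 / mean`` evaluated at each group's concentration, so
    the mean-variance relationship is the same for differential and
    non-differential features at any given mean.
    """
    mean_b = q.copy()
    mean_a = q * np.power(2.0, lfc)
    if onoff_minor is not None:
        oo = ~np.isnan(onoff_minor)
        # A-up on/off: group B silent; B-up: group A silent
        a_up = lfc > 0
        mean_b[oo & a_up] = onoff_minor[oo & a_up]
        mean_a[oo & ~a_up] = onoff_minor[oo & ~a_up]
    is_a = groups[None, :] == "A"
    per_group = np.where(is_a, mean_a[:, None], mean_b[:, None])
    alpha_a = cfg.alpha0 + cfg.alpha1 / mean_a
    alpha_b = cfg.alpha0 + cfg.alpha1 / mean_b
    alpha = np.where(is_a, alpha_a[:, None], alpha_b[:, None])
    return per_group * size_factors[None, :], alpha


def simulate_counts(
    cfg: SimulationConfig,
    plan: pd.DataFrame,
    gene_truth: pd.DataFrame,
) -> tuple[CountMatrix, CountMatrix, SampleSheet, pd.DataFrame]:
    """NB count matrices for binding (per planted BR) and expression.

    Returns (binding counts, expression counts, sample sheet, truth table,
    planted size factors by assay). Binding libraries are one ChIP library
    per cell line; expression libraries are ``expression_replicates`` per
    line.
    """
    lines = cfg.cell_lines

    sheet_rows = []
    for rep in range(1, cfg.binding_replicates + 1):
        for line, grp in lines.items():
            lib = f"{line}_chip" if cfg.binding_replicates == 1 else f"{line}_chip_r{rep}"
            sheet_rows.append(
                {"library": lib, "cell_line": line, "group": grp,
                 "assay": "binding", "replicate": rep}
            )
    for rep in range(1, cfg.expression_replicates + 1):
        for line, grp in lines.items():
            sheet_rows.append(
                {"library": f"{line}_rna_r{rep}", "cell_line": line,
                 "group": grp, "assay": "expression", "replicate": rep}
            )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))

    # binding counts
    rng_b = cfg.rng("counts_binding")
    bind_sheet = sheet.subset("binding").table
    sf_b = rng_b.uniform(*cfg.size_factor_range, size=len(bind_sheet))
    q_br = rng_b.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, size=len(plan))
    mean_b, alpha_b = _library_params(
        cfg, q_br, plan["log2fc"].to_numpy(), None,
        bind_sheet["group"].to_numpy(), sf_b,
    )
    k_bind = _nb_draw(rng_b, mean_b, alpha_b)
    binding = CountMatrix(
        pd.DataFrame(k_bind, index=plan["planted_id"].to_numpy(),
                     columns=bind_sheet["library"].to_numpy()),
        bind_sheet.set_index("library")["group"],
    )

    # expression counts
    rng_e = cfg.rng("counts_expression")
    expr_sheet = sheet.subset("expression").table
    sf_e = rng_e.uniform(*cfg.size_factor_range, size=len(expr_sheet))
    n = cfg.n_genes
    q_gene = rng_e.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, size=n)
    onoff_minor = np.full(n, np.nan)
    oo = gene_truth["onoff"].to_numpy()
    onoff_minor[oo] = rng_e.uniform(*cfg.onoff_minor_mean, size=int(oo.sum()))
    mean_e, alpha_e = _library_params(
        cfg, q_gene, gene_truth["log2fc"].to_numpy(), onoff_minor,
        expr_sheet["group"].to_numpy(), sf_e,
    )
    k_expr = _nb_draw(rng_e, mean_e, alpha_e)
    expression = CountMatrix(
        pd.DataFrame(k_expr, index=gene_truth["feature_id"].to_numpy(),
                     columns=expr_sheet["library"].to_numpy()),
        expr_sheet.set_index("library")["group"],
    )

    br_truth = plan[
        ["planted_id", "is_differential", "direction", "log2fc", "linked_gene",
         "singleton", "chrom", "start", "end"]
    ].rename(columns={"planted_id": "feature_id"})
    br_truth.insert(1, "kind", "BR")
    truth = pd.concat(
        [br_truth, gene_truth.assign(linked_gene="", singleton=False)],
        ignore_index=True,
    )
    size_factors = {
        "binding": pd.Series(sf_b, index=bind_sheet["library"].to_numpy()),
        "expression": pd.Series(sf_e, index=expr_sheet["library"].to_numpy()),
    }
    return binding, expression, sheet, truth, size_factors


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def simulate_fragments(
    cfg: SimulationConfig,
    plan: pd.DataFrame,
    binding: CountMatrix,
) -> dict[str, dict[str, np.ndarray]]:
    """Fragment intervals consistent with the planted binding counts.

    For BR *i* and library *j*, exactly ``k_ij`` fragments of
    ``fragment_length`` bp are placed so each overlaps the BR by >= 20 bp;
    optional uniform background fragments can be added per library. Returned
    as library -> chromosome -> (n, 2) start/end arrays (the layout
    ``rescore_fragments`` consumes directly; fragment volumes run into the
    millions, so per-fragment objects are avoided).
    """
    rng = cfg.rng("fragments")
    flen = cfg.fragment_length
    chroms = plan["chrom"].to_numpy()
    lo_all = np.maximum(plan["start"].to_numpy() - flen + 20, 0)
    hi_all = np.maximum(plan["end"].to_numpy() - 20, lo_all + 1)
    out: dict[str, dict[str, np.ndarray]] = {}
    k = binding.counts.to_numpy()
    for j, lib in enumerate(binding.libraries):
        kj = k[:, j]
        rep_lo = np.repeat(lo_all, kj).astype(float)
        rep_span = np.repeat(hi_all - lo_all, kj).astype(float)
        pos = (rep_lo + np.floor(rng.random(len(rep_lo)) * rep_span)).astype(np.int64)
        rep_chrom = np.repeat(chroms, kj)
        by_chrom: dict[str, np.ndarray] = {}
        for chrom in np.unique(chroms):
            sel = rep_chrom == chrom
            p = pos[sel]
            if cfg.background_fragments_per_mb > 0:
                length = cfg.chrom_sizes[chrom]
                nbg = rng.poisson(cfg.background_fragments_per_mb * length / 1e6)
                p = np.concatenate([p, rng.integers(0, length - flen, size=nbg)])
            p = np.sort(p)
            by_chrom[chrom] = np.column_stack([p, p + flen])
        out[lib] = by_chrom
    log.info("simulate_fragments: %s",
             ", ".join(f"{lib}={sum(len(a) for a in v.values())}"
                       for lib, v in out.items()))
    return out


def fragments_to_records(
    fragments: dict[str, np.ndarray],
) -> list[tuple[GenomicInterval, str, float]]:
    """Expand one library's fragment arrays to BED-writable records."""
    return [
        (GenomicInterval(chrom, int(s), int(e)), "", 0.0)
        for chrom, arr in sorted(fragments.items())
        for s, e in arr
    ]


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

def simulate_ontology(
    cfg: SimulationConfig, gene_truth: pd.DataFrame
) -> dict[str, set]:
    """Synthetic term -> gene-set ontology.

    Term 1 is loaded with differential genes (the planted enrichment);
    remaining terms are uniform gene samples of varying size.
    """
    rng = cfg.rng("ontology")
    ids = gene_truth["feature_id"].to_numpy()
    diff = gene_truth.loc[gene_truth["is_differential"], "feature_id"].to_numpy()
    lo, hi = cfg.ontology_term_size
    ontology: dict[str, set] = {}
    if len(diff):
        size = min(len(diff), int(rng.integers(lo, hi + 1)))
        ontology["T01_target"] = set(rng.choice(diff, size=size, replace=False))
    for t in range(2, cfg.n_ontology_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        ontology[f"T{t:02d}"] = set(rng.choice(ids, size=size, replace=False))
    return ontology


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(cfg, seed=seed)
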