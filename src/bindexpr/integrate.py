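"""Integration of differential binding with differential expression.

Gene/BR pairs from regulatory-domain association are joined with the two
differential tables, classified by which axes reach significance, and the
dually significant pairs are tabulated into four direction quadrants. The
quadrant counts are compared with expected counts formed from the product of
externally supplied direction marginals (by default the genome-wide
significant direction proportions of each assay) by a chi-square
goodness-of-fit statistic with 3 degrees of freedom.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, write_results

log = logging.getLogger(__name__)

QUADRANTS = ("A+/A+", "A+/B+", "B+/A+", "B+/B+")  # binding / expression
CLASSES = ("both-significant", "binding-only", "expression-only", "neither")


# ---------------------------------------------------------------------------
# Pair join
# ---------------------------------------------------------------------------

def join_pairs(
    pairs: pd.DataFrame,
    diff_binding: pd.DataFrame,
    diff_expression: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Join gene/BR pairs with both differential tables.

    ``pairs`` needs columns ``gene_id``, ``br_id`` (optionally
    ``tss_distance``). Classes use strict ``fdr < q`` on each axis; the
    quadrant is defined only for both-significant pairs.
    """
    bind = diff_binding.set_index("feature")
    expr = diff_expression.set_index("feature")
    unknown_br = set(pairs["br_id"]) - set(bind.index)
    if unknown_br:
        raise ValueError(f"pairs reference unknown BRs: {sorted(unknown_br)[:5]}")
    unknown_gene = set(pairs["gene_id"]) - set(expr.index)
    if unknown_gene:
        raise ValueError(f"pairs reference unknown genes: {sorted(unknown_gene)[:5]}")

    out = pairs.copy()
    out["binding_fold_change"] = bind.loc[out["br_id"], "fold_change"].to_numpy()
    out["binding_fdr"] = bind.loc[out["br_id"], "fdr"].to_numpy()
    out["binding_direction"] = bind.loc[out["br_id"], "direction"].to_numpy()
    out["expression_fold_change"] = expr.loc[out["gene_id"], "fold_change"].to_numpy()
    out["expression_fdr"] = expr.loc[out["gene_id"], "fdr"].to_numpy()
    out["expression_direction"] = expr.loc[out["gene_id"], "direction"].to_numpy()

    sig_b = out["binding_fdr"] < q
    sig_e = out["expression_fdr"] < q
    pair_class = np.select(
        [sig_b & sig_e, sig_b & ~sig_e, ~sig_b & sig_e],
        ["both-significant", "binding-only", "expression-only"],
        default="neither",
    )
    out["pair_class"] = pair_class

    quad = np.full(len(out), "", dtype=object)
    both = pair_class == "both-significant"
    bd = out["binding_direction"].str[0]  # 'A' or 'B'
    ed = out["expression_direction"].str[0]
    quad[both] = (bd[both] + "+/" + ed[both] + "+").to_numpy()
    out["quadrant"] = quad

    counts = out["pair_class"].value_counts()
    log.info("join_pairs: %d pairs (%s)", len(out),
             ", ".join(f"{c}={int(counts.get(c, 0))}" for c in CLASSES))
    return out


def quadrant_counts(pair_table: pd.DataFrame) -> dict[str, int]:
    both = pair_table[pair_table["pair_class"] == "both-significant"]
    return {qd: int((both["quadrant"] == qd).sum()) for qd in QUADRANTS}


def direction_marginal(diff_table: pd.DataFrame) -> float:
    """Fraction of significant features that are A-up (the binding or
    expression marginal fed to the concordance test)."""
    sig = diff_table[diff_table["direction"] != "none"]
    if len(sig) == 0:
        raise ValueError("no significant features; marginal undefined")
    return float((sig["direction"] == "A-up").mean())


# ---------------------------------------------------------------------------
# Concordance chi-square
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    """Quadrant goodness-of-fit against product marginals (df = 3).

    Expected counts are kept unrounded for the statistic; the display helper
    truncates them to integers, matching the usual tabulation.
    """

    observed: dict[str, int]
    p_bind: float
    p_expr: float
    expected_freq: dict[str, float] = field(init=False)
    expected_counts: dict[str, float] = field(init=False)
    contributions: dict[str, float] = field(init=False)
    chi2: float = field(init=False)
    df: int = 3
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_bind < 1.0 or not 0.0 < self.p_expr < 1.0:
            raise ValueError("marginals must lie strictly inside (0, 1)")
        n = sum(self.observed.values())
        if n <= 0:
            raise ValueError("need at least one observed pair")
        fb = {"A": self.p_bind, "B": 1.0 - self.p_bind}
        fe = {"A": self.p_expr, "B": 1.0 - self.p_expr}
        self.expected_freq = {
            qd: fb[qd[0]] * fe[qd[3]] for qd in QUADRANTS
        }
        self.expected_counts = {qd: n * f for qd, f in self.expected_freq.items()}
        if any(e == 0 for e in self.expected_counts.values()):
            raise ValueError("expected count of zero; chi-square undefined")
        self.contributions = {
            qd: (self.observed.get(qd, 0) - e) ** 2 / e
            for qd, e in self.expected_counts.items()
        }
        self.chi2 = float(sum(self.contributions.values()))
        self.p_value = float(stats.chi2.sf(self.chi2, self.df))

    @property
    def n(self) -> int:
        return sum(self.observed.values())

    def table(self) -> pd.DataFrame:
        """Tabular summary; expected counts also shown truncated to ints."""
        rows = []
        for qd in QUADRANTS:
            e_disp = math.trunc(self.expected_counts[qd])
            o = self.observed.get(qd, 0)
            rows.append(
                {
                    "quadrant": qd,
                    "expected_frequency": self.expected_freq[qd],
                    "expected_count": self.expected_counts[qd],
                    "expected_count_display": e_disp,
                    "observed_count": o,
                    "contribution": self.contributions[qd],
                    # the (o-e)^2/e a reader recomputes from the displayed
                    # integer expected counts
                    "contribution_display": (o - e_disp) ** 2 / e_disp
                    if e_disp > 0
                    else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def concordance_chi2(
    observed: dict[str, int], p_bind: float, p_expr: float
) -> ConcordanceResult:
    """Chi-square concordance of binding and expression directions.

    ``observed`` maps quadrant labels (``'A+/A+'`` etc.) to counts;
    ``p_bind`` / ``p_expr`` are the A-up marginal proportions. Expected
    counts are products of the marginals times the pair total; contributions
    ``(o - e)^2 / e`` use the unrounded expected counts.
    """
    unknown = set(observed) - set(QUADRANTS)
    if unknown:
        raise ValueError(f"unknown quadrant labels: {sorted(unknown)}")
    if any(v < 0 for v in observed.values()):
        raise ValueError("observed counts must be nonnegative")
    return ConcordanceResult(
        observed={qd: int(observed.get(qd, 0)) for qd in QUADRANTS},
        p_bind=p_bind,
        p_expr=p_expr,
    )


# ---------------------------------------------------------------------------
# On/off genes
# ---------------------------------------------------------------------------

def onoff_classify(
    diff_expression: pd.DataFrame, threshold: float = 5.0
) -> pd.Series:
    """Flag significantly differential genes that are effectively silent in
    the minor group (mean normalized count strictly below ``threshold``).

    Returns a Series indexed by feature with values 'A' (expressed in A
    only), 'B', or '' (not on/off).
    """
    flags = pd.Series("", index=diff_expression["feature"], dtype=object)
    a_up = (diff_expression["direction"] == "A-up") & (
        diff_expression["mean_B"] < threshold
    )
    b_up = (diff_expression["direction"] == "B-up") & (
        diff_expression["mean_A"] < threshold
    )
    flags[diff_expression.loc[a_up.to_numpy(), "feature"]] = "A"
    flags[diff_expression.loc[b_up.to_numpy(), "feature"]] = "B"
    log.info("onoff_classify: %d A-only, %d B-only (threshold %g)",
             int((flags == "A").sum()), int((flags == "B").sum()), threshold)
    return flags


# ---------------------------------------------------------------------------
# Clustering preparation
# ---------------------------------------------------------------------------

def cluster_prep(matrix: pd.DataFrame | CountMatrix) -> pd.DataFrame:
    """Transform counts for heatmap clustering.

    1. ``log(x + 1)`` elementwise;
    2. column (library) centering and unit-variance scaling (sample SD);
       zero-SD columns are zero-filled with a warning;
    3. row scaling to unit sum of squares; all-zero rows stay zero.
    """
    df = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("standardization needs >= 2 libraries")
    x = np.log1p(df.to_numpy(dtype=float))
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero_sd = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    if zero_sd.any():
        log.warning("cluster_prep: %d constant columns zero-filled",
                    int(zero_sd.sum()))
    sd_safe = np.where(zero_sd, 1.0, sd)
    x = (x - mu) / sd_safe
    x[:, zero_sd] = 0.0
    ss = np.sqrt((x**2).sum(axis=1))
    ss_safe = np.where(ss > 0, ss, 1.0)
    x = x / ss_safe[:, None]
    return pd.DataFrame(x, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# Result bundle
# ---------------------------------------------------------------------------

def report(
    outdir,
    *,
    diff_binding: pd.DataFrame,
    diff_expression: pd.DataFrame,
    pair_table: pd.DataFrame,
    concordance: ConcordanceResult | None,
    onoff: pd.Series,
    cluster_matrix: pd.DataFrame | None,
    manifest: dict,
) -> dict:
    """Write the deterministic result bundle and return a summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(diff_binding, outdir / "differential_binding.tsv")
    write_results(diff_expression, outdir / "differential_expression.tsv")
    write_results(pair_table, outdir / "pairs.tsv")

    onoff_df = pd.DataFrame(
        {"feature": onoff.index, "onoff_group": onoff.to_numpy()}
    )
    onoff_df[onoff_df["onoff_group"] != ""].to_csv(
        outdir / "onoff_genes.tsv", sep="\t", index=False
    )

    summary: dict = {
        "n_pairs": int(len(pair_table)),
        "class_counts": {
            c: int((pair_table["pair_class"] == c).sum()) for c in CLASSES
        },
        "onoff_counts": {
            "A": int((onoff == "A").sum()),
            "B": int((onoff == "B").sum()),
        },
    }
    if concordance is not None:
        concordance.table().to_csv(outdir / "concordance.tsv", sep="\t", index=False)
        with open(outdir / "concordance.txt", "w") as fh:
            fh.write(
                f"quadrant counts: {concordance.observed}\n"
                f"marginals: p_bind={concordance.p_bind:.4f} "
                f"p_expr={concordance.p_expr:.4f}\n"
                f"chi2 = {concordance.chi2:.2f}, df = {concordance.df}, "
                f"P = {concordance.p_value:.2e}\n"
            )
        summary["quadrant_counts"] = concordance.observed
        summary["chi2"] = concordance.chi2
        summary["chi2_p"] = concordance.p_value
    else:
        log.info("report: no dually significant pairs; chi-square stage skipped")
        (outdir / "concordance.txt").write_text(
            "no dually significant pairs; chi-square stage skipped\n"
        )
    if cluster_matrix is not None:
        cluster_matrix.to_csv(outdir / "cluster_matrix.tsv", sep="\t",
                              index_label="feature", float_format="%.10g")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
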