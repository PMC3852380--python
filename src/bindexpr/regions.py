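"""Binding-region construction from per-cell-line peak sets.

Peaks from all cell lines are pooled and every chain of overlapping or
abutting peaks is collapsed into one binding region (BR). Abutting means
zero gap in half-open coordinates (``end_a == start_b``); a 1-bp gap is not
merged. BRs occupied in fewer than ``min_lines`` distinct cell lines are
discarded before any counting. Fragment rescoring and cross-set overlap both
use the >= 1 bp overlap convention.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import BindingRegion, GenomicInterval
from .io import CountMatrix

log = logging.getLogger(__name__)


def merge_peaks(
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> list[BindingRegion]:
    """Merge per-cell-line peaks into binding regions.

    Parameters
    ----------
    peak_sets : mapping of cell line id -> peak intervals
        Replicate peak lists for a cell line should be unioned by the caller
        before merging; support counts distinct cell lines.

    Returns
    -------
    list of BindingRegion, sorted by (chrom, start), with ids ``BR000001``...
    BRs are pairwise disjoint and non-abutting; every input peak is contained
    in exactly one BR; the BR interval is the union span of its peaks.
    """
    tagged = [
        (iv.chrom, iv.start, iv.end, line)
        for line, peaks in peak_sets.items()
        for iv in peaks
    ]
    n_in = len(tagged)
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))

    regions: list[BindingRegion] = []
    cur = None  # [chrom, start, end, lines, n_peaks]
    for chrom, start, end, line in tagged:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(line)
            cur[4] += 1
        else:
            if cur is not None:
                regions.append(cur)
            cur = [chrom, start, end, {line}, 1]
    if cur is not None:
        regions.append(cur)

    brs = [
        BindingRegion(
            br_id=f"BR{i + 1:06d}",
            interval=GenomicInterval(chrom, start, end),
            support=frozenset(lines),
            n_peaks=n,
        )
        for i, (chrom, start, end, lines, n) in enumerate(regions)
    ]
    log.info("merge_peaks: %d peaks -> %d binding regions", n_in, len(brs))
    return brs


def filter_by_support(
    brs: Sequence[BindingRegion], min_lines: int = 2
) -> list[BindingRegion]:
    """Keep BRs supported by at least ``min_lines`` distinct cell lines."""
    if min_lines < 1:
        raise ValueError(f"min_lines must be >= 1, got {min_lines}")
    kept = [br for br in brs if len(br.support) >= min_lines]
    log.info(
        "filter_by_support(min_lines=%d): kept %d of %d BRs (%d discarded)",
        min_lines, len(kept), len(brs), len(brs) - len(kept),
    )
    return kept


def _br_arrays(brs: Sequence[BindingRegion]) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome sorted (starts, ends, row indices) for disjoint BRs."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, br in enumerate(brs):
        by_chrom.setdefault(br.interval.chrom, []).append(
            (br.interval.start, br.interval.end, i)
        )
    out = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        idx = np.array([t[2] for t in triples], dtype=np.int64)
        out[chrom] = (starts, ends, idx)
    return out


FragmentSet = Mapping[str, np.ndarray]  # chrom -> (n, 2) start/end array


def fragments_by_chrom(
    fragments: Sequence[GenomicInterval] | FragmentSet,
) -> dict[str, np.ndarray]:
    """Normalize a fragment collection to chrom -> (n, 2) int arrays."""
    if isinstance(fragments, Mapping):
        return {c: np.asarray(a, dtype=np.int64) for c, a in fragments.items()}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in fragments:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: np.asarray(spans, dtype=np.int64) for c, spans in by_chrom.items()
    }


def rescore_fragments(
    brs: Sequence[BindingRegion],
    fragment_files: Mapping[str, Sequence[GenomicInterval] | FragmentSet],
    groups: pd.Series | None = None,
) -> CountMatrix:
    """Count, per library, fragments overlapping each BR by >= 1 bp.

    Fragments may be given as ``GenomicInterval`` sequences or already
    bucketed as chrom -> (n, 2) coordinate arrays. BRs are disjoint after
    merging, so a fragment can hit more than one BR only by spanning the gap
    between two; it is then counted in each. Fragments on chromosomes
    without any BR contribute nothing (warned once per chromosome).
    """
    lookup = _br_arrays(brs)
    libraries = list(fragment_files.keys())
    counts = np.zeros((len(brs), len(libraries)), dtype=np.int64)
    warned: set[str] = set()

    for j, lib in enumerate(libraries):
        for chrom, f in fragments_by_chrom(fragment_files[lib]).items():
            if len(f) == 0:
                continue
            if chrom not in lookup:
                if chrom not in warned:
                    log.warning("rescore: no BRs on chromosome %s", chrom)
                    warned.add(chrom)
                continue
            starts, ends, idx = lookup[chrom]
            # BR k overlaps fragment [f0,f1) iff start_k < f1 and end_k > f0.
            lo = np.searchsorted(ends, f[:, 0], side="right")
            hi = np.searchsorted(starts, f[:, 1], side="left")
            counts_j = np.zeros(len(idx), dtype=np.int64)
            single = hi == lo + 1
            np.add.at(counts_j, lo[single], 1)
            # fragments spanning a gap hit 2+ BRs; rare, handled one by one
            for m in np.nonzero(hi > lo + 1)[0]:
                counts_j[lo[m]:hi[m]] += 1
            counts[idx, j] += counts_j

    df = pd.DataFrame(
        counts, index=[br.br_id for br in brs], columns=libraries
    )
    if groups is None:
        groups = pd.Series("A", index=df.columns)
    total = int(df.to_numpy().sum())
    log.info("rescore_fragments: %d BRs x %d libraries, %d assignments",
             len(brs), len(libraries), total)
    return CountMatrix(df, groups)


def overlap_sets(
    brs_a: Sequence[BindingRegion], brs_b: Sequence[BindingRegion]
) -> tuple[int, float]:
    """Count a-regions sharing >= 1 bp with any b-region.

    Returns ``(count, count / len(brs_a))``; an empty ``brs_a`` yields
    fraction 0 with a warning.
    """
    if not brs_a:
        log.warning("overlap_sets: empty query set, fraction reported as 0")
        return 0, 0.0
    lookup = _br_arrays(brs_b)
    count = 0
    for br in brs_a:
        chrom = br.interval.chrom
        if chrom not in lookup:
            continue
        starts, ends, _ = lookup[chrom]
        lo = np.searchsorted(ends, br.interval.start, side="right")
        hi = np.searchsorted(starts, br.interval.end, side="left")
        if hi > lo:
            count += 1
    return count, count / len(brs_a)


def brs_to_bed(brs: Iterable[BindingRegion]) -> list[tuple[GenomicInterval, str, float]]:
    """BR set as BED6 records: name = BR id, score = cell-line support."""
    return [(br.interval, br.br_id, float(len(br.support))) for br in brs]
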