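"""Quantitative page content: allele frequencies, per-exon coverage
aggregation, quality-metric histograms and exon CNV counts.

Coverage aggregation treats bases without a coverage row as zero depth:
absence of data must read as absence of depth, since displaying confidence
in the *absence* of variation is the point of the coverage track.
"""

from __future__ import annotations

import warnings as _warnings
from typing import Any, Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import (
    CNVCall,
    CoverageRow,
    DEFAULT_POPULATIONS,
    GenomeInterval,
    MetricHistogram,
    Variant,
)

#: Default histogram bins: 20 equal bins over [0, 100].
DEFAULT_HIST_EDGES: list[float] = [float(x) for x in range(0, 105, 5)]

#: Default strict lower bound on CNV quality (XHMM SQ).
DEFAULT_CNV_SQ_THRESHOLD = 60.0


def allele_frequency(ac: int, an: int) -> float:
    """AC/AN; 0.0 (with a warning) when AN is zero."""
    if ac < 0:
        raise ValueError("ac must be non-negative")
    if ac > an:
        raise ValueError(f"ac ({ac}) exceeds an ({an})")
    if an == 0:
        _warnings.warn("allele frequency undefined for AN=0; reporting 0.0", UserWarning)
        return 0.0
    return ac / an


def population_table(
    variant: Variant,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
) -> list[dict[str, Any]]:
    """One row per configured population, in fixed order, plus a Total row."""
    rows: list[dict[str, Any]] = []
    for pop in populations:
        counts = variant.pop_counts.get(pop)
        ac = counts.ac if counts else 0
        an = counts.an if counts else 0
        hom = counts.hom if counts else 0
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            af = allele_frequency(ac, an)
        rows.append({"population": pop, "ac": ac, "an": an, "hom": hom, "af": af})
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        total_af = allele_frequency(variant.ac_total, variant.an_total)
    rows.append({
        "population": "Total",
        "ac": variant.ac_total,
        "an": variant.an_total,
        "hom": variant.hom_total,
        "af": total_af,
    })
    return rows


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent (start, end) spans into a sorted disjoint list."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def aggregate_coverage(
    rows: Iterable[CoverageRow],
    intervals: Sequence[GenomeInterval],
    flank: int = 0,
) -> tuple[list[dict[str, Any]], list[CoverageRow]]:
    """Aggregate per-base coverage over exon intervals.

    Returns ``(per_exon_summaries, clipped_series)``.  Each summary holds the
    mean over bases of the per-base mean depth, of the per-base median depth,
    and of each depth-cutoff fraction; a base with no coverage row
    contributes zero to every metric.  The clipped series is the subset of
    input rows falling inside the (flank-extended) intervals, in positional
    order.  The per-exon "median" statistic is a mean of per-base medians; a
    median of medians across bases is not well-defined and the choice is
    recorded in the summary metadata key ``median_statistic``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not intervals:
        return [], []
    chrom = intervals[0].chrom
    spans = merge_intervals(
        (max(0, iv.start - flank), iv.end + flank)
        for iv in intervals
        if iv.chrom == chrom
    )
    by_pos: dict[int, CoverageRow] = {}
    cutoffs: set[int] = set()
    for row in rows:
        if row.chrom != chrom:
            continue
        by_pos[row.pos] = row
        cutoffs.update(row.frac_over)
    cutoff_list = sorted(cutoffs)

    summaries: list[dict[str, Any]] = []
    series: list[CoverageRow] = []
    for s, e in spans:
        n = e - s
        mean_sum = 0.0
        median_sum = 0.0
        frac_sums = {c: 0.0 for c in cutoff_list}
        for pos0 in range(s, e):
            row = by_pos.get(pos0 + 1)  # rows are 1-based
            if row is None:
                continue
            series.append(row)
            mean_sum += row.mean_depth
            median_sum += row.median_depth
            for c in cutoff_list:
                frac_sums[c] += row.frac_over.get(c, 0.0)
        summaries.append({
            "chrom": chrom,
            "start": s,
            "end": e,
            "mean": mean_sum / n,
            "median": median_sum / n,
            "frac_over": {str(c): frac_sums[c] / n for c in cutoff_list},
            "median_statistic": "mean_of_per_base_medians",
        })
    series.sort(key=lambda r: r.pos)
    return summaries, series


def compute_metric_histogram(
    values: Iterable[float],
    bin_edges: Sequence[float] = DEFAULT_HIST_EDGES,
    metric_name: str = "metric",
) -> MetricHistogram:
    """Bin values into ``counts[i] = #{v : edge[i] <= v < edge[i+1]}``.

    Values at or above the last edge fall into the last bin; values below
    the first edge are excluded.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly ascending with >= 2 entries")
    arr = np.asarray(list(values), dtype=float)
    if arr.size:
        arr = arr[arr >= edges[0]]
        arr = np.minimum(arr, edges[-1])  # last-bin rule
        counts, _ = np.histogram(arr, bins=edges)
    else:
        counts = np.zeros(len(edges) - 1, dtype=int)
    hist = MetricHistogram(
        metric_name=metric_name,
        bin_edges=[float(e) for e in edges],
        counts=[int(c) for c in counts],
    )
    hist.validate()
    return hist


def cnv_counts(
    calls: Iterable[CNVCall],
    intervals: Sequence[GenomeInterval],
    sq_threshold: float = DEFAULT_CNV_SQ_THRESHOLD,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
) -> dict[str, Any]:
    """Count confidently-called CNVs (SQ strictly above threshold) per exon.

    A call counts toward every interval it overlaps by at least one base,
    regardless of the amount of overlap.  Returns per-interval DEL/DUP
    counts with per-population breakdowns, plus dataset-wide totals.
    """
    trees: dict[str, IntervalTree] = {}
    per_interval: list[dict[str, Any]] = []
    for idx, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
        per_interval.append({
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "DEL": 0,
            "DUP": 0,
            "by_population": {p: {"DEL": 0, "DUP": 0} for p in populations},
        })
    totals = {
        "DEL": 0,
        "DUP": 0,
        "by_population": {p: {"DEL": 0, "DUP": 0} for p in populations},
    }
    for call in calls:
        if not (call.sq_score > sq_threshold):
            continue
        tree = trees.get(call.chrom)
        if tree is None:
            continue
        hits = tree.overlap(call.start, call.end)
        if not hits:
            continue
        totals[call.kind] += 1
        if call.population in totals["by_population"]:
            totals["by_population"][call.population][call.kind] += 1
        for hit in hits:
            entry = per_interval[hit.data]
            entry[call.kind] += 1
            if call.population in entry["by_population"]:
                entry["by_population"][call.population][call.kind] += 1
    return {
        "sq_threshold": sq_threshold,
        "intervals": per_interval,
        "totals": totals,
    }
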