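"""Lineage-enhancer definition and temporal TF-occupancy classification.

Lineage enhancers are distal H3K27ac peaks (edge-to-TSS distance strictly
greater than 2.5 kb) that significantly gain H3K27ac between two stages
(fold >= 2 at FDR <= 0.05 by default).  They are then classified by when
the classifying pioneer TFs occupy them: class I at both stages, class II
only at the later stage, class III only at the earlier stage; enhancers
bound at neither stage are left out of the catalog.  "Bound by the TFs"
means bound by at least one of them (union rule) unless configured
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, IntervalIndex, RegionSet
from .signal_stats import DiffResult, fisher_exact_2x2

CLASS_LABELS = ("I", "II", "III")


@dataclass
class EnhancerCatalog:
    """Classified enhancers with their occupancy flags and target genes."""

    regions: RegionSet
    table: pd.DataFrame  # index enhancer id; temporal_class, bound flags, ...

    def class_ids(self, label: str) -> list[str]:
        return list(self.table.index[self.table["temporal_class"] == label])

    def class_counts(self) -> dict[str, int]:
        vc = self.table["temporal_class"].value_counts()
        return {label: int(vc.get(label, 0)) for label in CLASS_LABELS}


def _tss_positions(tss: RegionSet) -> dict[str, np.ndarray]:
    per_chrom: dict[str, list[int]] = {}
    for iv in tss:
        pos = iv.summit if iv.summit is not None else iv.start
        per_chrom.setdefault(iv.chrom, []).append(pos)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in per_chrom.items()}


def _min_tss_distance(iv: GenomicInterval, positions: np.ndarray) -> int:
    """Edge-to-point distance from interval to the nearest TSS (same chrom)."""
    k = int(np.searchsorted(positions, iv.start))
    best = np.inf
    for pos in positions[max(0, k - 1) : k + 2]:
        best = min(best, iv.distance_to_point(int(pos)))
    # searchsorted against start misses TSS inside/right of the interval
    k2 = int(np.searchsorted(positions, iv.end))
    for pos in positions[max(0, k2 - 1) : k2 + 2]:
        best = min(best, iv.distance_to_point(int(pos)))
    return int(best) if math.isfinite(best) else -1


def filter_distal(peaks: RegionSet, tss: RegionSet, min_dist: int = 2500) -> RegionSet:
    """Keep peaks strictly farther than ``min_dist`` bp from every TSS.

    Distance is measured from the peak edge to the TSS point; peaks on
    chromosomes without any TSS are kept (vacuously distal).
    """
    if len(tss) == 0:
        raise ValueError("TSS set is empty")
    positions = _tss_positions(tss)
    kept = []
    for iv in peaks:
        pos = positions.get(iv.chrom)
        if pos is None or len(pos) == 0:
            kept.append(iv)
            continue
        if _min_tss_distance(iv, pos) > min_dist:
            kept.append(iv)
    return RegionSet(kept, peaks.chrom_sizes)


def call_lineage_enhancers(
    distal_peaks: RegionSet,
    diff: DiffResult,
    fc: float = 2.0,
    fdr: float = 0.05,
) -> RegionSet:
    """Distal peaks with log2fc >= log2(fc) and padj <= fdr."""
    table = diff.table
    missing = [iv.id for iv in distal_peaks if iv.id not in table.index]
    if missing:
        raise ValueError(
            f"{len(missing)} distal peaks missing from the differential "
            f"result (first: {missing[0]!r})"
        )
    thr = math.log2(fc)
    kept = [
        iv
        for iv in distal_peaks
        if table.at[iv.id, "log2fc"] >= thr and table.at[iv.id, "padj"] <= fdr
    ]
    return RegionSet(kept, distal_peaks.chrom_sizes)


def classify_temporal(
    enhancers: RegionSet,
    tf_peaks_stage1: Mapping[str, RegionSet],
    tf_peaks_stage2: Mapping[str, RegionSet],
    slop: int = 0,
    bound_rule: str = "union",
) -> EnhancerCatalog:
    """Classify enhancers by temporal occupancy of the classifying TFs.

    An enhancer is bound at a stage when >= 1 peak of (any of, or all of,
    per ``bound_rule``) the classifying TFs lies within ``slop`` bp of the
    enhancer interval.  Bound both stages -> I; stage-2 only -> II;
    stage-1 only -> III; neither -> excluded.
    """
    if bound_rule not in ("union", "intersection"):
        raise ValueError(f"unknown bound_rule {bound_rule!r}")
    tfs = sorted(set(tf_peaks_stage1) | set(tf_peaks_stage2))
    indexes = {
        (tf, 1): IntervalIndex(tf_peaks_stage1[tf]) if tf in tf_peaks_stage1 else IntervalIndex([])
        for tf in tfs
    }
    indexes.update(
        {
            (tf, 2): IntervalIndex(tf_peaks_stage2[tf]) if tf in tf_peaks_stage2 else IntervalIndex([])
            for tf in tfs
        }
    )
    rows = []
    kept = []
    for iv in enhancers:
        flags = {
            (tf, stage): indexes[(tf, stage)].overlaps_any(iv, slop=slop)
            for tf in tfs
            for stage in (1, 2)
        }
        agg = all if bound_rule == "intersection" else any
        bound1 = agg(flags[(tf, 1)] for tf in tfs)
        bound2 = agg(flags[(tf, 2)] for tf in tfs)
        if not (bound1 or bound2):
            continue
        label = "I" if (bound1 and bound2) else ("II" if bound2 else "III")
        row = {"enhancer_id": iv.id, "temporal_class": label,
               "bound_stage1": bound1, "bound_stage2": bound2}
        for tf in tfs:
            row[f"{tf}_stage1"] = flags[(tf, 1)]
            row[f"{tf}_stage2"] = flags[(tf, 2)]
        rows.append(row)
        kept.append(iv)
    table = pd.DataFrame(
        rows,
        columns=["enhancer_id", "temporal_class", "bound_stage1", "bound_stage2"]
        + [f"{tf}_stage{s}" for tf in tfs for s in (1, 2)],
    ).set_index("enhancer_id")
    return EnhancerCatalog(RegionSet(kept, enhancers.chrom_sizes), table)


def overlap_fraction(
    class_a: RegionSet,
    class_b: RegionSet,
    features: RegionSet,
    slop: int = 100,
) -> tuple[float, float, float, float]:
    """Per-class fraction of enhancers within ``slop`` bp of >= 1 feature,
    with a two-sided Fisher test on the 2x2 overlap-by-class table.

    Returns (frac_a, frac_b, odds_ratio, p).
    """
    if len(class_a) == 0 or len(class_b) == 0:
        raise ValueError("both classes must be non-empty")
    if len(features) == 0:
        raise ValueError("feature set is empty")
    index = IntervalIndex(features)
    hits_a = sum(index.overlaps_any(iv, slop=slop) for iv in class_a)
    hits_b = sum(index.overlaps_any(iv, slop=slop) for iv in class_b)
    odds, p = fisher_exact_2x2(
        [[hits_a, len(class_a) - hits_a], [hits_b, len(class_b) - hits_b]]
    )
    return hits_a / len(class_a), hits_b / len(class_b), odds, p


def assign_target_genes(
    enhancers: RegionSet,
    genes: RegionSet,
    expression: pd.Series,
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Assign each enhancer its nearest expressed gene (FPKM >= min_fpkm).

    Distance is edge-to-TSS on the same chromosome; exact ties go to the
    lexicographically smaller gene id.  Enhancers on chromosomes without an
    expressed gene get target NA and ``unassigned=True``.
    """
    if expression.empty:
        raise ValueError("expression table is empty")
    expressed: dict[str, list[tuple[int, str]]] = {}
    for iv in genes:
        gid = iv.id
        if gid is None or gid not in expression.index:
            continue
        if expression[gid] >= min_fpkm:
            pos = iv.summit if iv.summit is not None else iv.start
            expressed.setdefault(iv.chrom, []).append((pos, gid))
    per_chrom = {
        c: sorted(entries) for c, entries in expressed.items()
    }
    rows = []
    for iv in enhancers:
        entries = per_chrom.get(iv.chrom, [])
        best_gene = None
        best_dist = None
        if entries:
            positions = np.asarray([e[0] for e in entries], dtype=np.int64)
            k = int(np.searchsorted(positions, iv.start))
            candidates = set(range(max(0, k - 2), min(len(entries), k + 3)))
            k2 = int(np.searchsorted(positions, iv.end))
            candidates |= set(range(max(0, k2 - 2), min(len(entries), k2 + 3)))
            for idx in sorted(candidates):
                pos, gid = entries[idx]
                d = iv.distance_to_point(pos)
                if (
                    best_dist is None
                    or d < best_dist
                    or (d == best_dist and gid < best_gene)
                ):
                    best_dist, best_gene = d, gid
        rows.append(
            {
                "enhancer_id": iv.id,
                "target_gene": best_gene,
                "distance": best_dist if best_dist is not None else -1,
                "unassigned": best_gene is None,
            }
        )
    return pd.DataFrame(rows).set_index("enhancer_id")


def gene_class_composition(
    assignments: pd.DataFrame, catalog: EnhancerCatalog
) -> dict[str, float]:
    """Partition target genes into {only_I, only_II, both} by the classes of
    their assigned enhancers (classes I and II only)."""
    merged = assignments.join(catalog.table[["temporal_class"]], how="inner")
    merged = merged[merged["temporal_class"].isin(["I", "II"]) & ~merged["unassigned"]]
    by_gene = merged.groupby("target_gene")["temporal_class"].agg(set)
    if len(by_gene) == 0:
        return {"only_I": 0.0, "only_II": 0.0, "both": 0.0}
    n = len(by_gene)
    only_i = sum(1 for s in by_gene if s == {"I"})
    only_ii = sum(1 for s in by_gene if s == {"II"})
    both = sum(1 for s in by_gene if s == {"I", "II"})
    return {"only_I": only_i / n, "only_II": only_ii / n, "both": both / n}
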