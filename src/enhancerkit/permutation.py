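"""Random-shuffle null distributions for region-feature overlap enrichment.

Regions are relocated uniformly at random on their own chromosome with
length preserved (BEDTools-shuffle-like, no exclusion list by default); the
overlap statistic is the number of regions overlapping at least one
feature, and the enrichment p-value uses the add-one estimator
p = (r + 1) / (N + 1), which can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import GenomicInterval, RegionSet

DEFAULT_ITERATIONS = 10_000


@dataclass
class PermutationResult:
    observed: int
    null_counts: np.ndarray
    pvalue: float
    zscore: float

    @property
    def null_mean(self) -> float:
        return float(self.null_counts.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_counts.std(ddof=1)) if len(self.null_counts) > 1 else 0.0


def shuffle_regions(
    regions: RegionSet, chrom_sizes: Mapping[str, int], rng: np.random.Generator
) -> RegionSet:
    """Relocate each region uniformly on its own chromosome, preserving
    length and never extending past the chromosome end."""
    shuffled = []
    for iv in regions:
        size = chrom_sizes[iv.chrom]
        length = len(iv)
        if length > size:
            raise ValueError(
                f"region {iv.id} longer than chromosome {iv.chrom}"
            )
        start = int(rng.integers(0, size - length + 1))
        shuffled.append(
            GenomicInterval(iv.chrom, start, start + length, iv.id, iv.strand)
        )
    return RegionSet(shuffled, dict(chrom_sizes))


class _MergedFeatures:
    """Per-chromosome merged features for vectorized overlap counting."""

    def __init__(self, features: RegionSet) -> None:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in features:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for chrom, spans in per_chrom.items():
            spans.sort()
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.asarray(merged, dtype=np.int64)
            self.starts[chrom] = arr[:, 0]
            self.ends[chrom] = arr[:, 1]

    def count_overlapping(self, starts: np.ndarray, ends: np.ndarray, chrom: str) -> int:
        fs = self.starts.get(chrom)
        if fs is None:
            return 0
        fe = self.ends[chrom]
        k = np.searchsorted(fs, ends)
        hit = np.zeros(len(starts), dtype=bool)
        nz = k > 0
        hit[nz] = fe[k[nz] - 1] > starts[nz]
        return int(hit.sum())


def overlap_permutation_test(
    regions: RegionSet,
    features: RegionSet,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    alternative: str = "enrichment",
) -> PermutationResult:
    """Permutation test of region-feature overlap against shuffled nulls.

    The statistic is the number of regions overlapping >= 1 feature; the
    null redistributes regions uniformly per chromosome ``n_iterations``
    times.  ``alternative`` is "enrichment" (default) or "depletion".
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    rng = np.random.default_rng(seed)
    merged = _MergedFeatures(features)

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    observed = 0
    for chrom, ivs in by_chrom.items():
        starts = np.asarray([iv.start for iv in ivs], dtype=np.int64)
        ends = np.asarray([iv.end for iv in ivs], dtype=np.int64)
        observed += merged.count_overlapping(starts, ends, chrom)

    null_counts = np.zeros(n_iterations, dtype=np.int64)
    lengths = {
        chrom: np.asarray([len(iv) for iv in ivs], dtype=np.int64)
        for chrom, ivs in by_chrom.items()
    }
    sizes = {chrom: regions.chrom_sizes[chrom] for chrom in by_chrom}
    for it in range(n_iterations):
        total = 0
        for chrom, ivs in by_chrom.items():
            L = lengths[chrom]
            starts = rng.integers(0, sizes[chrom] - L + 1)
            total += merged.count_overlapping(starts, starts + L, chrom)
        null_counts[it] = total

    if alternative == "enrichment":
        r = int((null_counts >= observed).sum())
    elif alternative == "depletion":
        r = int((null_counts <= observed).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    pvalue = (r + 1) / (n_iterations + 1)
    sd = null_counts.std(ddof=1) if n_iterations > 1 else 0.0
    z = (observed - null_counts.mean()) / sd if sd > 0 else 0.0
    return PermutationResult(
        observed=observed,
        null_counts=null_counts,
        pvalue=float(pvalue),
        zscore=float(z),
    )
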