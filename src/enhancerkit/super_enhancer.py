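"""ROSE-style super-enhancer calling.

Enhancers within a 12.5-kb edge-to-edge gap are stitched into joined
regions, ranked by total normalized H3K27ac signal, and the rank-signal
curve (both axes rescaled to [0, 1]) is cut where a line of slope 1 is
tangent to it — the point minimizing y - x; everything with signal strictly
above that point's signal is a super-enhancer.  A constant signal vector
has no curvature and yields no super-enhancers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, RegionSet

DEFAULT_STITCH_GAP = 12_500


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    members: list[str]
    total_signal: float = 0.0
    rank: int = -1           # 1 = highest signal
    is_super: bool = False


def stitch(enhancers: RegionSet, gap: int = DEFAULT_STITCH_GAP) -> list[StitchedEnhancer]:
    """Single-linkage merge of enhancers whose edge-to-edge gap is <= gap."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in enhancers:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[StitchedEnhancer] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        cur_members = [ivs[0].id]
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
                cur_members.append(iv.id)
            else:
                out.append(
                    StitchedEnhancer(
                        GenomicInterval(chrom, cur_start, cur_end), cur_members
                    )
                )
                cur_start, cur_end, cur_members = iv.start, iv.end, [iv.id]
        out.append(
            StitchedEnhancer(GenomicInterval(chrom, cur_start, cur_end), cur_members)
        )
    return out


def rose_cutoff(
    stitched: Sequence[StitchedEnhancer],
    signal: Mapping[str, float],
) -> tuple[list[StitchedEnhancer], float]:
    """Flag super-enhancers above the slope-1 tangent of the rank curve.

    ``signal`` maps member enhancer id -> normalized signal; each stitched
    region's total is the sum over members.  Regions are sorted ascending by
    total signal; with ranks and signals rescaled to [0, 1] the cutoff is
    the curve point minimizing y - x (ties -> highest rank, i.e. fewest
    supers), and regions with signal strictly above the cutoff signal are
    flagged.  Returns (stitched with totals/ranks/flags filled, cutoff).
    """
    if len(stitched) < 3:
        raise ValueError("need >= 3 stitched regions for a rank curve")
    for se in stitched:
        se.total_signal = float(sum(signal[m] for m in se.members))
        if se.total_signal < 0:
            raise ValueError("signals must be non-negative")
    order = np.argsort([se.total_signal for se in stitched], kind="mergesort")
    totals = np.asarray([stitched[i].total_signal for i in order])
    n = len(totals)
    for rank_from_top, idx in enumerate(order[::-1]):
        stitched[idx].rank = rank_from_top + 1
    if totals[-1] == totals[0]:
        warnings.warn("constant signal vector: no super-enhancers called", stacklevel=2)
        for se in stitched:
            se.is_super = False
        return list(stitched), float(totals[-1])
    x = np.arange(n) / (n - 1)
    y = (totals - totals[0]) / (totals[-1] - totals[0])
    # slope-1 tangent from below = minimizer of y - x; tie -> largest index
    diffs = y - x
    cut_idx = int(n - 1 - np.argmin(diffs[::-1]))
    cutoff = float(totals[cut_idx])
    for se in stitched:
        se.is_super = se.total_signal > cutoff
    return list(stitched), cutoff


def se_composition(
    stitched: Sequence[StitchedEnhancer],
    classes: Mapping[str, str],
) -> dict[str, float]:
    """Fractions of super-enhancers containing only class I, only class II,
    or both, over supers with >= 1 classified member."""
    counts = {"only_I": 0, "only_II": 0, "both": 0}
    total = 0
    for se in stitched:
        if not se.is_super:
            continue
        found = {classes[m] for m in se.members if m in classes}
        found &= {"I", "II"}
        if not found:
            continue
        total += 1
        if found == {"I"}:
            counts["only_I"] += 1
        elif found == {"II"}:
            counts["only_II"] += 1
        else:
            counts["both"] += 1
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: v / total for k, v in counts.items()}


def stitched_to_frame(stitched: Sequence[StitchedEnhancer]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.interval.chrom for s in stitched],
            "start": [s.interval.start for s in stitched],
            "end": [s.interval.end for s in stitched],
            "members": [",".join(str(m) for m in s.members) for s in stitched],
            "total_signal": [s.total_signal for s in stitched],
            "rank": [s.rank for s in stitched],
            "is_super": [s.is_super for s in stitched],
        }
    )
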