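"""PWM scanning with exact p-values, and motif abundance / strength /
position statistics between enhancer classes.

Scores are log-odds in bits, sum_j log2(p_j(base) / background(base)).
P-values are exact under the i.i.d. background model: the score distribution
over random windows is computed by dynamic programming on a discretized
score grid (1e-3 bits), and the p-value of a score is the upper tail of
that distribution.  Both strands are scanned; a minus-strand hit is scored
against the reverse-complement PWM and reported at its leftmost plus-strand
offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PWM, encode_sequence
from .signal_stats import benjamini_hochberg, fisher_exact_2x2, rank_sum_compare

SCORE_PRECISION = 1e-3  # bits
DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_FLANK = 500


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    motif_id: str
    strand: str
    start: int          # leftmost offset on the + strand of the region
    score: float        # bits
    pvalue: float


class _ScoreModel:
    """Discretized log-odds scores and their exact background tail."""

    def __init__(self, pwm: PWM, precision: float = SCORE_PRECISION) -> None:
        self.precision = precision
        self.log_odds = pwm.log_odds
        self.int_scores = np.round(self.log_odds / precision).astype(np.int64)
        self.background = pwm.background
        mins = self.int_scores.min(axis=1)
        spans = self.int_scores.max(axis=1) - mins
        self.min_total = int(mins.sum())
        total_span = int(spans.sum())
        dist = np.zeros(total_span + 1)
        dist[0] = 1.0
        pos = 0
        for j in range(pwm.width):
            col = self.int_scores[j] - mins[j]
            new = np.zeros(pos + spans[j] + 1)
            for base in range(4):
                new[col[base] : col[base] + pos + 1] += (
                    self.background[base] * dist[: pos + 1]
                )
            pos += int(spans[j])
            dist[: pos + 1] = new
        self.dist = dist[: pos + 1]
        # tail[k] = P(int score >= min_total + k)
        self.tail = np.minimum(self.dist[::-1].cumsum()[::-1], 1.0)

    def pvalue(self, int_score: np.ndarray) -> np.ndarray:
        k = np.clip(int_score - self.min_total, 0, len(self.tail) - 1)
        return self.tail[k]


def _scan_one_strand(
    codes: np.ndarray, model: _ScoreModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(offsets, float scores, int scores) of all scorable windows."""
    w = model.log_odds.shape[0]
    L = codes.size
    if L < w:
        return np.empty(0, np.int64), np.empty(0), np.empty(0, np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (windows != 4).all(axis=1)
    offs = np.nonzero(valid)[0]
    if offs.size == 0:
        return offs, np.empty(0), np.empty(0, np.int64)
    win = windows[offs]
    cols = np.arange(w)
    scores = model.log_odds[cols[None, :], win].sum(axis=1)
    int_scores = model.int_scores[cols[None, :], win].sum(axis=1)
    return offs, scores, int_scores


def scan_pwm(
    sequences: Mapping[str, str],
    pwm: PWM,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Scan both strands of every sequence; report hits with p <= threshold.

    Returns a DataFrame (region_id, motif_id, strand, start, score, pvalue)
    ordered by region then offset.  Windows containing N are skipped; a
    sequence shorter than the PWM raises ``ValueError``.
    """
    fwd = _ScoreModel(pwm)
    rev = _ScoreModel(pwm.reverse_complement())
    rows: list[tuple] = []
    for region_id, seq in sequences.items():
        if len(seq) < pwm.width:
            raise ValueError(
                f"sequence {region_id!r} shorter than PWM width {pwm.width}"
            )
        codes = encode_sequence(seq)
        per_region: list[tuple] = []
        for strand, model in (("+", fwd), ("-", rev)):
            offs, scores, ints = _scan_one_strand(codes, model)
            if offs.size == 0:
                continue
            pvals = model.pvalue(ints)
            keep = pvals <= p_threshold
            per_region.extend(
                zip(
                    [region_id] * int(keep.sum()),
                    [pwm.motif_id] * int(keep.sum()),
                    [strand] * int(keep.sum()),
                    offs[keep].tolist(),
                    scores[keep].tolist(),
                    pvals[keep].tolist(),
                )
            )
        per_region.sort(key=lambda r: (r[3], r[2]))
        rows.extend(per_region)
    return pd.DataFrame(
        rows, columns=["region_id", "motif_id", "strand", "start", "score", "pvalue"]
    )


def occurrence_enrichment(
    class_a_seqs: Mapping[str, str],
    class_b_seqs: Mapping[str, str],
    pwms: Sequence[PWM],
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Per motif: percentage of regions in each class with >= 1 occurrence,
    two-sided Fisher test, BH adjustment across motifs."""
    if not class_a_seqs or not class_b_seqs:
        raise ValueError("both classes must be non-empty")
    rows = []
    for pwm in pwms:
        hits_a = scan_pwm(class_a_seqs, pwm, p_threshold)
        hits_b = scan_pwm(class_b_seqs, pwm, p_threshold)
        with_a = hits_a["region_id"].nunique()
        with_b = hits_b["region_id"].nunique()
        na, nb = len(class_a_seqs), len(class_b_seqs)
        odds, p = fisher_exact_2x2([[with_a, na - with_a], [with_b, nb - with_b]])
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "pct_a": 100.0 * with_a / na,
                "pct_b": 100.0 * with_b / nb,
                "odds_ratio": odds,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows).set_index("motif_id")
    out["padj"] = benjamini_hochberg(out["pvalue"].to_numpy())
    return out


def strength_comparison(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Rank-sum comparison of log-odds scores between two hit lists."""
    if len(scores_a) == 0 or len(scores_b) == 0:
        raise ValueError("both hit lists must be non-empty")
    return rank_sum_compare(scores_a, scores_b)


@dataclass
class PositionalProfile:
    """Motif-occurrence probability per offset around summits."""

    offsets: np.ndarray                     # -flank .. +flank
    probability: np.ndarray                 # per-offset fraction of regions
    class_label: str
    n_regions: int
    region_center_offsets: dict[str, np.ndarray]  # region -> hit-center offsets


def positional_profile(
    sequences: Mapping[str, str],
    summit_offsets: Mapping[str, int],
    pwm: PWM,
    flank: int = DEFAULT_FLANK,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    class_label: str = "",
) -> PositionalProfile:
    """Occurrence probability of the motif per offset relative to summits.

    A hit's position is its motif center (start + width//2).  Regions whose
    summit has fewer than ``flank`` bp of sequence on either side are
    dropped with a warning.
    """
    usable: dict[str, str] = {}
    dropped = 0
    for rid, seq in sequences.items():
        s = summit_offsets[rid]
        if s - flank < 0 or s + flank >= len(seq):
            dropped += 1
            continue
        usable[rid] = seq
    if dropped:
        warnings.warn(
            f"{dropped} regions dropped: summit closer than {flank} bp to the "
            "sequence edge",
            stacklevel=2,
        )
    offsets = np.arange(-flank, flank + 1)
    counts = np.zeros(offsets.size)
    centers_by_region: dict[str, np.ndarray] = {}
    hits = scan_pwm(usable, pwm, p_threshold)
    half_w = pwm.width // 2
    for rid, group in hits.groupby("region_id"):
        centers = group["start"].to_numpy() + half_w - summit_offsets[rid]
        centers = centers[(centers >= -flank) & (centers <= flank)]
        centers_by_region[rid] = np.unique(centers)
        counts[centers_by_region[rid] + flank] += 1
    for rid in usable:
        centers_by_region.setdefault(rid, np.empty(0, dtype=np.int64))
    n = len(usable)
    return PositionalProfile(
        offsets=offsets,
        probability=counts / n if n else counts,
        class_label=class_label,
        n_regions=n,
        region_center_offsets=centers_by_region,
    )


def central_enrichment(
    profile_a: PositionalProfile,
    profile_b: PositionalProfile,
    window: int = 100,
) -> tuple[float, float, float]:
    """One-sided Fisher test for central enrichment in class a vs class b.

    A region counts as central when it has >= 1 hit centered within
    +/- window/2 of the summit.  Returns (frac_a, frac_b, p one-sided).
    """
    half = window / 2.0

    def central_count(profile: PositionalProfile) -> int:
        return sum(
            1
            for centers in profile.region_center_offsets.values()
            if centers.size and (np.abs(centers) <= half).any()
        )

    ca, cb = central_count(profile_a), central_count(profile_b)
    na, nb = profile_a.n_regions, profile_b.n_regions
    if na == 0 or nb == 0:
        raise ValueError("both profiles must contain regions")
    _, p = fisher_exact_2x2([[ca, na - ca], [cb, nb - cb]], alternative="greater")
    return ca / na, cb / nb, p
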