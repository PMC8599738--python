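"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates a two-stage differentiation experiment (an early
"GT" stage and a later "PP2" stage): distal H3K27ac peaks that gain signal
upon lineage induction (lineage enhancers), temporal pioneer-TF occupancy
in three classes (I = bound both stages, II = late-only, III = early-only),
super-enhancer clusters with elevated aggregate signal, nearest expressed
target genes, motif instances planted at controlled strength and position
around accessibility summits, TF signal loss under perturbation of a
cooperating lineage TF, and a distance-decay Hi-C contact map with planted
focal loops.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy`` generator per operation, so identical configs give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    BASES,
    ContactMatrix,
    GenomicInterval,
    IntervalIndex,
    PWM,
    RegionSet,
    SignalTable,
    gc_background,
)

STAGES = ("GT", "PP2")
TFS = ("FOXA1", "FOXA2")


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 100_000_000, "chr2": 100_000_000, "chr3": 100_000_000}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic landscape.

    Default class counts mirror a discovered pancreatic landscape
    (561 / 1422 / 118 class I/II/III enhancers, 2574 lineage enhancers in
    total with 167 super-enhancers); counts, effect sizes and noise levels
    are all adjustable.
    """

    seed: int
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    # enhancer landscape
    n_class_i: int = 561
    n_class_ii: int = 1422
    n_class_iii: int = 118
    n_unbound: int = 473          # lineage enhancers never bound by the TFs
    n_inactive: int = 5000        # distal peaks with stable H3K27ac
    n_proximal: int = 200         # TSS-proximal H3K27ac peaks
    n_shared_gene_pairs: int = 100  # class I + class II enhancer flanking one gene
    n_se_clusters: int = 167
    se_cluster_size: int = 3
    se_signal_fold: float = 10.0
    enhancer_width: int = 600
    tf_peak_width: int = 200
    n_extra_tf_peaks: int = 500   # TF peaks away from any enhancer
    # count model
    n_replicates: int = 2
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05
    gain_log2fc: float = 2.0      # H3K27ac gain of lineage enhancers
    # expression
    expressed_fraction: float = 0.85
    # perturbation (knockdown of a cooperating lineage TF)
    loss_fraction_class_i: float = 0.03
    loss_fraction_class_ii: float = 0.23
    loss_log2fc: float = -2.0
    # Hi-C
    hic_resolution: int = 10_000
    hic_n_bins: int = 300
    hic_alpha: float = 1.0
    hic_diag_scale: float = 200.0
    hic_n_loops: int = 10
    hic_loop_fold: float = 5.0
    hic_loop_min_dist: int = 5
    hic_loop_max_dist: int = 30
    hic_loop_separation: int = 12

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "n_class_i", "n_class_ii", "n_class_iii", "n_unbound",
            "n_inactive", "n_proximal", "n_shared_gene_pairs", "n_se_clusters",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.hic_alpha <= 0:
            raise ValueError("hic_alpha must be > 0")
        if self.hic_loop_min_dist < 1:
            raise ValueError("loops must be off-diagonal (min distance >= 1 bin)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedLandscape:
    """Everything :func:`simulate_landscape` plants, plus the truth table."""

    enhancers: RegionSet            # all distal H3K27ac peaks (incl. inactive)
    proximal_peaks: RegionSet
    tf_peaks: dict[tuple[str, str], RegionSet]  # (tf, stage) -> peaks
    h3k27ac: SignalTable
    tss: RegionSet                  # 1-bp TSS intervals, id = gene id
    expression: pd.Series           # FPKM per gene id
    truth: pd.DataFrame             # indexed by enhancer id
    chrom_sizes: dict[str, int]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mu + phi*mu^2 (r = 1/phi)."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    return rng.negative_binomial(r, r / (r + mean))


def simulate_landscape(config: SimulationConfig) -> SimulatedLandscape:
    """Plant a two-stage enhancer landscape with exact class counts.

    Enhancers are laid out left to right along the configured chromosomes
    with gaps wide enough that isolated enhancers never stitch together and
    every planted target gene is its enhancer's nearest gene; raising the
    counts beyond what the chromosomes can hold raises ``ValueError``.
    """
    rng = np.random.default_rng(config.seed)
    width = config.enhancer_width

    # --- build the unit list (shuffled so classes interleave) -------------
    quotas = {
        "I": config.n_class_i,
        "II": config.n_class_ii,
        "III": config.n_class_iii,
        "unbound": config.n_unbound,
    }
    units: list[dict] = []
    # super-enhancer clusters: 38% only-I, 38% only-II, 24% mixed
    for k in range(config.n_se_clusters):
        u = rng.random()
        if u < 0.38:
            wanted = ["I"] * config.se_cluster_size
        elif u < 0.76:
            wanted = ["II"] * config.se_cluster_size
        else:
            wanted = ["I", "II"] * config.se_cluster_size
            wanted = wanted[: config.se_cluster_size]
        classes = []
        for c in wanted:
            if quotas[c] == 0:
                c = max(("I", "II"), key=lambda x: quotas[x])
            if quotas[c] == 0:
                raise ValueError("class quotas too small for the requested clusters")
            quotas[c] -= 1
            classes.append(c)
        units.append({"kind": "cluster", "classes": classes, "cluster_id": f"SE{k:04d}"})
    for k in range(config.n_shared_gene_pairs):
        if quotas["I"] == 0 or quotas["II"] == 0:
            raise ValueError("class quotas too small for shared-gene pairs")
        quotas["I"] -= 1
        quotas["II"] -= 1
        units.append({"kind": "pair", "classes": ["I", "II"]})
    for cls, left in quotas.items():
        units.extend({"kind": "single", "classes": [cls]} for _ in range(left))
    units.extend({"kind": "inactive", "classes": ["inactive"]} for _ in range(config.n_inactive))
    units.extend({"kind": "proximal", "classes": []} for _ in range(config.n_proximal))
    rng.shuffle(units)

    # --- place units along the chromosomes -------------------------------
    chroms = list(config.chrom_sizes)
    chrom_idx = 0
    cursor = 50_000  # margin so flanking windows never clip chromosome start
    enh_records: list[dict] = []
    prox_intervals: list[GenomicInterval] = []
    tss_intervals: list[GenomicInterval] = []
    gene_fpkm: dict[str, float] = {}
    n_enh = 0
    n_gene = 0

    def new_gene(expressed_bias: float | None = None) -> str:
        nonlocal n_gene
        gid = f"G{n_gene:05d}"
        n_gene += 1
        p_expr = config.expressed_fraction if expressed_bias is None else expressed_bias
        if rng.random() < p_expr:
            gene_fpkm[gid] = float(np.round(10.0 ** rng.normal(1.0, 0.5), 3)) + 1.0
        else:
            gene_fpkm[gid] = float(np.round(rng.uniform(0.0, 0.9), 3))
        return gid

    def place(length_needed: int) -> int:
        """Return a start coordinate with room for `length_needed` bp."""
        nonlocal chrom_idx, cursor
        while True:
            if chrom_idx >= len(chroms):
                raise ValueError(
                    "infeasible placement: chromosomes too small for the "
                    "requested number of regions"
                )
            if cursor + length_needed <= config.chrom_sizes[chroms[chrom_idx]]:
                return cursor
            chrom_idx += 1
            cursor = 50_000

    def add_enhancer(chrom: str, start: int, cls: str, cluster_id: str, gene: str | None) -> str:
        nonlocal n_enh
        eid = f"E{n_enh:05d}"
        n_enh += 1
        summit = start + width // 2
        enh_records.append(
            {
                "enhancer_id": eid,
                "chrom": chrom,
                "start": start,
                "end": start + width,
                "summit": summit,
                "true_class": cls,
                "cluster_id": cluster_id,
                "gene": gene,
            }
        )
        return eid

    # geometry: a unit's own TSS is always strictly nearer to its enhancers
    # than any neighboring unit's TSS (own <= 32 kb, neighbors >= 35 kb)
    GENE_UNIT_GAP = (35_000, 45_000)
    for unit in units:
        kind = unit["kind"]
        if kind == "single":
            need = width + 16_000
            start = place(need)
            chrom = chroms[chrom_idx]
            gid = new_gene()
            add_enhancer(chrom, start, unit["classes"][0], "", gid)
            tss_pos = start + width + int(rng.integers(5_000, 15_000))
            tss_intervals.append(GenomicInterval(chrom, tss_pos, tss_pos + 1, gid))
            cursor = start + need + int(rng.integers(*GENE_UNIT_GAP))
        elif kind == "cluster":
            gaps = rng.integers(3_000, 10_000, size=len(unit["classes"]) - 1)
            span = width * len(unit["classes"]) + int(gaps.sum())
            need = span + 11_000
            start = place(need)
            chrom = chroms[chrom_idx]
            gid = new_gene(expressed_bias=0.95)
            pos = start
            for i, cls in enumerate(unit["classes"]):
                add_enhancer(chrom, pos, cls, unit["cluster_id"], gid)
                pos += width + (int(gaps[i]) if i < len(gaps) else 0)
            tss_pos = start + span + int(rng.integers(5_000, 10_000))
            tss_intervals.append(GenomicInterval(chrom, tss_pos, tss_pos + 1, gid))
            cursor = start + need + int(rng.integers(*GENE_UNIT_GAP))
        elif kind == "pair":
            # class I enhancer ... gene ... class II enhancer, one shared gene
            d1 = int(rng.integers(8_000, 12_000))
            d2 = int(rng.integers(5_000, 10_000))
            need = width * 2 + d1 + d2 + 1_000
            start = place(need)
            chrom = chroms[chrom_idx]
            gid = new_gene(expressed_bias=1.0)
            add_enhancer(chrom, start, "I", "", gid)
            tss_pos = start + width + d1
            tss_intervals.append(GenomicInterval(chrom, tss_pos, tss_pos + 1, gid))
            add_enhancer(chrom, tss_pos + d2, "II", "", gid)
            cursor = start + need + int(rng.integers(*GENE_UNIT_GAP))
        elif kind == "inactive":
            need = width
            start = place(need)
            chrom = chroms[chrom_idx]
            add_enhancer(chrom, start, "inactive", "", None)
            cursor = start + need + int(rng.integers(5_000, 10_000))
        else:  # proximal peak right next to its own gene's TSS
            need = width + 2_500
            start = place(need)
            chrom = chroms[chrom_idx]
            gid = new_gene()
            prox_id = f"P{len(prox_intervals):05d}"
            prox_intervals.append(
                GenomicInterval(chrom, start, start + width, prox_id)
            )
            tss_pos = start + width + int(rng.integers(0, 2_000))
            tss_intervals.append(GenomicInterval(chrom, tss_pos, tss_pos + 1, gid))
            # proximal units carry a TSS too, so keep the large gap
            cursor = start + need + int(rng.integers(*GENE_UNIT_GAP))

    truth = pd.DataFrame(enh_records).set_index("enhancer_id")

    # --- temporal TF occupancy -------------------------------------------
    bound = {
        "I": (True, True),
        "II": (False, True),
        "III": (True, False),
        "unbound": (False, False),
        "inactive": (False, False),
    }
    for tf in TFS:
        for stage in STAGES:
            truth[f"{tf}_{stage}"] = False
    tf_intervals: dict[tuple[str, str], list[GenomicInterval]] = {
        (tf, stage): [] for tf in TFS for stage in STAGES
    }
    counter = {key: 0 for key in tf_intervals}
    for eid, rec in truth.iterrows():
        b_gt, b_pp2 = bound[rec["true_class"]]
        if not (b_gt or b_pp2):
            continue
        # FOXA1 always; FOXA2 in ~70% of bound enhancers (same stages)
        tfs_here = ["FOXA1"] + (["FOXA2"] if rng.random() < 0.7 else [])
        for tf in tfs_here:
            for stage, is_bound in zip(STAGES, (b_gt, b_pp2)):
                if not is_bound:
                    continue
                truth.loc[eid, f"{tf}_{stage}"] = True
                jitter = int(rng.integers(-100, 101))
                center = int(rec["summit"]) + jitter
                half = config.tf_peak_width // 2
                key = (tf, stage)
                tf_intervals[key].append(
                    GenomicInterval(
                        rec["chrom"], center - half, center - half + config.tf_peak_width,
                        f"{tf}_{stage}_{counter[key]:05d}",
                    )
                )
                counter[key] += 1
    truth["bound_GT"] = truth[[f"{tf}_GT" for tf in TFS]].any(axis=1)
    truth["bound_PP2"] = truth[[f"{tf}_PP2" for tf in TFS]].any(axis=1)

    # extra TF peaks away from any enhancer (background binding sites)
    enh_index = IntervalIndex(
        GenomicInterval(r["chrom"], r["start"], r["end"]) for _, r in truth.iterrows()
    )
    n_extra = 0
    attempts = 0
    while n_extra < config.n_extra_tf_peaks and attempts < config.n_extra_tf_peaks * 50:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, config.chrom_sizes[chrom] - config.tf_peak_width))
        iv = GenomicInterval(chrom, start, start + config.tf_peak_width)
        if enh_index.overlaps_any(iv, slop=500):
            continue
        tf = TFS[int(rng.integers(2))]
        for stage in STAGES:
            if rng.random() < 0.5:
                key = (tf, stage)
                tf_intervals[key].append(
                    GenomicInterval(chrom, start, start + config.tf_peak_width,
                                    f"{tf}_{stage}_{counter[key]:05d}")
                )
                counter[key] += 1
        n_extra += 1

    # --- H3K27ac counts ---------------------------------------------------
    lineage = truth["true_class"].isin(["I", "II", "III", "unbound"])
    truth["true_log2fc"] = np.where(lineage, config.gain_log2fc, 0.0)
    truth["is_super_enhancer"] = truth["cluster_id"] != ""
    base = np.where(truth["is_super_enhancer"], config.nb_mean * config.se_signal_fold, config.nb_mean)
    samples = [f"{stage}_rep{r + 1}" for stage in STAGES for r in range(config.n_replicates)]
    design = pd.DataFrame(
        {
            "stage": [s.split("_")[0] for s in samples],
            "condition": ["control"] * len(samples),
            "replicate": [int(s.split("rep")[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    region_ids = list(truth.index) + [iv.id for iv in prox_intervals]
    mean_gt = np.concatenate([base, np.full(len(prox_intervals), config.nb_mean)])
    lfc = np.concatenate([truth["true_log2fc"].to_numpy(), np.zeros(len(prox_intervals))])
    cols = {}
    for s in samples:
        stage_mean = mean_gt * (2.0 ** lfc if s.startswith(STAGES[1]) else 1.0)
        cols[s] = _nb_draw(rng, stage_mean, config.nb_dispersion)
    h3k27ac = SignalTable(
        pd.DataFrame(cols, index=pd.Index(region_ids, name="region_id")), design
    )

    enhancers = RegionSet(
        (
            GenomicInterval(r["chrom"], r["start"], r["end"], eid, ".", r["summit"])
            for eid, r in truth.iterrows()
        ),
        config.chrom_sizes,
    )
    return SimulatedLandscape(
        enhancers=enhancers,
        proximal_peaks=RegionSet(prox_intervals, config.chrom_sizes),
        tf_peaks={
            key: RegionSet(ivs, config.chrom_sizes) for key, ivs in tf_intervals.items()
        },
        h3k27ac=h3k27ac,
        tss=RegionSet(tss_intervals, config.chrom_sizes),
        expression=pd.Series(gene_fpkm, name="fpkm"),
        truth=truth,
        chrom_sizes=dict(config.chrom_sizes),
    )


def simulate_perturbation(
    landscape: SimulatedLandscape, config: SimulationConfig
) -> tuple[SignalTable, pd.Series]:
    """TF ChIP signal at class I/II enhancers in control vs knockdown cells.

    A configured fraction of each class loses signal (planted
    ``loss_log2fc``); returns the count table and a boolean truth series
    marking the dependent enhancers.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = landscape.truth
    target = truth[truth["true_class"].isin(["I", "II"])]
    dependent = pd.Series(False, index=target.index, name="perturbation_dependent")
    for cls, frac in (("I", config.loss_fraction_class_i), ("II", config.loss_fraction_class_ii)):
        ids = target.index[target["true_class"] == cls]
        n_dep = int(round(frac * len(ids)))
        chosen = rng.choice(ids, size=n_dep, replace=False)
        dependent.loc[chosen] = True

    samples = [f"{cond}_rep{r + 1}" for cond in ("SCRAM", "shTF") for r in range(config.n_replicates)]
    design = pd.DataFrame(
        {
            "stage": ["PP2"] * len(samples),
            "condition": [s.split("_")[0] for s in samples],
            "replicate": [int(s.split("rep")[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    base = np.full(len(target), config.nb_mean)
    lfc = np.where(dependent.to_numpy(), config.loss_log2fc, 0.0)
    cols = {}
    for s in samples:
        mean = base * (2.0 ** lfc if s.startswith("shTF") else 1.0)
        cols[s] = _nb_draw(rng, mean, config.nb_dispersion)
    table = SignalTable(
        pd.DataFrame(cols, index=pd.Index(target.index, name="region_id")), design
    )
    return table, dependent


# ---------------------------------------------------------------------------
# Sequences with planted motifs
# ---------------------------------------------------------------------------

MAX_PLANT_DRAWS = 100_000


def _pwm_emission_scores(pwm: PWM, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Log-odds scores of k-mers emitted by the PWM itself (Monte Carlo)."""
    lo = pwm.log_odds
    cum = pwm.probs.cumsum(axis=1)
    u = rng.random((n_draws, pwm.width))
    picks = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    return lo[np.arange(pwm.width)[None, :], picks].sum(axis=1)


def simulate_sequences(
    regions: RegionSet,
    pwm: PWM,
    strength_quantile: tuple[float, float] = (0.9, 1.0),
    offset_sd: float = 0.0,
    plant_probability: float = 1.0,
    seed: int = 0,
    gc: float = 0.409,
) -> tuple[dict[str, str], pd.DataFrame]:
    """I.i.d. background sequences with one motif instance per region.

    The instance is drawn from the PWM conditional on its log-odds score
    falling inside ``strength_quantile`` of the PWM's own emission-score
    distribution (rejection sampling, capped), reverse-complemented onto the
    minus strand half the time, and centered at summit + N(0, offset_sd).
    Returns (sequences, planted-hit table).
    """
    rng = np.random.default_rng(seed)
    if not (0.0 <= strength_quantile[0] < strength_quantile[1] <= 1.0):
        raise ValueError("strength_quantile must satisfy 0 <= lo < hi <= 1")
    bg = gc_background(gc)
    w = pwm.width
    for iv in regions:
        if len(iv) < w:
            raise ValueError(f"region {iv.id} shorter than the PWM width {w}")

    ref_scores = np.sort(_pwm_emission_scores(pwm, 20_000, rng))
    lo_score = float(np.quantile(ref_scores, strength_quantile[0]))
    hi_score = float(np.quantile(ref_scores, strength_quantile[1]))

    def draw_instance() -> tuple[str, float]:
        cum = pwm.probs.cumsum(axis=1)
        lo_m = pwm.log_odds
        for _ in range(MAX_PLANT_DRAWS):
            u = rng.random(w)
            picks = (u[:, None] > cum).sum(axis=1)
            score = float(lo_m[np.arange(w), picks].sum())
            if lo_score <= score <= hi_score:
                return "".join(BASES[i] for i in picks), score
        raise ValueError(
            f"strength band {strength_quantile} unreachable for PWM "
            f"{pwm.motif_id} within {MAX_PLANT_DRAWS} draws"
        )

    comp = str.maketrans("ACGT", "TGCA")
    seqs: dict[str, str] = {}
    planted: list[dict] = []
    for iv in regions:
        length = len(iv)
        seq = rng.choice(list(BASES), size=length, p=bg)
        summit_off = (iv.summit - iv.start) if iv.summit is not None else length // 2
        if rng.random() < plant_probability:
            kmer, score = draw_instance()
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = kmer if strand == "+" else kmer.translate(comp)[::-1]
            for _ in range(1000):
                center = summit_off + int(round(rng.normal(0.0, offset_sd)))
                start = center - w // 2
                if 0 <= start <= length - w:
                    break
            else:
                raise ValueError(f"cannot place motif inside region {iv.id}")
            seq[start : start + w] = list(inserted)
            planted.append(
                {
                    "region_id": iv.id,
                    "motif_id": pwm.motif_id,
                    "strand": strand,
                    "start": start,
                    "center_offset": start + w // 2 - summit_off,
                    "score": score,
                }
            )
        seqs[iv.id] = "".join(seq)
    return seqs, pd.DataFrame(
        planted,
        columns=["region_id", "motif_id", "strand", "start", "center_offset", "score"],
    )


# ---------------------------------------------------------------------------
# Hi-C contact maps
# ---------------------------------------------------------------------------

def simulate_hic(
    config: SimulationConfig,
    chrom: str = "chr1",
    anchor_bins: Sequence[int] | None = None,
) -> tuple[ContactMatrix, pd.DataFrame]:
    """Distance-decay contact map with planted focal loops.

    Expected counts fall off as (d)^-alpha in bin units; raw counts are
    Poisson around the expectation.  Each planted loop enriches a focal
    3x3 patch the way real loops do at 10-kb resolution: the loop pixel's
    expectation is multiplied by ``hic_loop_fold`` and its 8 adjacent
    pixels by half that enrichment (the patch stays inside the donut's
    inner exclusion zone, so background estimates are unaffected).  When
    ``anchor_bins`` is given, loop anchors are drawn from those bins
    (subject to the distance window and pairwise separation); loops on the
    diagonal are rejected by construction.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.hic_n_bins
    alpha = config.hic_alpha
    scale = config.hic_diag_scale

    def expected(d: int) -> float:
        if d == 0:
            return 2.0 * scale
        return scale * d ** (-alpha)

    # choose loop pixels (anchored draws first, random fallback)
    loops: list[tuple[int, int]] = []
    attempts = 0
    while len(loops) < config.hic_n_loops and attempts < 20_000:
        attempts += 1
        use_anchors = (
            anchor_bins is not None and len(anchor_bins) >= 2 and attempts <= 10_000
        )
        if use_anchors:
            i = int(rng.choice(anchor_bins))
            j = int(rng.choice(anchor_bins))
            if i > j:
                i, j = j, i
        else:
            i = 1 + int(rng.integers(0, n - config.hic_loop_min_dist - 1))
            j = i + int(rng.integers(config.hic_loop_min_dist, config.hic_loop_max_dist + 1))
        if i == j:
            continue
        d = j - i
        if not (config.hic_loop_min_dist <= d <= config.hic_loop_max_dist):
            continue
        if not (1 <= i and j < n - 1):
            continue
        if any(
            max(abs(i - a), abs(j - b)) <= config.hic_loop_separation for a, b in loops
        ):
            continue
        loops.append((i, j))
    if len(loops) < config.hic_n_loops:
        raise ValueError(
            "could not place the requested loops with the required separation"
        )

    # focal 3x3 enrichment kernel per loop (kept inside the donut exclusion)
    fold_map: dict[tuple[int, int], float] = {}
    side_fold = 1.0 + (config.hic_loop_fold - 1.0) / 2.0
    for i, j in loops:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = i + di, j + dj
                if not (0 <= ii < n and 0 <= jj < n) or jj <= ii:
                    continue
                mult = config.hic_loop_fold if (di, dj) == (0, 0) else side_fold
                fold_map[(ii, jj)] = max(fold_map.get((ii, jj), 1.0), mult)

    cm = ContactMatrix(chrom, config.hic_resolution, n)
    for i in range(n):
        for j in range(i, n):
            e = expected(j - i) * fold_map.get((i, j), 1.0)
            c = int(rng.poisson(e))
            if c > 0:
                cm.set(i, j, c)
    table = pd.DataFrame(
        [
            {
                "bin_i": i,
                "bin_j": j,
                "distance_bins": j - i,
                "fold": config.hic_loop_fold,
                "expected_background": expected(j - i),
            }
            for i, j in sorted(loops)
        ]
    )
    return cm, table
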