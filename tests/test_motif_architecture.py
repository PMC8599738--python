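import itertools

import numpy as np
import pytest

from enhancerkit import (
    central_enrichment,
    load_bundled_pwm,
    occurrence_enrichment,
    positional_profile,
    scan_pwm,
    strength_comparison,
)
from enhancerkit.io_formats import reverse_complement
from enhancerkit.motif_architecture import SCORE_PRECISION, _ScoreModel
from conftest import random_pwm

# 200-nt human NKX6.1-enhancer donor oligonucleotide used as a fixed
# realistic scanning substrate
NKX61_DONOR = (
    "TGCCTATGATTTATGTATTTGTTTAGTCAATAGTCTAATGTAAATGATGTAATTAATTATAGATGGTGG"
    "TGTCAGGTCATTTGTGTAAACAATCTGAGGTAAACAAGGGCTCTGTTTACTTCATGACAGATGCAGGGG"
    "GGTGGGGGGCTGAGTTGAGGGAATTCCAGGGGAACTTTTTCACGTGTGAATGGCGGCTGGGA"
)

BASE_ORDER = "ACGT"


def enumerate_null(pwm):
    """Exact discretized null score distribution by enumerating all 4^w
    windows under the background model (oracle; w <= 8 only)."""
    lo = np.log2(pwm.probs / pwm.background[None, :])
    int_lo = np.round(lo / SCORE_PRECISION).astype(int)
    null = {}
    for kmer in itertools.product(range(4), repeat=pwm.width):
        s = sum(int_lo[j, b] for j, b in enumerate(kmer))
        prob = float(np.prod([pwm.background[b] for b in kmer]))
        null[s] = null.get(s, 0.0) + prob
    return null


def brute_force_scan(seq, pwm, p_threshold=None, null=None):
    """Naive all-window scorer, independent of the package's DP/vectorized
    path.  When ``null`` (from :func:`enumerate_null`) is given, hits carry
    enumeration p-values and can be filtered at ``p_threshold``; otherwise
    p is None and all windows are reported."""
    lo = np.log2(pwm.probs / pwm.background[None, :])
    w = pwm.width
    int_lo = np.round(lo / SCORE_PRECISION).astype(int)
    if null is not None:
        levels = sorted(null)

        def pval(int_score):
            return min(sum(null[s] for s in levels if s >= int_score), 1.0)

    hits = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for off in range(len(s) - w + 1):
            window = s[off : off + w]
            if any(b not in BASE_ORDER for b in window):
                continue
            idx = [BASE_ORDER.index(b) for b in window]
            score = float(sum(lo[j, b] for j, b in enumerate(idx)))
            start = off if strand == "+" else len(s) - w - off
            if null is None:
                hits.append((strand, start, score, None))
                continue
            int_score = int(sum(int_lo[j, b] for j, b in enumerate(idx)))
            p = pval(int_score)
            if p_threshold is None or p <= p_threshold:
                hits.append((strand, start, score, p))
    return sorted(hits, key=lambda h: (h[1], h[0]))


class TestScanPwm:
    def test_consensus_scores_the_maximum(self):
        pwm = load_bundled_pwm()
        hits = scan_pwm({"s": pwm.consensus}, pwm, p_threshold=1.0)
        fwd = hits[hits.strand == "+"]
        assert fwd["score"].max() == pytest.approx(pwm.max_score)

    def test_reverse_complement_mirrors_hits(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(6, rng)
        seq = "".join(rng.choice(list("ACGT"), 80))
        fwd = scan_pwm({"s": seq}, pwm, p_threshold=0.3)
        rev = scan_pwm({"s": reverse_complement(seq)}, pwm, p_threshold=0.3)
        L = len(seq)
        mirrored = {
            (("-" if s == "+" else "+"), L - pwm.width - start, round(sc, 9))
            for s, start, sc in zip(fwd.strand, fwd.start, fwd.score)
        }
        got = {
            (s, start, round(sc, 9))
            for s, start, sc in zip(rev.strand, rev.start, rev.score)
        }
        assert got == mirrored

    def test_matches_naive_scorer_on_donor_sequence(self):
        pwm = load_bundled_pwm()
        hits = scan_pwm({"donor": NKX61_DONOR}, pwm, p_threshold=1.0)
        expected = brute_force_scan(NKX61_DONOR, pwm)
        got = sorted(
            (s, int(st), round(sc, 9))
            for s, st, sc in zip(hits.strand, hits.start, hits.score)
        )
        want = sorted((s, st, round(sc, 9)) for s, st, sc, _ in expected)
        assert got == want

    def test_null_distribution_matches_enumeration(self):
        rng = np.random.default_rng(5)
        pwm = random_pwm(5, rng)
        model = _ScoreModel(pwm)
        null = enumerate_null(pwm)
        # every attainable enumerated score sits inside the DP support
        for s in null:
            assert 0 <= s - model.min_total < len(model.dist)
        total_var = 0.0
        for k, p_dp in enumerate(model.dist):
            s = model.min_total + k
            total_var += abs(p_dp - null.get(s, 0.0))
        assert total_var < 1e-9

    def test_n_windows_skipped(self):
        pwm = load_bundled_pwm()
        seq = "N" * 30
        assert len(scan_pwm({"s": seq}, pwm, p_threshold=1.0)) == 0

    def test_short_sequence_rejected(self):
        pwm = load_bundled_pwm()
        with pytest.raises(ValueError, match="shorter than PWM"):
            scan_pwm({"s": "ACGT"}, pwm)

    def test_pvalues_monotone_in_score(self):
        # monotone up to the 1e-3-bit discretization of the p-value grid
        rng = np.random.default_rng(6)
        pwm = random_pwm(7, rng)
        seq = "".join(rng.choice(list("ACGT"), 500))
        hits = scan_pwm({"s": seq}, pwm, p_threshold=1.0)
        h = hits.sort_values("score")
        scores = h["score"].to_numpy()
        pvals = h["pvalue"].to_numpy()
        distinct = np.diff(scores) > 10 * SCORE_PRECISION
        assert (np.diff(pvals)[distinct] <= 1e-12).all()


class TestOccurrenceEnrichment:
    def test_duplicated_hits_do_not_change_percentages(self):
        pwm = load_bundled_pwm()
        rng = np.random.default_rng(7)
        bg = "".join(rng.choice(list("ACGT"), 200))
        one_hit = bg[:50] + pwm.consensus + bg[50 + pwm.width : 200]
        two_hits = (
            bg[:50] + pwm.consensus + bg[62:100] + pwm.consensus + bg[112:200]
        )
        a = {"r1": one_hit, "r2": bg}
        b = {"r1": two_hits, "r2": bg}
        res_a = occurrence_enrichment(a, a, [pwm])
        res_b = occurrence_enrichment(b, b, [pwm])
        assert res_a.iloc[0]["pct_a"] == res_b.iloc[0]["pct_a"] == 50.0

    def test_identical_sets_give_p_one(self):
        pwm = load_bundled_pwm()
        rng = np.random.default_rng(8)
        seqs = {
            f"r{i}": "".join(rng.choice(list("ACGT"), 100)) for i in range(10)
        }
        res = occurrence_enrichment(seqs, seqs, [pwm])
        assert res.iloc[0]["pvalue"] == pytest.approx(1.0)

    def test_bh_across_motifs(self):
        rng = np.random.default_rng(9)
        pwms = [random_pwm(6, rng) for _ in range(6)]
        seqs_a = {f"a{i}": "".join(rng.choice(list("ACGT"), 150)) for i in range(8)}
        seqs_b = {f"b{i}": "".join(rng.choice(list("ACGT"), 150)) for i in range(8)}
        res = occurrence_enrichment(seqs_a, seqs_b, pwms)
        assert len(res) == 6
        from enhancerkit import benjamini_hochberg

        assert np.allclose(
            res["padj"], benjamini_hochberg(res["pvalue"].to_numpy())
        )


class TestStrengthComparison:
    def test_identical_scores_give_p_one(self):
        _, p = strength_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_shifted_scores_extreme_p(self):
        from math import comb

        b = list(np.arange(10) * 0.1)
        a = [x + 3.0 for x in b]  # every a outranks every b
        _, p = strength_comparison(a, b)
        # two-sided doubling of the single most extreme rank split
        assert p == pytest.approx(2.0 / comb(20, 10))

    def test_separated_strength_bands_detected(self, small_landscape):
        from enhancerkit import simulate_sequences

        pwm = load_bundled_pwm()
        truth = small_landscape.truth
        regions = small_landscape.enhancers.subset(truth.index[:100])
        _, strong = simulate_sequences(regions, pwm, (0.9, 1.0), seed=1)
        _, weak = simulate_sequences(regions, pwm, (0.3, 0.5), seed=2)
        _, p = strength_comparison(strong["score"], weak["score"])
        assert p < 1e-6


class TestPositionalProfile:
    def _centered_seqs(self, pwm, n, rng, jitter=0):
        seqs, summits = {}, {}
        for i in range(n):
            bg = "".join(rng.choice(list("ACGT"), 2 * 520 + 1))
            center = 520 + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
            start = center - pwm.width // 2
            seq = bg[:start] + pwm.consensus + bg[start + pwm.width :]
            seqs[f"r{i}"] = seq
            summits[f"r{i}"] = 520
        return seqs, summits

    def test_planted_center_is_the_mode(self):
        pwm = load_bundled_pwm()
        rng = np.random.default_rng(3)
        seqs, summits = self._centered_seqs(pwm, 40, rng)
        prof = positional_profile(seqs, summits, pwm, flank=500)
        assert prof.offsets[int(np.argmax(prof.probability))] == 0
        assert prof.probability.max() == pytest.approx(1.0)

    def test_summit_too_close_to_edge_dropped(self):
        pwm = load_bundled_pwm()
        rng = np.random.default_rng(4)
        seqs = {"r0": "".join(rng.choice(list("ACGT"), 300))}
        with pytest.warns(UserWarning, match="dropped"):
            prof = positional_profile(seqs, {"r0": 150}, pwm, flank=500)
        assert prof.n_regions == 0

    def test_central_enrichment_detects_planted_centrality(self):
        pwm = load_bundled_pwm()
        rng = np.random.default_rng(5)
        seqs_a, summits_a = self._centered_seqs(pwm, 60, rng, jitter=20)
        seqs_b, summits_b = self._centered_seqs(pwm, 60, rng, jitter=450)
        prof_a = positional_profile(seqs_a, summits_a, pwm, flank=500, class_label="I")
        prof_b = positional_profile(seqs_b, summits_b, pwm, flank=500, class_label="II")
        frac_a, frac_b, p = central_enrichment(prof_a, prof_b, window=100)
        assert frac_a > frac_b
        assert p < 0.01
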