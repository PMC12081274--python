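"""Allelic dPWM scoring: QC filters, window scoring against a brute-force
oracle, score-change identities, and the significance machinery."""
import types

import numpy as np
import pandas as pd
import pytest

from cbskit import _seq
from cbskit.allelic import (BackgroundModel, ExactScoreChangeNull,
                            ImportanceSamplingNull, best_allele_scores,
                            classify_delta, dedupe_per_variant,
                            encode_truncated_pvalues, exact_change_pvalue,
                            filter_variants, flag_confident,
                            importance_sampling_pvalue,
                            intersect_variants_with_cbs, neglog10_rank,
                            score_alleles, score_pairs_table)
from cbskit.io import DataIntegrityError, GenomeIndex
from cbskit.motifs import MotifHit, pfm_to_pwm


def _variant_frame(rows):
    cols = ["chrom", "pos", "ref", "alt", "AC", "AN", "AF", "filter"]
    return pd.DataFrame(rows, columns=cols)


class TestFilterVariants:
    def test_eight_record_fixture_retains_four(self):
        an_hi, af = 100_000, 1e-5
        rows = [
            ("chr1", 10, "A", "C", 3, an_hi, af, "PASS"),       # keep
            ("chr1", 20, "AT", "C", 3, an_hi, af, "PASS"),      # multi-base ref
            ("chr1", 30, "G", "T", 0, an_hi, 0.0, "PASS"),      # AC = 0
            ("chr1", 40, "G", "T", 2, an_hi, af, "LowQual"),    # not PASS
            ("chr1", 50, "C", "A", 5, 70_000, af, "PASS"),      # low AN
            ("chr1", 60, "C", "G", 1, an_hi, af, "PASS"),       # keep
            ("chr1", 70, "T", "A", 9, an_hi, af, "PASS"),       # keep
            ("chr1", 80, "T", "G", 1, an_hi, af, "PASS"),       # keep
        ]
        res = filter_variants(_variant_frame(rows))
        assert len(res.kept) == 4
        assert list(res.kept["pos"]) == [10, 60, 70, 80]
        assert res.removed == {"not_snv": 1, "ac_zero": 1, "af_zero": 0,
                               "not_pass": 1, "low_an": 1}

    def test_an_boundary_is_strict(self):
        rows = [("chr1", 10, "A", "C", 3, 76_000, 1e-5, "PASS"),
                ("chr1", 11, "A", "C", 3, 76_001, 1e-5, "PASS")]
        res = filter_variants(_variant_frame(rows))
        assert list(res.kept["pos"]) == [11]

    def test_empty_table(self):
        res = filter_variants(_variant_frame([]))
        assert res.kept.empty
        assert all(v == 0 for v in res.removed.values())

    def test_missing_column_rejected(self):
        with pytest.raises(DataIntegrityError):
            filter_variants(pd.DataFrame({"chrom": ["chr1"]}))


def _motif(start, end, quantile=50, activity=2.0):
    return MotifHit(chrom="chr1", start=start, end=end, strand="+", score=1.0,
                    relative_score=0.9, motif_id="m", activity=activity,
                    quantile=quantile)


class TestIntersect:
    def test_coordinate_conversion(self):
        motif = _motif(100, 119)
        inside = _variant_frame([("chr1", 101, "A", "C", 1, 100_000, 1e-5,
                                  "PASS")])
        assert len(intersect_variants_with_cbs(inside, [motif])) == 1
        # 1-based 100 is 0-based 99: outside [100, 119)
        outside = _variant_frame([("chr1", 100, "A", "C", 1, 100_000, 1e-5,
                                   "PASS")])
        assert len(intersect_variants_with_cbs(outside, [motif])) == 0
        # 1-based 119 is 0-based 118: the last base of the motif
        last = _variant_frame([("chr1", 119, "A", "C", 1, 100_000, 1e-5,
                                "PASS")])
        assert len(intersect_variants_with_cbs(last, [motif])) == 1

    def test_bookended_motifs_emit_two_rows(self):
        motifs = [_motif(100, 119, quantile=10), _motif(110, 129, quantile=90)]
        var = _variant_frame([("chr1", 112, "A", "C", 1, 100_000, 1e-5,
                               "PASS")])
        pairs = intersect_variants_with_cbs(var, motifs)
        assert len(pairs) == 2
        assert sorted(pairs["quantile"]) == [10, 90]


def oracle_best_scores(window: str, alt: str, pwm, flank: int):
    """Independent subwindow/strand loop for ref and alt best scores."""
    L = pwm.length
    best_r = best_a = float("-inf")
    for s in range(len(window) - L + 1):
        if not (s <= flank <= s + L - 1):
            continue
        sub = window[s:s + L]
        alt_sub = sub[:flank - s] + alt + sub[flank - s + 1:]
        if "N" not in sub:
            best_r = max(best_r, pwm.score(sub), pwm.score(_seq.revcomp(sub)))
        if "N" not in alt_sub:
            best_a = max(best_a, pwm.score(alt_sub),
                         pwm.score(_seq.revcomp(alt_sub)))
    return best_r, best_a


class TestScoreAlleles:
    def test_matches_oracle_on_1000_random_windows(self, mid_pfm):
        pwm = pfm_to_pwm(mid_pfm)
        flank = 4
        rng = np.random.default_rng(13)
        windows = rng.integers(0, 4, size=(1000, 2 * flank + 1)).astype(np.uint8)
        alts = ((windows[:, flank] + rng.integers(1, 4, 1000)) % 4).astype(np.uint8)
        rb, ab = best_allele_scores(windows, alts, pwm, flank)
        for i in range(1000):
            w = _seq.decode(windows[i])
            er, ea = oracle_best_scores(w, "ACGT"[alts[i]], pwm, flank)
            assert rb[i] == pytest.approx(er, abs=1e-9)
            assert ab[i] == pytest.approx(ea, abs=1e-9)

    def test_identity_substitution_is_zero_gain(self, toy_pwm, random_genome):
        ref = random_genome.base("chr1", 500)
        fake = types.SimpleNamespace(chrom="chr1", pos=501, ref=ref, alt=ref)
        score = score_alleles(fake, None, random_genome, toy_pwm, flank=3)
        assert score.delta_pwm == 0.0
        assert score.binding_class == "gain"

    def test_consensus_disruption_hand_computed(self, toy_pwm):
        # genome = consensus planted centrally; variant at motif column 1
        cons = toy_pwm.consensus
        genome = GenomeIndex({"chr1": "TTTT" + cons + "TTTT"})
        pos0 = 5  # motif column 1 (0-based), the strong C column
        col = 1
        ref = cons[col]
        worst = "ACGT"[int(np.argmin(toy_pwm.log_odds[:, col]))]
        fake = types.SimpleNamespace(chrom="chr1", pos=pos0 + 1, ref=ref,
                                     alt=worst)
        score = score_alleles(fake, None, genome, toy_pwm, flank=2)
        # the planted motif is the best subwindow for both alleles here,
        # verified against the independent oracle
        w = genome.fetch("chr1", pos0 - 2, pos0 + 3)
        er, ea = oracle_best_scores(w, worst, toy_pwm, 2)
        assert score.ref_best == pytest.approx(er, abs=1e-12)
        assert score.alt_best == pytest.approx(ea, abs=1e-12)
        assert score.delta_pwm > 0 and score.binding_class == "loss"

    def test_ref_mismatch_is_hard_error(self, toy_pwm):
        genome = GenomeIndex({"chr1": "AAAAAAAA"})
        fake = types.SimpleNamespace(chrom="chr1", pos=4, ref="C", alt="G")
        with pytest.raises(DataIntegrityError, match="chr1:4"):
            score_alleles(fake, None, genome, toy_pwm, flank=2)

    def test_contig_shorter_than_motif_drops_pair(self, toy_pwm):
        # contig of 2 bases cannot host any 3-mer subwindow: every candidate
        # is N-padded and skipped, so the pair is dropped
        genome = GenomeIndex({"chr1": "AC"})
        fake = types.SimpleNamespace(chrom="chr1", pos=1, ref="A", alt="C")
        assert score_alleles(fake, None, genome, toy_pwm, flank=10) is None


class TestDeltaIdentities:
    @pytest.fixture()
    def fixtures(self, mid_pfm):
        pwm = pfm_to_pwm(mid_pfm)
        flank = 4
        rng = np.random.default_rng(29)
        windows = rng.integers(0, 4, size=(1000, 9)).astype(np.uint8)
        alts = ((windows[:, flank] + rng.integers(1, 4, 1000)) % 4).astype(np.uint8)
        return pwm, flank, windows, alts

    def test_allele_swap_antisymmetry(self, fixtures):
        pwm, flank, windows, alts = fixtures
        rb, ab = best_allele_scores(windows, alts, pwm, flank)
        swapped = windows.copy()
        swapped[:, flank] = alts
        rb2, ab2 = best_allele_scores(swapped, windows[:, flank], pwm, flank)
        np.testing.assert_allclose(rb - ab, -(rb2 - ab2), atol=1e-9)

    def test_strand_reversal_invariance(self, fixtures):
        pwm, flank, windows, alts = fixtures
        rb, ab = best_allele_scores(windows, alts, pwm, flank)
        rc_windows = np.array([_seq.revcomp_codes(w) for w in windows])
        rc_alts = _seq.complement_codes(alts)
        rb2, ab2 = best_allele_scores(rc_windows, rc_alts, pwm, flank)
        np.testing.assert_allclose(rb, rb2, atol=1e-9)
        np.testing.assert_allclose(ab, ab2, atol=1e-9)

    def test_gain_loss_partition(self, fixtures):
        pwm, flank, windows, alts = fixtures
        rb, ab = best_allele_scores(windows, alts, pwm, flank)
        classes = {classify_delta(d) for d in (rb - ab)}
        assert classes <= {"gain", "loss"}


def brute_force_null(pwm, background, flank):
    """Literal loop over all windows x substitutions (tiny scale only)."""
    W = 2 * flank + 1
    bg = background.base_probs
    atoms = []
    for idx in range(4 ** W):
        digits = [(idx // 4 ** (W - 1 - j)) % 4 for j in range(W)]
        window = "".join("ACGT"[d] for d in digits)
        p_win = np.prod([bg[d] for d in digits])
        center = digits[flank]
        for a in range(4):
            if a == center:
                continue
            er, ea = oracle_best_scores(window, "ACGT"[a], pwm, flank)
            atoms.append((er - ea, p_win / 3.0))
    return atoms


class TestExactNull:
    def test_matches_literal_triple_loop(self, toy_pwm):
        bg = BackgroundModel(base_probs=np.array([0.3, 0.2, 0.2, 0.3]))
        flank = 1  # window length 3, 64 windows
        atoms = brute_force_null(toy_pwm, bg, flank)
        null = ExactScoreChangeNull(toy_pwm, bg, flank)
        for d in np.linspace(-6, 6, 13):
            expect_ge = sum(w for a, w in atoms if a >= d - 1e-9)
            expect_le = sum(w for a, w in atoms if a <= d + 1e-9)
            assert null.tail_ge(d) == pytest.approx(expect_ge, abs=1e-12)
            assert null.tail_le(d) == pytest.approx(expect_le, abs=1e-12)

    def test_unreachable_tail_is_zero(self, toy_pwm):
        bg = BackgroundModel()
        null = ExactScoreChangeNull(toy_pwm, bg, flank=2)
        huge = toy_pwm.score_max - toy_pwm.score_min + 1
        assert null.pvalue(huge) == 0.0
        assert null.pvalue(-huge) == 0.0  # below support, <= direction

    def test_full_support_at_opposite_extreme(self, toy_pwm):
        null = ExactScoreChangeNull(toy_pwm, BackgroundModel(), flank=2)
        assert null.tail_ge(float(null.deltas.min())) == pytest.approx(1.0)
        assert null.tail_le(float(null.deltas.max())) == pytest.approx(1.0)

    def test_tails_monotone(self, toy_pwm):
        null = ExactScoreChangeNull(toy_pwm, BackgroundModel(), flank=2)
        grid = np.linspace(null.deltas.min() - 1, null.deltas.max() + 1, 41)
        ge = [null.tail_ge(d) for d in grid]
        le = [null.tail_le(d) for d in grid]
        assert all(a >= b - 1e-12 for a, b in zip(ge, ge[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(le, le[1:]))

    def test_refuses_large_enumeration(self, mid_pfm):
        pwm = pfm_to_pwm(mid_pfm)
        with pytest.raises(ValueError):
            ExactScoreChangeNull(pwm, BackgroundModel(), flank=7)


class TestImportanceSampling:
    def test_agrees_with_exact_within_3_se(self, toy_pwm):
        bg = BackgroundModel(base_probs=np.array([0.35, 0.15, 0.15, 0.35]))
        flank = 2
        exact = ExactScoreChangeNull(toy_pwm, bg, flank)
        null = ImportanceSamplingNull(toy_pwm, bg, flank, n_samples=30_000,
                                      seed=3)
        for d in [-4.0, -1.5, -0.5, 0.5, 1.5, 3.0, 5.0]:
            p_exact = exact.pvalue(d)
            p_is, se = null.pvalue(d)
            assert abs(p_is - p_exact) <= 3 * se + 1e-12

    def test_deterministic_given_seed(self, toy_pwm):
        args = (toy_pwm, BackgroundModel(), 2, 5000, 77)
        p1 = importance_sampling_pvalue(1.0, *args)
        p2 = importance_sampling_pvalue(1.0, *args)
        assert p1 == p2

    def test_estimate_one_when_whole_support_in_tail(self, toy_pwm):
        null = ImportanceSamplingNull(toy_pwm, BackgroundModel(), 2,
                                      n_samples=5000, seed=5)
        huge = toy_pwm.score_max - toy_pwm.score_min + 1
        p, se = null.pvalue(-huge + 0.0)  # below support, <= direction: empty
        assert p == 0.0
        p, se = null.pvalue(0.0 - 2 * huge)
        assert p == 0.0
        # whole support is >= a delta far below the minimum: weighted mean ~ 1
        p, se = null._tail(np.ones(null.n, dtype=bool))
        assert p == pytest.approx(1.0, abs=0.02)

    def test_rejects_too_few_samples(self, toy_pwm):
        with pytest.raises(ValueError):
            ImportanceSamplingNull(toy_pwm, BackgroundModel(), 2, 100, 0)


class TestPvalueBookkeeping:
    @pytest.mark.parametrize("p,expected", [
        (0.0, 1e-7), (0.05, 0.05), (5e-8, 1e-7),
    ])
    def test_dummy_floor(self, p, expected):
        assert encode_truncated_pvalues(p) == expected

    def test_neglog10_of_floored_zero(self):
        assert neglog10_rank(0.0) == pytest.approx(7.0)

    def test_negative_p_rejected(self):
        with pytest.raises(ValueError):
            encode_truncated_pvalues(-0.1)

    def test_confidence_threshold_is_strict(self, toy_pwm, random_genome):
        def fake_score(p):
            s = score_alleles(
                types.SimpleNamespace(chrom="chr1", pos=900,
                                      ref=random_genome.base("chr1", 899),
                                      alt="A" if random_genome.base("chr1", 899)
                                      != "A" else "C"),
                None, random_genome, toy_pwm, flank=3)
            s.p_value = p
            return s
        flagged = flag_confident([fake_score(0.049), fake_score(0.05),
                                  fake_score(0.2)])
        assert [s.confident for s in flagged] == [True, False, False]
        assert sum(s.confident for s in flagged) + \
            sum(not s.confident for s in flagged) == 3


class TestDedupe:
    def test_keeps_smallest_p_then_largest_effect(self):
        df = pd.DataFrame({
            "variant_id": ["v1", "v1", "v1", "v2", "v2"],
            "p_value": [0.01, 0.001, 0.001, 0.5, 0.5],
            "delta_pwm": [3.0, 1.0, -2.0, 0.5, -0.5],
            "motif_chrom": ["chr1"] * 5,
            "motif_start": [10, 20, 30, 40, 35],
            "motif_end": [29, 39, 49, 59, 54],
            "motif_strand": ["+"] * 5,
        })
        out = dedupe_per_variant(df).set_index("variant_id")
        assert out.loc["v1", "delta_pwm"] == -2.0  # p tie, larger |delta|
        # v2: |delta| tie, earlier motif coordinate wins
        assert out.loc["v2", "motif_start"] == 35
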