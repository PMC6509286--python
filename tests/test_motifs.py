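"""PWM construction/scanning and RIC-style RSS scoring."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cutrun.core import InputError, encode, revcomp
from cutrun.motifs import (
    DEFAULT_BACKGROUND,
    DegenerateModelError,
    Pwm,
    RssModel,
    build_pwm,
    default_heptamer_counts,
    find_rss_near_junctions,
    pwm_exact_pvalue,
    pwm_score,
    scan_rss_region,
    scan_sequence,
    score_rss,
)


def _brute_force_pvalue(pwm, query):
    """Enumerate all 4^w windows under the background model."""
    total = 0.0
    for seq in itertools.product("ACGT", repeat=pwm.width):
        s = pwm_score(pwm, "".join(seq))
        if s >= query:
            p = 1.0
            for c in seq:
                p *= pwm.background["ACGT".index(c)]
            total += p
    return total


class TestBuildPwm:
    def test_uniform_counts_uniform_background_gives_zero_logodds(self):
        pwm = build_pwm(np.full((3, 4), 5.0), 1.0, np.full(4, 0.25))
        assert np.allclose(pwm.log_odds, 0.0)

    def test_zero_counts_with_pseudocount_equals_background(self):
        pwm = build_pwm(np.zeros((4, 4)), 1.0)
        assert np.allclose(pwm.probs, DEFAULT_BACKGROUND)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_single_column_hand_value(self):
        # A:2 (others 0), pseudocount 1, background A=0.3:
        # p(A) = (2 + 0.3) / 3, log-odds = log2(p / 0.3)
        pwm = build_pwm([[2.0, 0.0, 0.0, 0.0]], 1.0)
        expected_p = 2.3 / 3.0
        assert pwm.probs[0, 0] == pytest.approx(expected_p, abs=1e-12)
        assert pwm.log_odds[0, 0] == pytest.approx(
            math.log2(expected_p / 0.3), abs=1e-12
        )

    def test_all_zero_column_without_pseudocount_is_degenerate(self):
        with pytest.raises(DegenerateModelError):
            build_pwm(np.zeros((2, 4)), 0.0)


class TestPwmScore:
    def test_all_n_window_scores_zero(self):
        pwm = build_pwm(default_heptamer_counts())
        assert pwm_score(pwm, "NNNNNNN") == 0.0

    def test_length_mismatch_rejected(self):
        pwm = build_pwm(default_heptamer_counts())
        with pytest.raises(InputError):
            pwm_score(pwm, "ACGT")

    def test_dinucleotide_scores_match_enumeration(self):
        counts = np.array([[8, 1, 1, 0], [0, 5, 3, 2]], dtype=float)
        pwm = build_pwm(counts, 1.0)
        for a, b in itertools.product("ACGT", repeat=2):
            expected = pwm.log_odds[0, "ACGT".index(a)] + pwm.log_odds[1, "ACGT".index(b)]
            assert pwm_score(pwm, a + b) == pytest.approx(expected, abs=1e-12)

    def test_one_hot_consensus_achieves_maximum(self):
        probs = np.zeros((3, 4))
        probs[:, 0] = 1.0  # AAA, zero pseudocount one-hot
        pwm = Pwm(probs=probs, background=np.full(4, 0.25), pseudocount=0.0)
        assert pwm_score(pwm, "AAA") == pwm.log_odds[:, 0].sum()
        assert pwm_score(pwm, "AAC") == -np.inf


class TestExactPvalue:
    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_matches_brute_force(self, width, rng):
        counts = rng.integers(0, 20, size=(width, 4)).astype(float)
        pwm = build_pwm(counts, 1.0)
        scores = sorted(
            {pwm_score(pwm, "".join(s)) for s in itertools.product("ACGT", repeat=width)}
        )
        for q in scores[::5] + [scores[0], scores[-1]]:
            assert pwm_exact_pvalue(pwm, q) == pytest.approx(
                _brute_force_pvalue(pwm, q), abs=1e-9
            )

    def test_minus_infinity_gives_one(self):
        pwm = build_pwm(default_heptamer_counts())
        assert pwm_exact_pvalue(pwm, -np.inf) == 1.0

    def test_maximum_score_gives_consensus_background_probability(self):
        counts = np.array([[30, 1, 1, 1], [1, 30, 1, 1]], dtype=float)
        pwm = build_pwm(counts, 1.0)
        max_score = pwm.log_odds[0].max() + pwm.log_odds[1].max()
        # only AC achieves the maximum for this strict-max PWM
        assert pwm_exact_pvalue(pwm, max_score) == pytest.approx(
            0.3 * 0.2, abs=1e-12
        )

    def test_monotone_non_increasing(self, rng):
        pwm = build_pwm(rng.integers(0, 9, size=(5, 4)).astype(float))
        grid = np.linspace(-20, 20, 81)
        ps = [pwm_exact_pvalue(pwm, s) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestScanSequence:
    def test_planted_consensus_found_once(self):
        pwm = build_pwm(default_heptamer_counts())
        seq = "TTTTTTTTTT" + "CACAGTG" + "TTTTTTTTTT"
        hits = [h for h in scan_sequence(seq, pwm, p_threshold=1e-4) if h[1] == "+"]
        assert [h[0] for h in hits] == [10]

    def test_palindromic_motif_hits_both_strands(self):
        # CACGTG is its own reverse complement
        counts = np.zeros((6, 4))
        for i, b in enumerate("CACGTG"):
            counts[i, "ACGT".index(b)] = 50
        pwm = build_pwm(counts, 1.0)
        seq = "AAAAA" + "CACGTG" + "AAAAA"
        hits = scan_sequence(seq, pwm, p_threshold=1e-3)
        strands = {h[1] for h in hits if h[0] == 5}
        assert strands == {"+", "-"}

    def test_background_hit_rate_matches_null_expectation(self, rng):
        pwm = build_pwm(default_heptamer_counts())
        scores, tails = pwm.score_distribution()
        # attained size of the p<=1e-3 cut (the score lattice is discrete)
        attained = tails[tails <= 1e-3].max()
        L = 30_000
        seq = "".join(
            rng.choice(list("ACGT"), size=L, p=DEFAULT_BACKGROUND)
        )
        hits = scan_sequence(seq, pwm, p_threshold=1e-3)
        n_windows = 2 * (L - pwm.width + 1)
        expectation = n_windows * attained
        se = math.sqrt(n_windows * attained * (1 - attained))
        assert abs(len(hits) - expectation) < 3 * se

    def test_short_sequence_yields_no_hits(self):
        pwm = build_pwm(default_heptamer_counts())
        assert scan_sequence("ACG", pwm) == []


TOY_HEPT = np.array(
    [[0.7, 0.1, 0.1, 0.1]] * 7
)
TOY_NONA = np.array([[0.25, 0.25, 0.25, 0.25]] * 9)


class TestScoreRss:
    def test_consensus_scores_zero_and_passes(self):
        m = RssModel.default()
        seq = "CACAGTG" + "T" * 12 + "ACAAAAACC"
        hit = score_rss(seq, 0, 12, m)
        assert hit.score == 0.0
        assert hit.passes  # 0 > -38.81
        assert len(hit.interval) == 7 + hit.spacer_length + 9

    def test_zero_probability_base_floors_at_minus_1000(self):
        hept = np.zeros((7, 4))
        for i, b in enumerate("CACAGTG"):
            hept[i, "ACGT".index(b)] = 1.0
        nona = np.zeros((9, 4))
        for i, b in enumerate("ACAAAAACC"):
            nona[i, "ACGT".index(b)] = 1.0
        m = RssModel(heptamer_probs=hept, nonamer_probs=nona)
        seq = "AACAGTG" + "T" * 12 + "ACAAAAACC"  # first base impossible
        hit = score_rss(seq, 0, 12, m)
        assert hit.score == -1000.0
        assert not hit.passes

    def test_single_mismatch_matches_hand_computed_log_ratio(self):
        m = RssModel(heptamer_probs=TOY_HEPT, nonamer_probs=TOY_NONA)
        # consensus of TOY_HEPT is AAAAAAA; one C at position 0 costs
        # log10(0.1 / 0.7); the uniform nonamer contributes 0 everywhere
        seq = "CAAAAAA" + "G" * 12 + "ACAAAAACC"
        hit = score_rss(seq, 0, 12, m)
        assert hit.score == pytest.approx(math.log10(0.1 / 0.7), abs=1e-12)

    def test_out_of_range_offset_rejected(self):
        m = RssModel.default()
        with pytest.raises(InputError):
            score_rss("CACAGTG", 0, 12, m)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_strand_consistency(self, seed):
        """Scoring the reverse complement on the opposite strand is identical.

        The invariant applies per candidate window, so it is checked with
        singleton spacer sets (best-spacer selection over a flexible set is
        anchored at the left edge of the scanned orientation).
        """
        r = np.random.default_rng(seed)
        base = RssModel.default()
        m = RssModel(
            heptamer_probs=base.heptamer_probs,
            nonamer_probs=base.nonamer_probs,
            spacer_lengths_12=frozenset({12}),
            spacer_lengths_23=frozenset({23}),
        )
        seq = "".join(r.choice(list("ACGT"), size=50))
        for rss_type, site_len in ((12, 28), (23, 39)):
            hit_plus = score_rss(seq, 5, rss_type, m, strand="+")
            rc = revcomp(seq)
            offset_rc = len(seq) - 5 - site_len
            hit_minus = score_rss(rc, offset_rc, rss_type, m, strand="-")
            assert hit_minus.score == hit_plus.score

    @given(st.integers(0, 2**31 - 1), st.integers(0, 15))
    @settings(max_examples=25, deadline=None)
    def test_mutating_away_from_modal_base_never_raises_score(self, seed, which):
        r = np.random.default_rng(seed)
        m = RssModel.default()
        site = list("CACAGTG" + "A" * 12 + "ACAAAAACC")
        conserved = list(range(7)) + list(range(19, 28))
        # randomize a few conserved positions first
        for _ in range(3):
            site[conserved[r.integers(16)]] = "ACGT"[r.integers(4)]
        base = score_rss("".join(site), 0, 12, m).score
        pos = conserved[which]
        consensus = ("CACAGTG" + "A" * 12 + "ACAAAAACC")[pos]
        for b in "ACGT":
            if b == consensus:
                continue
            mutated = site.copy()
            mutated[pos] = b
            s = score_rss("".join(mutated), 0, 12, m).score
            if site[pos] == consensus:
                assert s <= base
            assert -1000.0 <= s <= 0.0

    def test_region_scan_agrees_with_scalar_scorer(self, rng):
        m = RssModel.default()
        seq = "".join(rng.choice(list("ACGT"), size=120))
        codes = encode(seq)
        hits = scan_rss_region(codes, m, passing_only=False)
        for h in hits[::17]:
            scalar = score_rss(seq, h.interval.start, h.rss_type, m, strand=h.strand)
            assert np.isclose(h.score, scalar.score, atol=1e-9)


class TestFindRssNearJunctions:
    def test_junction_next_to_planted_consensus_is_flagged(self, small_sim):
        from cutrun.motifs import RssModel

        res = small_sim
        model = RssModel.default()
        labels = res.truth.junction_labels["sj"]
        results = find_rss_near_junctions(
            res.junctions["sj"], res.genome, model, window=100
        )
        flags = np.array([r.has_passing_rss for r in results])
        assert flags[labels].all()

    def test_polya_chromosome_with_cac_free_model_has_no_hits(self):
        from cutrun.core import Junction

        genome = {"chrA": encode("A" * 3000)}
        m = RssModel.default()
        results = find_rss_near_junctions(
            [Junction("chrA", 1500)], genome, m, window=100
        )
        assert not results[0].has_passing_rss

    def test_unknown_chromosome_names_the_junction(self):
        from cutrun.core import Junction

        with pytest.raises(InputError, match="chrZ:5"):
            find_rss_near_junctions(
                [Junction("chrZ", 5)], {"chrA": encode("A" * 2000)}, RssModel.default()
            )

    def test_hits_respect_the_distance_rule(self, small_sim):
        res = small_sim
        results = find_rss_near_junctions(
            res.junctions["control"][:20], res.genome, window=100
        )
        for r in results:
            for h in r.hits:
                assert h.interval.distance_to(r.junction.pos) <= 100
                assert h.passes


class TestModelRoundTrip:
    def test_toml_round_trip_preserves_scores(self, tmp_path, rng):
        m = RssModel.default()
        path = tmp_path / "rss.toml"
        m.to_toml(path)
        m2 = RssModel.from_toml(path)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        for t in (12, 23):
            assert score_rss(seq, 3, t, m).score == score_rss(seq, 3, t, m2).score
        assert m2.threshold_12 == -38.81 and m2.threshold_23 == -58.45
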