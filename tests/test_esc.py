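"""ESC consensus criteria and usage-weighted fraction computation."""

import itertools

import numpy as np
import pytest

from cutrun.core import InputError
from cutrun.esc import (
    EscPair,
    SegmentRss,
    classify_esc,
    enumerate_esc_pairs,
    heptamer_class,
    load_repertoire,
    nonamer_ok,
    renormalize_usage,
    weighted_consensus_fraction,
)
from cutrun.synthetic import simulate_repertoire, write_repertoire_tsv

GOOD_NONAMER = "ACAAAAACC"


def _seg(name, rss_type, heptamer="CACAGTG", nonamer=GOOD_NONAMER, usage=1.0,
         locus="L1", seg_type=None):
    return SegmentRss(
        locus=locus,
        segment=name,
        segment_type=seg_type or ("V" if rss_type == 23 else "J"),
        rss_type=rss_type,
        heptamer=heptamer,
        spacer="A" * rss_type,
        nonamer=nonamer,
        usage_freq=usage,
    )


class TestHeptamerClass:
    @pytest.mark.parametrize(
        "heptamer,expected",
        [
            ("CACAGTG", "consensus"),
            ("CACAATG", "cac_one_mismatch"),  # known alternative heptamer
            ("CACAGCC", "fail"),  # two mismatches vs AGTG
            ("AACAGTG", "fail"),  # CAC prefix absent
            ("CACTGTG", "cac_one_mismatch"),
            ("CACNGTG", "fail"),  # non-ACGT counts as mismatch-from-everything
        ],
    )
    def test_examples(self, heptamer, expected):
        assert heptamer_class(heptamer) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(InputError):
            heptamer_class("CACAGT")


class TestNonamerOk:
    @pytest.mark.parametrize(
        "nonamer,expected",
        [("GGGGAAGGG", True), ("GGGGCAGGG", False), ("ACAAAAACC", True)],
    )
    def test_positions_five_and_six(self, nonamer, expected):
        assert nonamer_ok(nonamer) is expected


class TestClassifyEsc:
    def _pair(self, h1, n1, h2, n2):
        return EscPair(
            segment_a=_seg("a", 12, h1, n1),
            segment_b=_seg("b", 23, h2, n2),
            weight=1.0,
            consensus_match=False,
        )

    def test_double_consensus_passes(self):
        assert classify_esc(self._pair("CACAGTG", GOOD_NONAMER, "CACAGTG", GOOD_NONAMER))

    def test_single_mismatch_heptamer_passes(self):
        assert classify_esc(self._pair("CACAATG", GOOD_NONAMER, "CACAGTG", GOOD_NONAMER))

    def test_bad_nonamer_fails(self):
        assert not classify_esc(
            self._pair("CACAGTG", "ACAACAACC", "CACAGTG", GOOD_NONAMER)
        )

    def test_brute_force_over_all_heptamers_against_consensus(self):
        """Re-implement the criteria from scratch over all 4^7 heptamers."""
        n_pass = 0
        for h in itertools.product("ACGT", repeat=7):
            h = "".join(h)
            ok = h.startswith("CAC") and sum(
                a != b for a, b in zip(h[3:], "AGTG")
            ) <= 1
            got = classify_esc(self._pair(h, GOOD_NONAMER, "CACAGTG", GOOD_NONAMER))
            assert got == ok, h
            n_pass += got
        assert n_pass == 13  # consensus + 12 single-mismatch variants


class TestEnumeratePairs:
    def test_cartesian_product_within_locus(self):
        rep = [_seg(f"V{i}", 23) for i in range(4)] + [_seg(f"J{i}", 12) for i in range(3)]
        assert len(enumerate_esc_pairs(rep)) == 12

    def test_no_cross_locus_pairs(self):
        rep = (
            [_seg("V1", 23, locus="A"), _seg("J1", 12, locus="A")]
            + [_seg("V2", 23, locus="B"), _seg("J2", 12, locus="B")]
        )
        # 2 loci x (1 x 1) each
        pairs = enumerate_esc_pairs(rep)
        assert len(pairs) == 2
        assert all(p.segment_a.locus == p.segment_b.locus for p in pairs)

    def test_uniform_usage_gives_equal_weights(self):
        rep = renormalize_usage(
            [_seg(f"V{i}", 23) for i in range(3)] + [_seg(f"J{i}", 12) for i in range(4)]
        )
        pairs = enumerate_esc_pairs(rep)
        assert all(np.isclose(p.weight, 1 / 12) for p in pairs)

    def test_single_type_locus_yields_no_pairs(self):
        assert enumerate_esc_pairs([_seg("V1", 23)]) == []

    def test_pairing_rules_restrict_types(self):
        rep = [
            _seg("V1", 23, seg_type="V"),
            _seg("J1", 12, seg_type="J"),
            _seg("D1", 12, seg_type="D"),
        ]
        pairs = enumerate_esc_pairs(rep, pairing_rules=[("*", "V", "J")])
        assert len(pairs) == 1
        assert {pairs[0].segment_a.segment, pairs[0].segment_b.segment} == {"V1", "J1"}


class TestWeightedFraction:
    def test_all_matching_gives_one(self):
        rep = renormalize_usage([_seg("V1", 23), _seg("V2", 23), _seg("J1", 12)])
        _, overall = weighted_consensus_fraction(enumerate_esc_pairs(rep))
        assert overall == 1.0

    def test_half_matching_equal_usage_gives_half(self):
        rep = renormalize_usage(
            [
                _seg("V1", 23),
                _seg("V2", 23, heptamer="AAAAAAA"),
                _seg("J1", 12),
            ]
        )
        _, overall = weighted_consensus_fraction(enumerate_esc_pairs(rep))
        assert overall == 0.5

    def test_row_order_permutation_invariant(self, rng):
        segs, _ = simulate_repertoire(10, 6, 0.5, "dirichlet", seed=21)
        base = weighted_consensus_fraction(enumerate_esc_pairs(segs))[1]
        perm = [segs[i] for i in rng.permutation(len(segs))]
        assert weighted_consensus_fraction(enumerate_esc_pairs(perm))[1] == pytest.approx(
            base, abs=1e-15
        )

    def test_usage_rescaling_invariant(self):
        segs, _ = simulate_repertoire(6, 4, 0.5, "dirichlet", seed=3)
        scaled = [
            SegmentRss(
                locus=s.locus, segment=s.segment, segment_type=s.segment_type,
                rss_type=s.rss_type, heptamer=s.heptamer, spacer=s.spacer,
                nonamer=s.nonamer,
                usage_freq=s.usage_freq * (7.0 if s.segment_type == "V" else 0.2),
            )
            for s in segs
        ]
        f1 = weighted_consensus_fraction(enumerate_esc_pairs(renormalize_usage(segs)))[1]
        f2 = weighted_consensus_fraction(enumerate_esc_pairs(renormalize_usage(scaled)))[1]
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_matches_generator_truth_exactly(self):
        for seed in (0, 1, 2):
            segs, expected = simulate_repertoire(15, 5, 0.6, "dirichlet", seed=seed)
            _, overall = weighted_consensus_fraction(enumerate_esc_pairs(segs))
            assert overall == pytest.approx(expected, abs=1e-15)


class TestLoadRepertoire:
    def test_synthetic_file_round_trips(self, tmp_path):
        segs, _ = simulate_repertoire(8, 4, 0.7, "dirichlet", seed=5)
        path = tmp_path / "rep.tsv"
        write_repertoire_tsv(segs, path)
        loaded = load_repertoire(path)
        assert len(loaded) == 12
        f_direct = weighted_consensus_fraction(enumerate_esc_pairs(segs))[1]
        f_loaded = weighted_consensus_fraction(enumerate_esc_pairs(loaded))[1]
        assert f_loaded == pytest.approx(f_direct, abs=1e-12)

    def test_bad_heptamer_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "locus\tsegment\tsegment_type\trss_type\theptamer\tspacer\tnonamer\tusage_freq\n"
            "L1\tV1\tV\t23\tCACAGT\t" + "A" * 23 + "\tACAAAAACC\t0.5\n"
        )
        with pytest.raises(InputError, match="line 2"):
            load_repertoire(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("locus\tsegment\n")
        with pytest.raises(InputError, match="missing columns"):
            load_repertoire(path)

    def test_prenormalized_usage_unchanged(self, tmp_path):
        segs = [
            _seg("V1", 23, usage=0.2),
            _seg("V2", 23, usage=0.3),
            _seg("V3", 23, usage=0.5),
            _seg("J1", 12, usage=1.0),
        ]
        path = tmp_path / "rep.tsv"
        write_repertoire_tsv(segs, path)
        loaded = load_repertoire(path)
        assert [s.usage_freq for s in loaded[:3]] == pytest.approx([0.2, 0.3, 0.5])
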