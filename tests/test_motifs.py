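"""Motif shape enumeration, parsing, matching and the lazy count matrix."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepmotifs.motifs import (
    GAP_MAX,
    MAX_SPAN,
    MotifError,
    MotifPattern,
    count_matrix,
    enumerate_shapes,
    find_occurrences,
    format_motif,
    parse_motif,
)

from .conftest import make_records, regex_starts


class TestEnumerateShapes:
    @pytest.mark.parametrize("k,expected", [(2, 4), (3, 16), (4, 27), (5, 5)])
    def test_counts(self, k, expected):
        assert len(enumerate_shapes(k)) == expected

    def test_bigram_shapes_explicit(self):
        assert enumerate_shapes(2) == [(0,), (1,), (2,), (3,)]

    def test_matches_brute_force(self):
        """Per-slot gap bounds + span cap, re-derived by raw enumeration."""
        for k in (2, 3, 4):
            brute = [
                g
                for g in itertools.product(range(GAP_MAX[k] + 1), repeat=k - 1)
                if k + sum(g) <= MAX_SPAN
            ]
            assert enumerate_shapes(k) == sorted(brute)
        brute5 = [
            g
            for g in itertools.product(range(2), repeat=4)
            if sum(g) <= 1 and 5 + sum(g) <= MAX_SPAN
        ]
        assert enumerate_shapes(5) == sorted(brute5)

    def test_span_bound_and_lysine_tetragram_shape(self):
        all_shapes = [(k, g) for k in (2, 3, 4, 5) for g in enumerate_shapes(k)]
        assert len(all_shapes) == 52
        assert all(k + sum(g) <= MAX_SPAN for k, g in all_shapes)
        # the widest tetragram shape K__K__K__K has span exactly 10
        assert (2, 2, 2) in enumerate_shapes(4)

    @pytest.mark.parametrize("k", [1, 6, 0])
    def test_invalid_k(self, k):
        with pytest.raises(MotifError):
            enumerate_shapes(k)


class TestParseFormat:
    @pytest.mark.parametrize(
        "text,classes,gaps",
        [
            ("S_S", ("S", "S"), (1,)),
            ("L___L", ("L", "L"), (3,)),
            ("SS", ("S", "S"), (0,)),
            ("[AVIL]__[AVIL][AVIL]", ("AVIL", "AVIL", "AVIL"), (2, 0)),
            ("K__K__K__K", ("K", "K", "K", "K"), (2, 2, 2)),
        ],
    )
    def test_parse(self, text, classes, gaps):
        p = parse_motif(text)
        assert p.classes == tuple(frozenset(c) for c in classes)
        assert p.gaps == gaps

    @pytest.mark.parametrize(
        "bad", ["_AB", "AB_", "A", "", "A_b", "[]A", "ABCDEF", "S____S", "A_____B"]
    )
    def test_malformed(self, bad):
        with pytest.raises(MotifError):
            parse_motif(bad)

    def test_round_trip_all_shapes(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for k in (2, 3, 4, 5):
            for gaps in enumerate_shapes(k):
                classes = tuple(
                    frozenset(rng.choice(letters, size=1)) for _ in range(k)
                )
                p = MotifPattern(classes, gaps)
                assert parse_motif(format_motif(p)) == p

    def test_inadmissible_shape_rejected(self):
        with pytest.raises(MotifError):
            MotifPattern((frozenset("K"),) * 5, (1, 1, 0, 0))


class TestFindOccurrences:
    def test_hand_checked(self):
        res = find_occurrences("MASSS", parse_motif("S_S"))
        assert res.starts == (2,)

    def test_overlaps_counted(self):
        res = find_occurrences("LLLL", parse_motif("LL"))
        assert res.starts == (0, 1, 2)

    def test_span_longer_than_sequence(self):
        assert find_occurrences("KK", parse_motif("K__K")).count == 0

    def test_class_membership(self):
        res = find_occurrences("VSLIA", parse_motif("[AVIL]_[AVIL]"))
        assert res.starts == (0, 2)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_regex_oracle(self, data):
        """Property: identical starts to the lookahead-regex oracle."""
        alpha = data.draw(st.sampled_from(["ASLK", "ACDEFGHIKL", "KR"]))
        seq = data.draw(st.text(alphabet=alpha, min_size=0, max_size=30))
        k = data.draw(st.sampled_from([2, 3, 4, 5]))
        gaps = data.draw(st.sampled_from(enumerate_shapes(k)))
        classes = tuple(
            frozenset(data.draw(st.sets(st.sampled_from(alpha), min_size=1, max_size=2)))
            for _ in range(k)
        )
        pat = MotifPattern(classes, gaps)
        assert list(find_occurrences(seq, pat).starts) == regex_starts(seq, pat)


class TestCountMatrix:
    def test_single_record(self):
        cm = count_matrix(make_records(["SS"]), k_range=(2,))
        assert cm.motif_strings() == ["SS"]
        assert cm.matrix.toarray().tolist() == [[1]]

    def test_presence_column_sums(self):
        cm = count_matrix(make_records(["SSA", "ASA", "AAA"]), k_range=(2,))
        assert cm.row_by_string("SS").sum() == 1

    def test_planted_presence_row_sum(self, rng):
        """LR planted in exactly 37 of 100 L/R-free sequences is recovered."""
        seqs = ["".join(rng.choice(list("ASG"), size=20)) for _ in range(100)]
        chosen = rng.choice(100, size=37, replace=False)
        for i in chosen:
            s = list(seqs[i])
            pos = int(rng.integers(0, 19))
            s[pos : pos + 2] = "LR"
            seqs[i] = "".join(s)
        cm = count_matrix(make_records(seqs), k_range=(2,), mode="presence")
        assert cm.row_by_string("LR").sum() == 37

    def test_count_dominates_presence(self, rng):
        seqs = ["".join(rng.choice(list("ASLK"), size=25)) for _ in range(30)]
        recs = make_records(seqs)
        pres = count_matrix(recs, k_range=(2, 3), mode="presence")
        cnt = count_matrix(recs, k_range=(2, 3), mode="count")
        assert pres.motif_keys == cnt.motif_keys
        assert (cnt.matrix.toarray() >= pres.matrix.toarray()).all()

    def test_no_unobserved_motifs(self, rng):
        """Lazy instantiation: every row has at least one nonzero entry."""
        seqs = ["".join(rng.choice(list("AS"), size=15)) for _ in range(10)]
        cm = count_matrix(make_records(seqs), k_range=(2, 3, 4, 5))
        assert (np.asarray(cm.matrix.sum(axis=1)).ravel() > 0).all()
        # two letters only: no motif may contain any other residue
        assert all(set(key[2]) <= set("AS") for key in cm.motif_keys)

    def test_deterministic_row_order(self, rng):
        seqs = ["".join(rng.choice(list("ASLK"), size=20)) for _ in range(20)]
        a = count_matrix(make_records(seqs), k_range=(2, 3))
        b = count_matrix(make_records(seqs), k_range=(2, 3))
        assert a.motif_keys == b.motif_keys
        ks = [key[0] for key in a.motif_keys]
        assert ks == sorted(ks)

    def test_subpattern_monotonicity(self, rng):
        """Presence of (c1,c2,c3; g1,g2) never exceeds that of either
        constituent bigram."""
        seqs = ["".join(rng.choice(list("ASL"), size=30)) for _ in range(40)]
        recs = make_records(seqs)
        cm = count_matrix(recs, k_range=(2, 3), mode="presence")
        tri = [key for key in cm.motif_keys if key[0] == 3][:100]
        for k, gaps, chars in tri:
            tri_n = cm.row((k, gaps, chars)).sum()
            left = cm.row((2, (gaps[0],), chars[:2])).sum()
            right = cm.row((2, (gaps[1],), chars[1:])).sum()
            assert tri_n <= min(left, right)

    def test_empty_records(self):
        cm = count_matrix([], k_range=(2,))
        assert cm.matrix.shape == (0, 0)

    def test_invalid_k_range(self):
        with pytest.raises(MotifError):
            count_matrix(make_records(["AAAA"]), k_range=(1, 2))
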