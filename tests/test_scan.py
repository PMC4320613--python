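"""Purine-rich acceptor scan: fractions, G tracts, groups, profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_window, naive_g_tracts, naive_purine_fraction
from repa.scan import (classify_group, find_g_tracts, first_g_histogram,
                       is_repa_candidate, position_profile, purine_fraction,
                       read_calls_tsv, run_length_distribution, scan_windows,
                       write_calls_tsv, call_site, GTract, RepaCall)

CAMK1 = "GTCTTGGGGGTTTAG"
ABCC11 = "TTCTGGGAAACGAAG"

windows_st = st.text(alphabet="ACGT", min_size=15, max_size=15)


class TestPurineFraction:
    @pytest.mark.parametrize(
        "seq,expected",
        [(CAMK1, 5 / 8), (ABCC11, 7 / 8), ("TTTTTTTTTTTCCAG", 0.0)],
    )
    def test_hand_counts(self, seq, expected):
        assert purine_fraction(make_window(seq), -10, -3) == pytest.approx(expected)

    def test_n_bases_removed_from_denominator(self):
        w = make_window("TTTTTNNGGGGTTAG")
        # -10..-3 covers TNNGGGGT: 4 purines over 6 informative
        assert purine_fraction(w, -10, -3) == pytest.approx(4 / 6)

    def test_all_n_range_is_nan(self):
        w = make_window("TTTTT" + "N" * 8 + "AG")
        assert math.isnan(purine_fraction(w, -10, -3))

    def test_range_outside_window_errors(self):
        with pytest.raises(IndexError):
            purine_fraction(make_window("TTAG"), -10, -3)

    @settings(derandomize=True, max_examples=200)
    @given(windows_st)
    def test_matches_hand_count(self, seq):
        assert purine_fraction(make_window(seq), -10, -3) == pytest.approx(
            naive_purine_fraction(seq)
        )


class TestRepaCandidate:
    def test_camk1_is_candidate(self):
        assert is_repa_candidate(make_window(CAMK1))

    def test_pyrimidine_acceptor_is_not(self):
        assert not is_repa_candidate(make_window("TTTTTTTTTTTCCAG"))

    def test_strict_threshold_four_of_eight_fails(self):
        # AAAA at -10..-7, pyrimidines at -6..-3: exactly 4/8 = 0.50
        assert not is_repa_candidate(make_window("TTTTTAAAATTTCAG"))
        # 5/8 = 0.625 passes
        assert is_repa_candidate(make_window("TTTTTAAAAATTCAG"))

    def test_non_ag_acceptor_never_candidate(self):
        assert not is_repa_candidate(make_window("TTTTTAAAAAAAAAC"))

    def test_truncated_window_false(self):
        w = make_window("TTTAG")
        w = w.__class__(**{**w.__dict__, "truncated": True})
        assert not is_repa_candidate(w)

    @settings(derandomize=True, max_examples=200)
    @given(windows_st)
    def test_threshold_monotonicity(self, seq):
        """Raising the purine threshold never gains candidates."""
        w = make_window(seq)
        calls = [is_repa_candidate(w, t) for t in (0.3, 0.6, 0.9)]
        assert calls == sorted(calls, reverse=True)


class TestGTracts:
    def test_camk1_single_pentamer(self):
        (t,) = find_g_tracts(make_window(CAMK1))
        assert (t.first_g_position, t.length, t.over_cap) == (-10, 5, False)

    def test_abcc11_trimer(self):
        (t,) = find_g_tracts(make_window(ABCC11))
        assert (t.first_g_position, t.length) == (-11, 3)

    def test_maximal_run_over_cap(self):
        (t,) = find_g_tracts(make_window("GGGGGGGGGGGGGAG"))
        assert (t.first_g_position, t.length, t.over_cap) == (-15, 13, True)

    def test_run_invading_ag_excluded(self):
        # G run ends at -2: touches the acceptor, must not be reported
        assert find_g_tracts(make_window("TTTTTTTTTTGGGAG"[:-2] + "AG")) == \
            find_g_tracts(make_window("TTTTTTTTTTGGGAG"))
        assert find_g_tracts(make_window("TTTTTTTTTGGGGAG")) != []
        assert find_g_tracts(make_window("TTTTTTTTTTTGGAG")) == []

    def test_multiple_tracts_sorted(self):
        tracts = find_g_tracts(make_window("GGGTTGGGGTTTCAG"))
        assert [(t.first_g_position, t.length) for t in tracts] == \
            [(-15, 3), (-10, 4)]

    @settings(derandomize=True, max_examples=300)
    @given(windows_st)
    def test_matches_regex_oracle(self, seq):
        ours = [(t.first_g_position, t.length)
                for t in find_g_tracts(make_window(seq))]
        assert ours == naive_g_tracts(seq)


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "seq,label",
        [
            (CAMK1, "ggggg"),
            ("TTTTGAAAATTTCAG", "gaaaa"),
            ("TTTGTGGAATTTCAG", "gtggaa"),
            ("TTTTTTTTTTTTCAG", "other"),
            ("TTTTTTTTTTTTAAG", "nnnrag"),  # purine at -3, no literal motif
        ],
    )
    def test_literal_and_fallback_labels(self, seq, label):
        assert classify_group(make_window(seq)) == label

    def test_precedence_on_multi_match(self):
        # contains both GGGGG and GGAAA; gtggaa > ggggg > ggaaa
        assert classify_group(make_window("TTGGGGGGAAATCAG")) == "ggggg"

    def test_motif_must_lie_within_minus12_minus3(self):
        # GGGGG only at -15..-11: outside the classification region
        assert classify_group(make_window("GGGGGTTTTTTTCAG")) == "other"


class TestProfile:
    def test_single_window_indicator(self):
        prof = position_profile([make_window("ACGTA")])
        assert prof.n_sites == 1
        assert prof.freq.loc[-5, "A"] == 1.0
        assert prof.freq.loc[-3, "G"] == 1.0

    def test_union_is_weighted_mean(self):
        a = [make_window("AAAAA"), make_window("CCCCC")]
        b = [make_window("GGGGG")]
        both = position_profile(a + b)
        pa, pb = position_profile(a), position_profile(b)
        expected = (pa.counts + pb.counts)
        assert (both.counts == expected).all().all()

    def test_mixed_spans_rejected(self):
        with pytest.raises(ValueError):
            position_profile([make_window("ACGT"), make_window("ACGTA")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            position_profile([])

    def test_constitutive_marginal_near_20pct(self, small_genome):
        """Planted constitutive windows average ~20% A/G at -10..-3."""
        from repa.annotation import derive_introns, extract_windows

        introns = derive_introns(small_genome.models)
        windows, _ = extract_windows(small_genome.genome, introns)
        truth = small_genome.truth.set_index("site_id")
        const = [w for w in windows
                 if w.site_id in truth.index and not truth.loc[w.site_id].is_repa]
        prof = position_profile(const)
        marginal = prof.purine_fraction.loc[list(range(-10, -2))]
        assert len(const) > 150
        assert abs(marginal.mean() - 0.20) < 0.03

    def test_repa_marginal_purine_rich(self, small_genome):
        from repa.annotation import derive_introns, extract_windows

        introns = derive_introns(small_genome.models)
        windows, _ = extract_windows(small_genome.genome, introns)
        truth = small_genome.truth.set_index("site_id")
        repa = [w for w in windows
                if w.site_id in truth.index and truth.loc[w.site_id].is_repa]
        prof = position_profile(repa)
        marginal = prof.purine_fraction.loc[list(range(-10, -2))]
        assert marginal.mean() > 0.6


class TestHistograms:
    def _calls(self, specs):
        return [
            RepaCall(f"s{i}", 1.0, True, "other",
                     tuple(GTract(p, l) for p, l in tracts))
            for i, tracts in enumerate(specs)
        ]

    def test_singleton(self):
        h = first_g_histogram(self._calls([[(-8, 3)]]))
        assert dict(h) == {-8: 1}

    def test_five_prime_most_tract_wins(self):
        h = first_g_histogram(self._calls([[(-11, 3), (-6, 3)]]))
        assert dict(h) == {-11: 1}

    def test_planted_mixture_recovered(self, small_genome):
        from repa.annotation import derive_introns, extract_windows

        introns = derive_introns(small_genome.models)
        windows, _ = extract_windows(small_genome.genome, introns)
        calls = [c for c in scan_windows(windows) if c.is_repa]
        truth = small_genome.truth
        planted = truth[truth.is_repa]
        h = first_g_histogram(calls)
        expected = planted.tract_first_g.value_counts()
        assert dict(h) == {int(k): int(v) for k, v in expected.items()}
        rl = run_length_distribution(calls)
        expected_rl = planted.tract_length.value_counts()
        assert dict(rl) == {int(k): int(v) for k, v in expected_rl.items()}
        assert int(h.sum()) == len(planted)


def test_calls_tsv_roundtrip(tmp_path):
    calls = [call_site(make_window(CAMK1, site_id="chr1:+:100")),
             call_site(make_window("TTTTTTTTTTTCCAG", site_id="chr1:-:200"))]
    p = tmp_path / "calls.tsv"
    write_calls_tsv(calls, p)
    assert read_calls_tsv(p) == calls
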