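"""Marker-state calling, segmentation and CO/NCO / SGC/BIR classification."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magrec.segment import (
    ClassifierConfig,
    MarkerState,
    call_marker_states,
    classify_diploid_loh,
    classify_spore_recombination,
    segment_genotypes,
    subtract_control_events,
)

CFG = ClassifierConfig()


def marker_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "count_S", "count_K"])


def states_from(pattern, spacing=200, chrom="chrI", start=0):
    """MarkerState list from a compact string like 'SSKKS'."""
    out = []
    for i, ch in enumerate(pattern):
        st_ = {"S": "S", "K": "K", "H": "HET", ".": "MISSING"}[ch]
        out.append(MarkerState(chrom, start + i * spacing, st_, 0.5, 30))
    return out


class TestMarkerStates:
    @pytest.mark.parametrize(
        "cs,ck,expected",
        [
            (15, 15, "HET"),
            (0, 20, "K"),
            (20, 0, "S"),
            (2, 1, "MISSING"),  # below min_depth 5
            (1, 19, "K"),  # af 0.95
            (4, 16, "MISSING"),  # af 0.8: between het band and pure
        ],
    )
    def test_state_assignment(self, cs, ck, expected):
        df = marker_frame([("chrI", 100, cs, ck)])
        [state] = call_marker_states(df, CFG)
        assert state.state == expected

    def test_threshold_semantics_by_enumeration(self):
        # every count pair up to depth 40 obeys the banding rules exactly
        for cs, ck in itertools.product(range(0, 21), repeat=2):
            df = marker_frame([("chrI", 100, cs, ck)])
            [state] = call_marker_states(df, CFG)
            total = cs + ck
            if total < CFG.min_depth:
                assert state.state == "MISSING"
                continue
            af = ck / total
            if af >= CFG.loh_af:
                assert state.state == "K"
            elif af <= 1 - CFG.loh_af:
                assert state.state == "S"
            elif CFG.het_band[0] <= af <= CFG.het_band[1]:
                assert state.state == "HET"
            else:
                assert state.state == "MISSING"

    def test_allele_fraction_recorded_even_for_missing(self):
        df = marker_frame([("chrI", 100, 2, 1)])
        [state] = call_marker_states(df, CFG)
        assert state.allele_fraction == pytest.approx(1 / 3)

    def test_unsorted_input_rejected(self):
        df = marker_frame([("chrI", 200, 10, 10), ("chrI", 100, 10, 10)])
        with pytest.raises(ValueError):
            call_marker_states(df, CFG)

    def test_negative_counts_rejected(self):
        df = marker_frame([("chrI", 100, -1, 10)])
        with pytest.raises(ValueError):
            call_marker_states(df, CFG)


class TestSegmentation:
    def test_run_length_segmentation(self):
        segs = segment_genotypes(states_from("SSSKKSS"), CFG)
        assert [(s.state, s.n_markers) for s in segs] == [("S", 3), ("K", 2), ("S", 2)]

    def test_singleton_absorbed_when_flanks_agree(self):
        segs = segment_genotypes(states_from("SSKSS"), CFG)
        assert len(segs) == 1
        assert segs[0].state == "S"

    def test_all_missing_gives_empty_list(self):
        assert segment_genotypes(states_from("....."), CFG) == []

    def test_missing_markers_do_not_break_runs(self):
        segs = segment_genotypes(states_from("SS..SS"), CFG)
        assert len(segs) == 1 and segs[0].n_markers == 4

    def test_terminal_short_run_kept_low_confidence(self):
        segs = segment_genotypes(states_from("SSSSK"), CFG)
        assert [s.state for s in segs] == ["S", "K"]
        assert segs[1].low_confidence

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("SKH."), min_size=1, max_size=40))
    def test_segmentation_idempotent(self, chars):
        segs = segment_genotypes(states_from("".join(chars)), CFG)
        # rebuild states implied by the segments and re-segment
        implied = []
        for s in segs:
            state_char = {"S": "S", "K": "K", "HET": "H"}[s.state]
            implied.extend([state_char] * s.n_markers)
        segs2 = segment_genotypes(states_from("".join(implied)), CFG)
        assert [(s.state, s.n_markers, s.low_confidence) for s in segs] == [
            (s.state, s.n_markers, s.low_confidence) for s in segs2
        ]


class TestSporeClassification:
    def _classify(self, pattern, spacing):
        segs = segment_genotypes(states_from(pattern, spacing=spacing), CFG)
        return classify_spore_recombination(segs, CFG)

    def test_short_interstitial_tract_is_one_nco(self):
        # K tract of 3 markers over 1 kb inside S background
        events, counts = self._classify("SSSSKKKSSSS", spacing=500)
        kinds = [e.kind for e in events]
        assert kinds.count("NCO") == 1 and kinds.count("CO") == 0
        assert counts["chrI"] == 0

    def test_single_switch_is_one_co(self):
        events, counts = self._classify("SSSSKKKK", spacing=500)
        kinds = [e.kind for e in events]
        assert kinds == ["CO"] and counts["chrI"] == 1

    def test_tract_at_threshold_counts_as_two_switches(self):
        # 6-marker K tract spanning 2 kb-per-marker = 10 kb >= 5 kb
        events, counts = self._classify("SSSSKKKKSSSS", spacing=2000)
        kinds = [e.kind for e in events]
        assert kinds.count("CO") == 2 and kinds.count("NCO") == 0
        assert counts["chrI"] == 2

    def test_co_breakpoint_interval_spans_flanking_markers(self):
        events, _ = self._classify("SSKK", spacing=1000)
        [co] = events
        assert (co.start, co.end) == (1000, 2001)

    def test_switch_count_equals_segments_minus_one_without_ncos(self):
        events, counts = self._classify("SSSSKKKKKKSSSSSSKKKK", spacing=2000)
        assert counts["chrI"] == 3
        assert all(e.kind == "CO" for e in events)

    def test_het_chromosome_skipped(self):
        segs = segment_genotypes(states_from("HHHHH"), CFG)
        events, counts = classify_spore_recombination(segs, CFG)
        assert events == [] and counts["chrI"] == 0

    def test_raising_nco_threshold_never_increases_co_count(self):
        patterns = ["SSKKSS", "SKKKKS", "SSSKKKKKSSS", "SKSKSK", "SSKKKKKKSS"]
        for pattern in patterns:
            for spacing in (300, 900, 1500):
                last = None
                for thresh in (1000, 3000, 5000, 10_000):
                    cfg = ClassifierConfig(nco_max_len=thresh)
                    segs = segment_genotypes(states_from(pattern, spacing=spacing), cfg)
                    _, counts = classify_spore_recombination(segs, cfg)
                    if last is not None:
                        assert counts["chrI"] <= last
                    last = counts["chrI"]


class TestDiploidLoh:
    def test_terminal_tract_is_bir(self):
        segs = segment_genotypes(states_from("HHHHSSS", spacing=5000), CFG)
        events, flag = classify_diploid_loh(segs, CFG)
        assert not flag
        assert [e.kind for e in events] == ["BIR"]
        assert events[0].attrs["donor"] == "S"

    def test_interstitial_tract_is_sgc(self):
        segs = segment_genotypes(states_from("HHHKKHHH", spacing=500), CFG)
        events, flag = classify_diploid_loh(segs, CFG)
        assert [e.kind for e in events] == ["SGC"]

    def test_all_het_gives_no_events(self):
        segs = segment_genotypes(states_from("HHHHHH"), CFG)
        events, flag = classify_diploid_loh(segs, CFG)
        assert events == [] and not flag

    def test_no_het_anywhere_raises_haploidization_candidate(self):
        segs = segment_genotypes(states_from("SSSSSS"), CFG)
        events, flag = classify_diploid_loh(segs, CFG)
        assert events == [] and flag

    def test_exhaustive_small_patterns_follow_terminal_rule(self):
        # every {H,S,K} pattern of length <= 5: LOH runs touching either
        # end are BIR, interstitial runs are SGC
        for n in range(1, 6):
            for pattern in itertools.product("HSK", repeat=n):
                pattern = "".join(pattern)
                segs = segment_genotypes(states_from(pattern, spacing=3000), CFG)
                events, flag = classify_diploid_loh(segs, CFG)
                confident = [s for s in segs if not s.low_confidence]
                if confident and not any(s.state == "HET" for s in confident):
                    assert flag and events == []
                    continue
                assert not flag
                exp = []
                for i, s in enumerate(confident):
                    if s.state in ("S", "K"):
                        exp.append(
                            "BIR" if i in (0, len(confident) - 1) else "SGC"
                        )
                assert sorted(e.kind for e in events) == sorted(exp)


class TestControlSubtraction:
    def test_identical_event_removed(self):
        segs = segment_genotypes(states_from("HHHKKHHH", spacing=500), CFG)
        events, _ = classify_diploid_loh(segs, CFG)
        kept, removed = subtract_control_events(events, list(events), CFG)
        assert kept == [] and len(removed) == len(events)

    def test_empty_control_returns_input(self):
        segs = segment_genotypes(states_from("HHHKKHHH", spacing=500), CFG)
        events, _ = classify_diploid_loh(segs, CFG)
        kept, removed = subtract_control_events(events, [], CFG)
        assert kept == events and removed == []

    def test_nearby_event_retained_at_zero_tolerance(self):
        segs = segment_genotypes(states_from("HHHKKHHH", spacing=500), CFG)
        events, _ = classify_diploid_loh(segs, CFG)
        shifted = [
            type(e)(e.kind, e.chrom, e.start + 50, e.end + 50, attrs=dict(e.attrs))
            for e in events
        ]
        kept, removed = subtract_control_events(events, shifted, CFG)
        assert kept == events
        cfg = ClassifierConfig(control_tolerance=100)
        kept2, removed2 = subtract_control_events(events, shifted, cfg)
        assert kept2 == []
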