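"""HE event calling, founding-pattern grouping and chromosome tallies."""

import itertools

import pytest

from musakaryo.chromosomes import ChromosomeSpec
from musakaryo.karyotype import DosageSegment
from musakaryo.patterns import (
    HEEvent,
    call_he_events,
    chromosome_counts,
    count_unique_hes,
    group_patterns,
    load_pattern_events,
    load_table1_fixture,
    locate_region,
    match_event,
)


CHR = ChromosomeSpec("chr01", 30_000_000, 13_000_000)


class TestLocateRegion:
    def test_segment_reaching_chromosome_start_is_terminal_first_arm(self):
        assert locate_region(1, 5_000_000, CHR) == ("first", "terminal")

    def test_interior_first_arm_segment_is_interstitial(self):
        assert locate_region(10_000_000, 12_000_000, CHR) == ("first", "interstitial")

    def test_full_chromosome_segment_is_whole_chromosome(self):
        assert locate_region(1, CHR.length, CHR) == ("spanning", "whole_chromosome")

    def test_second_arm_terminal(self):
        assert locate_region(20_000_000, CHR.length, CHR) == ("second", "terminal")

    def test_centromere_crossing_segment_spans_arms(self):
        assert locate_region(10_000_000, 20_000_000, CHR) == ("spanning", "interstitial")

    def test_midpoint_fallback_without_centromere(self):
        chrom = ChromosomeSpec("chr02", 20_000_000)
        assert locate_region(12_000_000, 15_000_000, chrom) == ("second", "interstitial")

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            locate_region(0, 5, CHR)


def _seg(chrom, start, end, a, b):
    return DosageSegment(chrom, start, end, a, b, 1.0)


class TestCallHEEvents:
    def test_baseline_karyotype_produces_nothing(self, chroms):
        kar = [_seg(c.name, 1, c.length, 1, 2) for c in chroms]
        hes, aneu = call_he_events(kar, 3, chroms)
        assert hes == [] and aneu == []

    def test_whole_chromosome_copy_loss_is_aneuploidy_not_he(self, chroms):
        chr08 = next(c for c in chroms if c.name == "chr08")
        kar = [_seg(c.name, 1, c.length, 1, 2) for c in chroms if c.name != "chr08"]
        kar.append(_seg("chr08", 1, chr08.length, 0, 2))
        hes, aneu = call_he_events(kar, 3, chroms)
        assert hes == []
        assert len(aneu) == 1 and aneu[0].locclass == "whole_chromosome"

    def test_terminal_substitution_is_an_he_event(self, chroms):
        chr11 = next(c for c in chroms if c.name == "chr11")
        kar = [_seg(c.name, 1, c.length, 1, 2) for c in chroms if c.name != "chr11"]
        kar.append(_seg("chr11", 1, 17_000_000, 1, 2))
        kar.append(_seg("chr11", 17_000_001, chr11.length, 0, 3))
        hes, aneu = call_he_events(kar, 3, chroms)
        assert aneu == []
        assert len(hes) == 1
        assert (hes[0].arm, hes[0].locclass) == ("second", "terminal")

    def test_invalid_ploidy_rejected(self, chroms):
        with pytest.raises(ValueError):
            call_he_events([], 4, chroms)


def _ev(chrom="chr04", start=22_000_001, end=32_000_000, a=0, b=3,
        arm="second", locclass="terminal"):
    return HEEvent(chrom, start, end, a, b, arm, locclass)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=100)
@given(
    s1=st.integers(1, 10_000_000),
    s2=st.integers(1, 10_000_000),
    tol=st.integers(0, 2_000_000),
)
def test_match_event_is_symmetric(s1, s2, tol):
    """Event matching never depends on argument order."""
    e1 = _ev(start=s1, end=s1 + 5_000_000)
    e2 = _ev(start=s2, end=s2 + 5_000_000)
    assert match_event(e1, e2, tol) == match_event(e2, e1, tol)


class TestMatchEvent:
    def test_identical_events_match(self):
        assert match_event(_ev(), _ev())

    def test_different_states_never_match(self):
        assert not match_event(_ev(a=0, b=3), _ev(a=2, b=1))

    def test_breakpoint_offset_at_tolerance_boundary(self):
        tol = 1_000_000
        assert match_event(_ev(), _ev(start=22_000_001 + tol), breakpoint_tolerance=tol)
        assert not match_event(
            _ev(), _ev(start=22_000_001 + tol + 1), breakpoint_tolerance=tol
        )

    def test_locclass_must_agree(self):
        assert not match_event(_ev(), _ev(locclass="interstitial"))


class TestGroupPatterns:
    def test_identical_event_sets_form_one_group(self):
        events = {"acc1": [_ev()], "acc2": [_ev(start=22_500_001)]}
        groups = group_patterns(events)
        assert len(groups) == 1
        assert groups[0].members == ["acc1", "acc2"]

    def test_fixture_patterns_1a_1b_1c_are_three_distinct_groups(self):
        fixture = load_pattern_events()
        events = {f"acc_{p}": fixture[p][1] for p in ("1a", "1b", "1c")}
        groups = group_patterns(events)
        assert len(groups) == 3
        # the three patterns share the chr04/chr11 terminal substitutions
        # and the chr09 interstitial A2:B1 region
        shared = [
            e
            for e in groups[0].canonical_events
            if all(
                any(match_event(e, f) for f in g.canonical_events) for g in groups
            )
        ]
        assert {e.chrom for e in shared} == {"chr04", "chr09", "chr11"}

    def test_aneuploid_accession_groups_by_he_signature_with_flag(self):
        events = {"plain": [_ev()], "aneuploid": [_ev()]}
        groups = group_patterns(events, aneuploid_accessions={"aneuploid"})
        assert len(groups) == 1
        assert groups[0].aneuploid_members == ["aneuploid"]

    def test_grouping_invariant_to_input_and_event_order(self):
        fixture = load_pattern_events()
        base = {f"acc_{p}": fixture[p][1] for p in ("1a", "1b", "1c", "4", "5")}
        reference = [
            (g.pattern_id, tuple(g.members)) for g in group_patterns(base)
        ]
        for perm_seed in range(3):
            import random

            r = random.Random(perm_seed)
            keys = list(base)
            r.shuffle(keys)
            shuffled = {}
            for k in keys:
                evs = list(base[k])
                r.shuffle(evs)
                shuffled[k] = evs
            assert [
                (g.pattern_id, tuple(g.members)) for g in group_patterns(shuffled)
            ] == reference

    def test_mixed_baselines_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            group_patterns({"a": [], "b": []}, baselines={"a": 2, "b": 3})


class TestCountUniqueHEs:
    def test_disjoint_groups_sum(self):
        from musakaryo.patterns import HEPatternGroup

        g1 = HEPatternGroup("G1", ["a"], [_ev(chrom=c) for c in ("chr01", "chr02", "chr03")])
        g2 = HEPatternGroup(
            "G2", ["b"], [_ev(chrom=c) for c in ("chr04", "chr05", "chr06", "chr07")]
        )
        assert count_unique_hes([g1, g2]) == 7

    def test_shared_event_counted_once(self):
        from musakaryo.patterns import HEPatternGroup

        shared = _ev(chrom="chr09")
        g1 = HEPatternGroup("G1", ["a"], [shared, _ev(chrom="chr01"), _ev(chrom="chr02")])
        g2 = HEPatternGroup("G2", ["b"], [shared, _ev(chrom="chr03"), _ev(chrom="chr04")])
        assert count_unique_hes([g1, g2]) == 5

    def test_matches_brute_force_transitive_closure(self, rng):
        from musakaryo.patterns import HEPatternGroup

        tol = 1_000_000
        for trial in range(10):
            events = []
            for _ in range(int(rng.integers(3, 9))):
                events.append(
                    _ev(
                        chrom=f"chr{rng.integers(1, 4):02d}",
                        start=int(rng.integers(1, 5)) * 700_000 + 1,
                        end=10_000_000 + int(rng.integers(1, 5)) * 700_000,
                        arm="first",
                        locclass="interstitial",
                    )
                )
            k = int(rng.integers(1, len(events) + 1))
            g1 = HEPatternGroup("G1", ["a"], events[:k])
            g2 = HEPatternGroup("G2", ["b"], events[k:])
            # brute force: connected components of the match graph
            adj = {i: set() for i in range(len(events))}
            for i, j in itertools.combinations(range(len(events)), 2):
                if match_event(events[i], events[j], tol):
                    adj[i].add(j)
                    adj[j].add(i)
            seen, n_comp = set(), 0
            for i in range(len(events)):
                if i in seen:
                    continue
                n_comp += 1
                stack = [i]
                while stack:
                    u = stack.pop()
                    if u in seen:
                        continue
                    seen.add(u)
                    stack.extend(adj[u] - seen)
            assert count_unique_hes([g1, g2], tol) == n_comp

    def test_monotone_when_groups_added(self):
        from musakaryo.patterns import HEPatternGroup

        g1 = HEPatternGroup("G1", ["a"], [_ev(chrom="chr01")])
        g2 = HEPatternGroup("G2", ["b"], [_ev(chrom="chr02")])
        assert count_unique_hes([g1]) <= count_unique_hes([g1, g2])


def _karyotype_from_pattern(pattern, chroms):
    from musakaryo.simulate import make_truth_karyotype

    ploidy, events = load_pattern_events(chroms)[pattern]
    kar = make_truth_karyotype(
        ploidy, [(e.chrom, e.start, e.end, e.a_copies, e.b_copies) for e in events], chroms
    )
    return [_seg(s.chrom, s.start, s.end, s.a_copies, s.b_copies) for s in kar.segments]


class TestChromosomeCounts:
    def test_baseline_triploid_is_11_a_22_b(self, chroms):
        kar = [_seg(c.name, 1, c.length, 1, 2) for c in chroms]
        assert chromosome_counts(kar, chroms) == (11, 22)

    def test_pelipita_karyotype_has_25_b_chromosomes(self, chroms):
        # chr02 and chr11 fully substituted, chr07 centromere A0:B3
        assert chromosome_counts(_karyotype_from_pattern("4", chroms), chroms) == (8, 25)

    def test_b_richest_karyotype_has_28_b_chromosomes(self, chroms):
        # six of 11 centromeres A0:B3
        assert chromosome_counts(_karyotype_from_pattern("5", chroms), chroms) == (5, 28)

    def test_totals_equal_33_for_euploid_triploids(self, chroms):
        for pattern in ("1a", "1b", "1c", "4", "5"):
            n_a, n_b = chromosome_counts(_karyotype_from_pattern(pattern, chroms), chroms)
            assert n_a + n_b == 33

    def test_no_call_centromere_warns_and_skips(self, chroms):
        kar = [_seg(c.name, 1, c.length, 1, 2) for c in chroms if c.name != "chr01"]
        with pytest.warns(UserWarning, match="chr01"):
            n_a, n_b = chromosome_counts(kar, chroms)
        assert n_a + n_b == 30


class TestTable1Fixture:
    def test_sample_sizes(self):
        records = load_table1_fixture()
        assert len(records) == 45
        assert sum(r.genome == "AB" for r in records) == 9
        assert sum(r.genome.startswith("ABB") for r in records) == 36

    def test_three_ab_hybrids_without_deviating_regions(self):
        records = load_table1_fixture()
        clean = [r for r in records if r.genome == "AB" and r.base_pattern == "(2x)"]
        assert len(clean) == 3

    def test_two_indonesian_saba_accessions_unassigned(self):
        records = load_table1_fixture()
        na = [r for r in records if r.pattern == "N/A"]
        assert {r.name for r in na} == {"Kepok Kuning", "Kepok Tanjung"}
        assert all(r.origin == "Indonesia" and r.subgroup == "Saba" for r in na)

    def test_pelipita_subgroup_shares_pattern_4(self):
        records = load_table1_fixture()
        p4 = [r for r in records if r.base_pattern == "4"]
        assert len(p4) == 3
        assert all("Pelipita" in r.name for r in p4)
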