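"""Dosage karyotyping: windows, segmentation, state classification."""

import numpy as np
import pandas as pd
import pytest

from musakaryo.ancestry import assign_site_depths, extract_het_sites
from musakaryo.karyotype import (
    KaryotypeParams,
    WindowProfile,
    classify_segment,
    expected_b_fraction,
    het_modality,
    karyotype_accession,
    segment_chromosome,
    segment_exhaustive,
    window_profiles,
)
from musakaryo.simulate import SimulationConfig, make_truth_karyotype, simulate_accession_depths, simulate_panels


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=100)
@given(a=st.integers(0, 4), b=st.integers(0, 4))
def test_b_fraction_symmetry_under_label_swap(a, b):
    """Swapping A and B labels complements the expected B fraction."""
    if a + b == 0:
        return
    assert expected_b_fraction(a, b) + expected_b_fraction(b, a) == pytest.approx(1.0)
    assert 0.0 <= expected_b_fraction(a, b) <= 1.0


class TestExpectedBFraction:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(0, 3, 1.0), (2, 1, 1 / 3), (2, 0, 0.0), (1, 1, 0.5), (1, 2, 2 / 3), (0, 2, 1.0)],
    )
    def test_state_to_fraction(self, a, b, expected):
        assert expected_b_fraction(a, b) == pytest.approx(expected)

    def test_zero_total_copies_rejected(self):
        with pytest.raises(ValueError):
            expected_b_fraction(0, 0)


class TestHetModality:
    def test_fractions_around_half_are_unimodal(self, rng):
        n = rng.integers(20, 40, size=50)
        k = rng.binomial(n, 0.5)
        frac = np.minimum(k, n - k) / n
        assert het_modality(frac, depths=n) == "unimodal_half"

    def test_fractions_around_thirds_are_multimodal(self, rng):
        n = rng.integers(20, 40, size=50)
        p = rng.choice([1 / 3, 2 / 3], size=50)
        k = rng.binomial(n, p)
        frac = np.minimum(k, n - k) / n
        assert het_modality(frac, depths=n) == "multimodal_thirds"

    def test_too_few_sites_is_insufficient(self):
        assert het_modality([0.5, 0.48]) == "insufficient"
        assert het_modality([]) == "insufficient"


@pytest.fixture(scope="module")
def baseline_windows(small_chroms):
    """Callable windows of a simulated baseline triploid chromosome."""
    cfg = SimulationConfig(sites_per_chrom=2000, diagnostic_fraction=1.0, seed=21)
    _pa, _pb, truth = simulate_panels(cfg, small_chroms)
    kar = make_truth_karyotype(3, [], small_chroms, "base")
    depths = simulate_accession_depths(kar, truth, cfg, small_chroms)
    sites = assign_site_depths(depths, truth)
    params = KaryotypeParams(window_size=500_000)
    return window_profiles(sites, small_chroms, params), params


class TestWindowProfiles:
    def test_windows_tile_chromosomes(self, baseline_windows, small_chroms):
        wins, params = baseline_windows
        for c in small_chroms:
            cw = [w for w in wins if w.chrom == c.name]
            assert cw[0].start == 1 and cw[-1].end == c.length
            for w1, w2 in zip(cw, cw[1:]):
                assert w2.start == w1.end + 1

    def test_baseline_norm_coverage_near_one(self, baseline_windows):
        wins, _ = baseline_windows
        cov = np.array([w.norm_coverage for w in wins if w.callable])
        assert abs(np.median(cov) - 1.0) < 0.05

    def test_empty_window_flagged_no_call(self, small_chroms):
        sites = pd.DataFrame(
            {"chrom": ["chr01"], "pos": [100], "depth_a": [10], "depth_b": [20]}
        )
        wins = window_profiles(sites, small_chroms, KaryotypeParams(min_sites=1))
        empties = [w for w in wins if w.n_sites == 0]
        assert empties and all(not w.callable for w in empties)

    def test_unknown_chromosome_rejected(self, small_chroms):
        sites = pd.DataFrame(
            {"chrom": ["chrX"], "pos": [100], "depth_a": [1], "depth_b": [1]}
        )
        with pytest.raises(ValueError, match="chrX"):
            window_profiles(sites, small_chroms)

    def test_whole_chromosome_loss_drops_coverage_to_two_thirds(self, small_chroms):
        cfg = SimulationConfig(sites_per_chrom=2000, diagnostic_fraction=1.0, seed=22)
        _pa, _pb, truth = simulate_panels(cfg, small_chroms)
        chr08 = next(c for c in small_chroms if c.name == "chr08")
        kar = make_truth_karyotype(3, [("chr08", 1, chr08.length, 0, 2)], small_chroms)
        depths = simulate_accession_depths(kar, truth, cfg, small_chroms)
        sites = assign_site_depths(depths, truth)
        wins = window_profiles(sites, small_chroms, KaryotypeParams(window_size=500_000))
        cov = np.array([w.norm_coverage for w in wins if w.chrom == "chr08" and w.callable])
        assert abs(np.mean(cov) - 2 / 3) < 0.05


def _make_windows(b_fracs, n_reads=1500, cov=None):
    cov = cov if cov is not None else [1.0] * len(b_fracs)
    return [
        WindowProfile(
            chrom="chr01",
            start=1 + i * 500_000,
            end=(i + 1) * 500_000,
            n_sites=50,
            b_reads=int(round(f * n_reads)),
            total_reads=n_reads,
            norm_coverage=c,
        )
        for i, (f, c) in enumerate(zip(b_fracs, cov))
    ]


class TestSegmentation:
    def test_constant_profile_has_no_breakpoints(self):
        wins = _make_windows([2 / 3] * 15)
        assert segment_chromosome(wins) == []

    def test_single_transition_recovered_within_one_window(self, small_chroms):
        cfg = SimulationConfig(sites_per_chrom=2000, diagnostic_fraction=1.0, seed=23)
        _pa, _pb, truth = simulate_panels(cfg, small_chroms)
        chr04 = next(c for c in small_chroms if c.name == "chr04")
        true_bp = 3_456_789
        kar = make_truth_karyotype(3, [("chr04", true_bp, chr04.length, 0, 3)], small_chroms)
        depths = simulate_accession_depths(kar, truth, cfg, small_chroms)
        sites = assign_site_depths(depths, truth)
        params = KaryotypeParams(window_size=500_000)
        wins = [w for w in window_profiles(sites, small_chroms, params) if w.chrom == "chr04"]
        cuts = segment_chromosome(wins, params)
        assert len(cuts) == 1
        assert abs(cuts[0] - true_bp) <= params.window_size

    @pytest.mark.parametrize("seed", range(8))
    def test_dynamic_program_matches_exhaustive_oracle(self, seed):
        # random <=20-window instances with <=2 true change points
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        n_cp = int(rng.integers(0, 3))
        cuts = sorted(rng.choice(range(2, n - 1), size=n_cp, replace=False)) if n_cp else []
        levels = rng.choice([1 / 3, 0.5, 2 / 3, 1.0], size=n_cp + 1, replace=False)
        fracs = np.empty(n)
        bounds = [0, *cuts, n]
        for lvl, (lo, hi) in zip(levels, zip(bounds, bounds[1:])):
            fracs[lo:hi] = lvl
        reads = rng.binomial(1500, np.clip(fracs, 0.01, 0.99))
        wins = [
            WindowProfile("chr01", 1 + i * 10, (i + 1) * 10, 50, int(reads[i]), 1500, 1.0)
            for i in range(n)
        ]
        params = KaryotypeParams(window_size=10)
        assert segment_chromosome(wins, params) == segment_exhaustive(
            wins, params, max_changepoints=4
        )

    def test_non_callable_windows_are_ignored(self):
        wins = _make_windows([2 / 3] * 6 + [1.0] * 6)
        wins[3].callable = False
        cuts = segment_chromosome(wins)
        assert cuts == [wins[6].start]


class TestClassifySegment:
    P = KaryotypeParams()

    def test_baseline_triploid(self):
        a, b, conf = classify_segment(2000, 3000, [1.0] * 5, [], 3, self.P)
        assert (a, b) == (1, 2) and conf > 0.95

    def test_monosomic_b2_needs_het_modality(self, rng):
        n = rng.integers(20, 40, size=30)
        k = rng.binomial(n, 0.5)
        frac = np.minimum(k, n - k) / n
        a, b, _ = classify_segment(
            2990, 3000, [0.67] * 5, frac, 3, self.P, het_depths=n
        )
        assert (a, b) == (0, 2)

    def test_trisomic_b3_with_thirds_modality(self, rng):
        n = rng.integers(20, 40, size=30)
        k = rng.binomial(n, rng.choice([1 / 3, 2 / 3], size=30))
        frac = np.minimum(k, n - k) / n
        a, b, _ = classify_segment(
            2990, 3000, [1.0] * 5, frac, 3, self.P, het_depths=n
        )
        assert (a, b) == (0, 3)

    def test_tetrasomic_a2b2(self):
        a, b, _ = classify_segment(1500, 3000, [1.33] * 5, [], 3, self.P)
        assert (a, b) == (2, 2)

    def test_tetrasomic_a1b3(self):
        a, b, _ = classify_segment(2250, 3000, [1.33] * 5, [], 3, self.P)
        assert (a, b) == (1, 3)

    def test_diploid_missing_b(self):
        a, b, _ = classify_segment(5, 3000, [1.0] * 5, [], 2, self.P)
        assert (a, b) == (2, 0)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            classify_segment(0, 0, [], [], 3, self.P)


@pytest.fixture(scope="module")
def full_cohort(chroms):
    """Panels + diagnostics on full-size chromosomes, 1000 sites each."""
    cfg = SimulationConfig(sites_per_chrom=1000, diagnostic_fraction=1.0, seed=31)
    _pa, _pb, truth = simulate_panels(cfg, chroms)
    return cfg, truth


def _window_accuracy(segments, truth_kar, chroms, window_size):
    """Fraction of windows whose inferred state matches truth."""
    hits = total = 0
    for c in chroms:
        for start in range(1, c.length + 1, window_size):
            mid = min(start + window_size // 2, c.length)
            true_state = truth_kar.state_at(c.name, mid)
            inferred = next(
                (
                    (s.a_copies, s.b_copies)
                    for s in segments
                    if s.chrom == c.name and s.start <= mid <= s.end
                ),
                None,
            )
            total += 1
            hits += inferred == true_state
    return hits / total


class TestKaryotypeAccession:
    def test_baseline_accession_yields_eleven_baseline_segments(
        self, full_cohort, chroms
    ):
        cfg, truth = full_cohort
        kar = make_truth_karyotype(3, [], chroms, "base")
        depths = simulate_accession_depths(kar, truth, cfg, chroms)
        sites = assign_site_depths(depths, truth)
        segs = karyotype_accession(sites, chroms, baseline_ploidy=3)
        assert len(segs) == 11
        assert all(s.state == (1, 2) for s in segs)

    def test_fully_b_pattern_recovered(self, full_cohort, chroms):
        # three whole chromosomes fully B plus three centromeric B
        # regions, no A2:B1 anywhere (the B-richest karyotype surveyed)
        cfg, truth = full_cohort
        from musakaryo.patterns import load_pattern_events

        _ploidy, events = load_pattern_events(chroms)["5"]
        kar = make_truth_karyotype(
            3, [(e.chrom, e.start, e.end, e.a_copies, e.b_copies) for e in events], chroms
        )
        depths = simulate_accession_depths(kar, truth, cfg, chroms)
        sites = assign_site_depths(depths, truth)
        het = extract_het_sites(depths, truth)
        segs = karyotype_accession(sites, chroms, het_sites=het, baseline_ploidy=3)
        acc = _window_accuracy(segs, kar, chroms, 500_000)
        assert acc >= 0.95
        assert not any(s.state == (2, 1) for s in segs)

    def test_diploid_terminal_loss_is_single_deviation(self, full_cohort, chroms):
        cfg, truth = full_cohort
        kar = make_truth_karyotype(2, [("chr06", 1, 5_000_000, 2, 0)], chroms, "dip")
        depths = simulate_accession_depths(kar, truth, cfg, chroms)
        sites = assign_site_depths(depths, truth)
        segs = karyotype_accession(sites, chroms, baseline_ploidy=2)
        deviating = [s for s in segs if s.state != (1, 1)]
        assert len(deviating) == 1
        assert deviating[0].chrom == "chr06" and deviating[0].state == (2, 0)
        assert deviating[0].start == 1

    def test_ab_label_swap_maps_states_symmetrically(self, full_cohort, chroms):
        cfg, truth = full_cohort
        kar = make_truth_karyotype(3, [("chr04", 22_000_001, 32_000_000, 0, 3)], chroms)
        depths = simulate_accession_depths(kar, truth, cfg, chroms)
        sites = assign_site_depths(depths, truth)
        segs = karyotype_accession(sites, chroms, baseline_ploidy=3)
        swapped = sites.rename(columns={"depth_a": "depth_b", "depth_b": "depth_a"})
        segs_swapped = karyotype_accession(swapped, chroms, baseline_ploidy=3)
        states = {(s.chrom, s.start, s.end): s.state for s in segs}
        states_sw = {(s.chrom, s.start, s.end): s.state for s in segs_swapped}
        assert states.keys() == states_sw.keys()
        for key, (a, b) in states.items():
            assert states_sw[key] == (b, a)

    def test_states_invariant_under_uniform_depth_rescaling(self, full_cohort, chroms):
        cfg, truth = full_cohort
        kar = make_truth_karyotype(3, [("chr04", 22_000_001, 32_000_000, 0, 3)], chroms)
        depths = simulate_accession_depths(kar, truth, cfg, chroms)
        sites = assign_site_depths(depths, truth)
        segs = karyotype_accession(sites, chroms, baseline_ploidy=3)
        scaled = sites.assign(depth_a=sites.depth_a * 3, depth_b=sites.depth_b * 3)
        segs_scaled = karyotype_accession(scaled, chroms, baseline_ploidy=3)
        assert [(s.chrom, s.start, s.end, s.state) for s in segs] == [
            (s.chrom, s.start, s.end, s.state) for s in segs_scaled
        ]

    def test_rescaling_one_chromosome_shifts_its_copy_number_call(
        self, full_cohort, chroms
    ):
        # a fully B chromosome rescaled to 2/3 depth is indistinguishable
        # from losing one of its three B copies: the call must shift from
        # A0:B3 to A0:B2
        cfg, truth = full_cohort
        chr08 = next(c for c in chroms if c.name == "chr08")
        kar = make_truth_karyotype(3, [("chr08", 1, chr08.length, 0, 3)], chroms)
        depths = simulate_accession_depths(kar, truth, cfg, chroms)
        sites = assign_site_depths(depths, truth)
        segs = karyotype_accession(sites, chroms, baseline_ploidy=3)
        assert all(s.state == (0, 3) for s in segs if s.chrom == "chr08")
        mask = sites.chrom == "chr08"
        rescaled = sites.copy()
        rescaled.loc[mask, "depth_a"] = (sites.loc[mask, "depth_a"] * 2 / 3).round().astype(int)
        rescaled.loc[mask, "depth_b"] = (sites.loc[mask, "depth_b"] * 2 / 3).round().astype(int)
        segs2 = karyotype_accession(rescaled, chroms, baseline_ploidy=3)
        assert all(s.state == (0, 2) for s in segs2 if s.chrom == "chr08")
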