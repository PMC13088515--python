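"""Haplotype scan: QC, windows, counting, deficit test, merging, carrier calls."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapdeficit.genotypes import PhasedGenotypes
from hapdeficit.scan import (
    Region,
    Window,
    apply_qc_filters,
    assign_carrier_status,
    count_window_haplotypes,
    deficit_binomial_test,
    enumerate_windows,
    expected_homozygotes,
    haplotype_freq_from_carrier_freq,
    hwe_exact_test,
    merge_significant_windows,
    records_to_frame,
    scan,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def binom_lower_tail_oracle(obs: int, n: int, p: float) -> float:
    """Direct term-by-term summation of P(X <= obs), X ~ Binomial(n, p)."""
    if p == 0:
        return 1.0
    if p == 1:
        return 1.0 if obs >= n else 0.0
    total = 0.0
    term = (1 - p) ** n
    for i in range(obs + 1):
        total += term
        term *= (n - i) / (i + 1) * p / (1 - p)
    return min(1.0, total)


def hwe_exact_oracle(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact-integer HWE test: conditional genotype probabilities via comb."""
    n = n_het + n_hom1 + n_hom2
    n_a = n_het + 2 * min(n_hom1, n_hom2)

    def prob(h: int) -> Fraction:
        rare = (n_a - h) // 2
        common = n - h - rare
        return Fraction(
            math.comb(n, h) * math.comb(n - h, rare) * 2 ** h,
            1) / Fraction(math.comb(2 * n, n_a))

    hets = range(n_a % 2, n_a + 1, 2)
    probs = {h: prob(h) for h in hets}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def toy_phased(diplotypes: list[tuple[str, str]], n_markers: int) -> PhasedGenotypes:
    markers = pd.DataFrame({
        "chrom": "1", "marker_id": [f"m{i}" for i in range(n_markers)],
        "pos_bp": np.arange(1, n_markers + 1) * 100_000,
        "allele1": "A", "allele2": "B"})
    alleles = np.zeros((len(diplotypes), n_markers, 2), dtype=np.uint8)
    for i, (h0, h1) in enumerate(diplotypes):
        alleles[i, :, 0] = [int(c) for c in h0]
        alleles[i, :, 1] = [int(c) for c in h1]
    return PhasedGenotypes([f"a{i}" for i in range(len(diplotypes))],
                           alleles, markers)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


class TestQC:
    def test_low_maf_marker_removed(self, rng):
        n = 200
        geno = rng.binomial(2, 0.4, size=(n, 3))
        geno[:, 1] = 0
        geno[0, 1] = 1  # alt allele freq 1/400 = 0.0025 < 1%
        markers = pd.DataFrame({"chrom": "1",
                                "marker_id": ["a", "b", "c"],
                                "pos_bp": [1, 2, 3],
                                "allele1": "A", "allele2": "B"})
        _, kept, _, report = apply_qc_filters(geno, markers)
        assert list(kept["marker_id"]) == ["a", "c"]
        assert report["markers_removed_maf"] == 1

    def test_clean_table_unchanged(self, rng):
        geno = rng.binomial(2, 0.5, size=(100, 4))
        markers = pd.DataFrame({"chrom": "1",
                                "marker_id": list("abcd"),
                                "pos_bp": [1, 2, 3, 4],
                                "allele1": "A", "allele2": "B"})
        out, kept, animals, _ = apply_qc_filters(geno, markers)
        assert out.shape == geno.shape
        assert len(animals) == 100

    def test_half_typed_animal_removed(self, rng):
        geno = rng.binomial(2, 0.5, size=(30, 10))
        geno[7, :5] = -1  # 50% call rate <= 70% threshold
        markers = pd.DataFrame({"chrom": "1",
                                "marker_id": [f"m{i}" for i in range(10)],
                                "pos_bp": np.arange(1, 11),
                                "allele1": "A", "allele2": "B"})
        _, _, animals, report = apply_qc_filters(geno, markers)
        assert len(animals) == 29
        assert "S8" not in animals
        assert report["animals_removed_call_rate"] == 1

    def test_hwe_violating_marker_removed(self, rng):
        geno = rng.binomial(2, 0.5, size=(200, 2))
        geno[:, 1] = np.where(np.arange(200) < 100, 0, 2)  # no hets at 50/50
        markers = pd.DataFrame({"chrom": "1", "marker_id": ["a", "b"],
                                "pos_bp": [1, 2], "allele1": "A", "allele2": "B"})
        _, kept, _, report = apply_qc_filters(geno, markers)
        assert list(kept["marker_id"]) == ["a"]
        assert report["markers_removed_hwe"] == 1

    def test_everything_removed_raises(self):
        geno = np.zeros((5, 2), dtype=int)  # monomorphic: MAF 0
        markers = pd.DataFrame({"chrom": "1", "marker_id": ["a", "b"],
                                "pos_bp": [1, 2], "allele1": "A", "allele2": "B"})
        with pytest.raises(ValueError, match="QC removed all"):
            apply_qc_filters(geno, markers)

    @pytest.mark.parametrize("counts", [(10, 5, 5), (50, 25, 25), (3, 0, 17),
                                        (0, 50, 50), (7, 13, 2), (21, 10, 69)])
    def test_hwe_exact_matches_integer_oracle(self, counts):
        got = hwe_exact_test(*counts)
        want = hwe_exact_oracle(*counts)
        assert got == pytest.approx(want, rel=1e-9)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


class TestWindows:
    def test_hand_enumerated_starts(self, toy_markers):
        wins = enumerate_windows(toy_markers, sizes=(1_000_000,), step=500_000)
        assert [(w.start, w.end) for w in wins] == [
            (1, 1_000_001), (500_001, 1_500_001), (1_000_001, 2_000_001),
            (1_500_001, 2_500_001), (2_000_001, 3_000_001)]
        assert all(len(w.marker_idx) >= 2 for w in wins)

    def test_chromosome_shorter_than_window(self):
        markers = pd.DataFrame({"chrom": "1", "marker_id": ["a", "b"],
                                "pos_bp": [100, 900],
                                "allele1": "A", "allele2": "B"})
        wins = enumerate_windows(markers, sizes=(1_000_000,))
        assert len(wins) == 1
        assert wins[0].marker_idx == (0, 1)

    def test_marker_at_end_boundary_excluded(self):
        markers = pd.DataFrame({"chrom": "1",
                                "marker_id": ["a", "b", "c"],
                                "pos_bp": [1, 500_000, 1_000_001],
                                "allele1": "A", "allele2": "B"})
        wins = enumerate_windows(markers, sizes=(1_000_000,), step=2_000_000)
        # window [1, 1000001): marker at pos 1000001 == end is excluded
        assert wins[0].marker_idx == (0, 1)

    def test_nonpositive_step_rejected(self, toy_markers):
        with pytest.raises(ValueError, match="step"):
            enumerate_windows(toy_markers, step=0)

    def test_windows_respect_chromosomes(self):
        markers = pd.DataFrame({
            "chrom": ["1"] * 3 + ["2"] * 3,
            "marker_id": [f"m{i}" for i in range(6)],
            "pos_bp": [1, 400_000, 800_000] * 2,
            "allele1": "A", "allele2": "B"})
        wins = enumerate_windows(markers, sizes=(1_000_000,))
        assert {w.chrom for w in wins} == {"1", "2"}
        for w in wins:
            assert all(markers.loc[list(w.marker_idx), "chrom"] == w.chrom)


# ---------------------------------------------------------------------------
# Haplotype counting
# ---------------------------------------------------------------------------


class TestCounting:
    def test_three_animal_hand_tally(self):
        # diplotypes (AB|AB), (AB|ab), (ab|ab) at 2 markers; A/B encoded 0, a/b 1
        phased = toy_phased([("00", "00"), ("00", "11"), ("11", "11")], 2)
        window = Window("1", 1, 1_000_001, 1_000_000, (0, 1))
        recs = {r.alleles: r for r in count_window_haplotypes(phased, window)}
        ab = recs["00"]
        assert (ab.count, ab.het_carriers, ab.obs_hom) == (3, 1, 1)
        assert recs["11"].count == 3
        assert sum(r.count for r in recs.values()) == 2 * 3

    def test_identical_homozygotes(self):
        phased = toy_phased([("0101", "0101")] * 5, 4)
        window = Window("1", 1, 1_000_001, 1_000_000, (0, 1, 2, 3))
        recs = count_window_haplotypes(phased, window)
        assert len(recs) == 1
        assert recs[0].count == 10
        assert recs[0].obs_hom == 5
        assert recs[0].het_carriers == 0

    def test_matches_naive_string_multiset_oracle(self, rng):
        n, m = 20, 6
        alleles = rng.integers(0, 2, size=(n, m, 2), dtype=np.uint8)
        markers = pd.DataFrame({
            "chrom": "1", "marker_id": [f"m{i}" for i in range(m)],
            "pos_bp": np.arange(1, m + 1) * 10_000,
            "allele1": "A", "allele2": "B"})
        phased = PhasedGenotypes([f"a{i}" for i in range(n)], alleles, markers)
        window = Window("1", 1, 1_000_001, 1_000_000, tuple(range(m)))

        from collections import Counter
        strings = [["".join(map(str, alleles[i, :, c])) for c in (0, 1)]
                   for i in range(n)]
        k_oracle = Counter(s for pair in strings for s in pair)
        hom_oracle = Counter(p[0] for p in strings if p[0] == p[1])
        het_oracle = Counter(s for p in strings if p[0] != p[1] for s in set(p))

        recs = count_window_haplotypes(phased, window)
        assert {r.alleles: r.count for r in recs} == dict(k_oracle)
        for r in recs:
            assert r.obs_hom == hom_oracle.get(r.alleles, 0)
            assert r.het_carriers == het_oracle.get(r.alleles, 0)

    def test_empty_window_rejected(self):
        phased = toy_phased([("00", "00")], 2)
        with pytest.raises(ValueError, match="no markers"):
            count_window_haplotypes(phased, Window("1", 1, 2, 1, ()))


# ---------------------------------------------------------------------------
# Deficit statistics
# ---------------------------------------------------------------------------


class TestDeficitStats:
    def test_expected_homozygotes_closed_form(self):
        assert expected_homozygotes(0.0, 500) == 0.0
        assert expected_homozygotes(0.1, 1000) == pytest.approx(10.0)

    def test_carrier_frequency_inversion_minor_root(self):
        q = haplotype_freq_from_carrier_freq(0.137)
        assert q < 0.5
        assert 2 * q * (1 - q) == pytest.approx(0.137)

    @pytest.mark.parametrize("obs,n,q", [
        (0, 1000, 0.02), (3, 500, 0.1), (0, 8263, 0.074), (25, 10000, 0.05),
        (12, 10000, 0.035), (0, 50, 0.3),
    ])
    def test_matches_summation_oracle(self, obs, n, q):
        want = binom_lower_tail_oracle(obs, n, q * q)
        assert deficit_binomial_test(obs, n, q) == pytest.approx(want, rel=1e-12)

    def test_known_value_zero_observed(self):
        # P(X = 0) = (1 - 0.0004)^1000 = 0.670266...
        want = (1 - 0.02 ** 2) ** 1000
        assert deficit_binomial_test(0, 1000, 0.02) == pytest.approx(want, rel=1e-12)
        assert round(want, 4) == 0.6703

    def test_degenerate_inputs(self):
        assert deficit_binomial_test(0, 1000, 0.0) == 1.0
        assert deficit_binomial_test(1000, 1000, 0.5) == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(n=st.integers(1, 300), obs=st.integers(0, 300),
           q=st.floats(0, 1, allow_nan=False))
    def test_p_value_properties(self, n, obs, q):
        obs = min(obs, n)
        p = deficit_binomial_test(obs, n, q)
        assert 0 < p <= 1
        if obs < n:
            # monotone: seeing more homozygotes cannot reduce the tail p
            assert deficit_binomial_test(obs + 1, n, q) >= p


# ---------------------------------------------------------------------------
# Scan, merging, carrier status
# ---------------------------------------------------------------------------


class TestScan:
    def test_planted_region_detected_with_zero_homozygotes(self, scan_population):
        st_ = scan_population.true_state
        records = scan(scan_population.phased)
        hits = [r for r in records if r.significant
                and r.window.start < st_.region_end
                and st_.region_start < r.window.end
                and set(r.alleles) == {"1"}]
        assert hits, "planted lethal haplotype not among significant records"
        assert all(r.obs_hom == 0 for r in hits)

    def test_bonferroni_never_below_raw_p_and_capped(self, scan_population):
        records = scan(scan_population.phased)
        m = len(records)
        for r in records[:200]:
            assert r.p_adj >= r.p_value
            assert r.p_adj <= 1.0
            assert r.p_adj == pytest.approx(min(1.0, m * r.p_value))

    def test_counts_sum_to_2n_within_each_window(self, scan_population):
        phased = scan_population.phased
        window = enumerate_windows(phased.markers)[0]
        recs = count_window_haplotypes(phased, window)
        assert sum(r.count for r in recs) == 2 * phased.n_animals
        for r in recs:
            assert r.count == r.het_carriers + 2 * r.obs_hom

    def test_impossible_frequency_filter_empties_result(self, scan_population):
        assert scan(scan_population.phased, min_haplotype_freq=1.1) == []

    def test_output_sorted_by_adjusted_p(self, scan_population):
        records = scan(scan_population.phased)
        p_adj = [r.p_adj for r in records]
        assert p_adj == sorted(p_adj)


class TestMergeAndStatus:
    @staticmethod
    def _rec(chrom, start, end, p_adj, alleles="11", idx=(0, 1)):
        from hapdeficit.scan import HaplotypeRecord
        return HaplotypeRecord(
            window=Window(chrom, start, end, end - start, idx),
            alleles=alleles, count=10, freq=0.05, het_carriers=10,
            carrier_freq=0.1, obs_hom=0, exp_hom=1.0, p_value=p_adj / 10,
            p_adj=p_adj, significant=True)

    def test_overlapping_windows_merge(self):
        regions = merge_significant_windows([
            self._rec("1", 1_000_000, 2_000_000, 1e-6),
            self._rec("1", 1_500_000, 2_500_000, 1e-4)])
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1_000_000, 2_500_000)
        assert regions[0].representative.p_adj == 1e-6

    def test_adjacent_windows_merge_but_gapped_do_not(self):
        regions = merge_significant_windows([
            self._rec("1", 0, 1_000_000, 1e-6),
            self._rec("1", 1_000_000, 2_000_000, 1e-5),
            self._rec("1", 3_000_000, 4_000_000, 1e-5)])
        assert [(r.start, r.end) for r in regions] == [
            (0, 2_000_000), (3_000_000, 4_000_000)]

    def test_different_chromosomes_never_merge(self):
        regions = merge_significant_windows([
            self._rec("1", 0, 1_000_000, 1e-6),
            self._rec("2", 0, 1_000_000, 1e-6)])
        assert len(regions) == 2

    def test_planted_simulation_yields_single_covering_region(self, scan_population):
        st_ = scan_population.true_state
        records = scan(scan_population.phased)
        regions = merge_significant_windows(records)
        assert len(regions) == 1
        assert regions[0].start < st_.region_end
        assert st_.region_start < regions[0].end

    def test_carrier_status_levels_and_unknown(self):
        phased = toy_phased([("11", "11"), ("11", "00"), ("00", "00")], 2)
        region = Region("1", 1, 1_000_001, [self._rec("1", 1, 1_000_001, 1e-6)])
        tab = assign_carrier_status(phased, region, all_animals=["a0", "a1", "a2",
                                                                 "ghost"])
        status = dict(zip(tab["animal_id"], tab["status"]))
        assert status == {"a0": "homozygous", "a1": "carrier",
                          "a2": "non-carrier", "ghost": "unknown"}

    def test_status_counts_match_haplotype_record(self, scan_population):
        records = scan(scan_population.phased)
        regions = merge_significant_windows(records)
        rep = regions[0].representative
        tab = assign_carrier_status(scan_population.phased, regions[0])
        counts = tab["status"].value_counts()
        assert counts.get("carrier", 0) == rep.het_carriers
        assert counts.get("homozygous", 0) == rep.obs_hom

    def test_records_frame_columns(self, scan_population):
        frame = records_to_frame(scan(scan_population.phased)[:5])
        assert {"chrom", "carrier_freq", "obs_hom", "exp_hom",
                "p_adj"} <= set(frame.columns)
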