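"""Centromere-pair representation and breakpoint mapping."""

import numpy as np
import pytest

from cenrec import (
    AlignmentError,
    Category,
    CentromereBreakpointMapper,
    Orientation,
    ParentalCentromerePair,
    bin_breakpoints,
    cen3_construct,
    cen3_fixture_pair,
    detect_acentric_ru,
    find_informative_sites,
    gen_centromere_pair,
    gen_recombinant,
    genotype_recombinant,
    longest_identity_tract,
    map_breakpoint,
)
from cenrec.centromere import IdentityTract, InformativeSiteSet, _all_runs
from conftest import CEN3_POSITIONS


def brute_force_sites(pair):
    """Independent column-by-column scan."""
    pos = []
    for i in range(pair.length):
        w, y = pair.seq_w[i], pair.seq_y[i]
        if w != y and "-" not in (w, y):
            pos.append(i + 1)
    return tuple(pos)


def brute_force_longest_run(positions, length):
    """Exhaustive enumeration of all site-free runs."""
    site = set(positions)
    best = (0, None, None)  # (len, start, end)
    start = None
    for col in range(1, length + 2):
        if col <= length and col not in site:
            if start is None:
                start = col
        else:
            if start is not None:
                run = (col - start, start, col - 1)
                if run[0] > best[0]:
                    best = run
                start = None
    return best


class TestInformativeSites:
    def test_cen3_fixture_positions(self, cen3_pair, cen3_sites):
        assert cen3_sites.positions == CEN3_POSITIONS
        assert cen3_sites.seq_length == 117
        # alleles differ and are non-gap at every site
        for w, y in zip(cen3_sites.allele_w, cen3_sites.allele_y):
            assert w != y and "-" not in (w, y)

    def test_identical_sequences_yield_empty_set(self):
        pair = ParentalCentromerePair("a", "b", "ACGTACGT", "ACGTACGT")
        assert find_informative_sites(pair).positions == ()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        pair = gen_centromere_pair(200, n_snps=int(rng.integers(0, 30)), seed=seed)
        assert find_informative_sites(pair).positions == brute_force_sites(pair)

    def test_gap_columns_tracked_separately(self):
        pair = ParentalCentromerePair("a", "b", "A-GTAC", "ATGTGC")
        sites = find_informative_sites(pair)
        assert sites.positions == (5,)
        assert sites.indel_columns == (2,)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            ParentalCentromerePair("a", "b", "ACGT", "ACG")


class TestIdentityTracts:
    def test_cen3_43bp_tract(self, cen3_sites):
        tract = longest_identity_tract(cen3_sites)
        assert (tract.start, tract.end) == (25, 67)
        assert tract.length == 43
        assert tract.bounded_by == (24, 68)

    def test_single_site_at_one_forces_terminal_run(self):
        sites = InformativeSiteSet((1,), ("A",), ("C",), 10)
        tract = longest_identity_tract(sites)
        assert (tract.start, tract.end, tract.length) == (2, 10, 9)

    def test_empty_site_set_returns_whole_sequence(self):
        sites = InformativeSiteSet((), (), (), 50)
        tract = longest_identity_tract(sites)
        assert (tract.start, tract.end, tract.length) == (1, 50, 50)
        assert tract.bounded_by == (None, None)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        length = int(rng.integers(5, 120))
        n = int(rng.integers(1, min(length, 15)))
        positions = tuple(sorted(rng.choice(length, size=n, replace=False) + 1))
        sites = InformativeSiteSet(positions, ("A",) * n, ("C",) * n, length)
        tract = longest_identity_tract(sites)
        exp_len, exp_start, _ = brute_force_longest_run(positions, length)
        assert tract.length == exp_len
        if exp_len > 0:
            assert tract.start == exp_start  # tie-break: smallest start

    @pytest.mark.parametrize("seed", range(20))
    def test_tract_lengths_plus_sites_partition_sequence(self, seed):
        rng = np.random.default_rng(200 + seed)
        length = int(rng.integers(3, 80))
        n = int(rng.integers(1, min(length, 10)))
        positions = tuple(sorted(rng.choice(length, size=n, replace=False) + 1))
        sites = InformativeSiteSet(positions, ("A",) * n, ("C",) * n, length)
        total = sum(t.length for t in _all_runs(sites)) + len(positions)
        assert total == length


class TestGenotyping:
    def test_parental_w_is_all_w(self, cen3_pair, cen3_sites):
        assert genotype_recombinant(cen3_pair.seq_w, cen3_pair) == ("W",) * 7

    def test_constructed_recombinant_vector(self, cen3_pair):
        seq, _ = gen_recombinant(cen3_pair, "simple", breakpoint_column=40)
        assert genotype_recombinant(seq, cen3_pair) == tuple("WWWYYYY")

    def test_foreign_base_is_n(self, cen3_pair, cen3_sites):
        p = cen3_sites.positions[0]
        alien = next(
            b for b in "ACGT"
            if b not in (cen3_sites.allele_w[0], cen3_sites.allele_y[0])
        )
        seq = cen3_pair.seq_w[: p - 1] + alien + cen3_pair.seq_w[p:]
        assert genotype_recombinant(seq, cen3_pair)[0] == "N"

    def test_length_mismatch_rejected(self, cen3_pair):
        with pytest.raises(AlignmentError):
            genotype_recombinant("ACGT", cen3_pair)


class TestBreakpointMapping:
    def test_simple_recombinant_maps_between_24_and_68(self, cen3_sites):
        call = map_breakpoint(tuple("WWWYYYY"), cen3_sites)
        assert call.category is Category.SIMPLE_RECOMBINANT
        assert call.breakpoint == (24, 68)
        assert call.n_switches == 1

    def test_all_parental_vectors(self, cen3_sites):
        assert map_breakpoint(("W",) * 7, cen3_sites).category is Category.PARENTAL_W
        assert map_breakpoint(("Y",) * 7, cen3_sites).category is Category.PARENTAL_Y

    def test_patchy_vector_counts_switches(self, cen3_sites):
        call = map_breakpoint(tuple("WYWYYYY"), cen3_sites)
        assert call.category is Category.PATCHY
        assert call.n_switches == 3
        assert call.breakpoint is None

    def test_all_n_is_ambiguous(self, cen3_sites):
        call = map_breakpoint(("N",) * 7, cen3_sites)
        assert call.category is Category.AMBIGUOUS

    def test_n_sites_widen_the_interval(self, cen3_sites):
        call = map_breakpoint(tuple("WWNYYYY"), cen3_sites)
        assert call.category is Category.SIMPLE_RECOMBINANT
        assert call.breakpoint == (13, 68)

    def test_reversed_orientation_single_switch(self, cen3_sites):
        # Y-left/W-right pattern against the declared W-left orientation
        call = map_breakpoint(tuple("YYYWWWW"), cen3_sites)
        assert call.category is Category.AMBIGUOUS
        call2 = map_breakpoint(
            tuple("YYYWWWW"), cen3_sites, Orientation.Y_LEFT_W_RIGHT
        )
        assert call2.category is Category.SIMPLE_RECOMBINANT
        assert call2.breakpoint == (24, 68)

    @pytest.mark.parametrize("seed", range(30))
    def test_breakpoint_recovery_contains_true_column(self, cen3_pair,
                                                      cen3_mapper, seed):
        rng = np.random.default_rng(seed)
        b = int(rng.integers(2, cen3_pair.length + 1))
        seq, truth = gen_recombinant(cen3_pair, "simple", breakpoint_column=b)
        call = cen3_mapper.predict([seq])[0]
        assert call.category in (
            Category.SIMPLE_RECOMBINANT, Category.PARENTAL_W, Category.PARENTAL_Y
        )
        if call.category is Category.SIMPLE_RECOMBINANT:
            left, right = call.breakpoint
            # the true column lies inside (left, right]; switching exactly at
            # a site column makes that site the first right-parent site
            assert left < b <= right

    def test_round_trip_parental_for_generated_pairs(self):
        for seed in range(10):
            pair = gen_centromere_pair(150, n_snps=8, seed=300 + seed)
            mapper = CentromereBreakpointMapper().fit(pair)
            call = mapper.predict([pair.seq_w])[0]
            assert call.category is Category.PARENTAL_W


class TestBinning:
    def test_97_of_99_in_central_bin(self, cen3_pair, cen3_mapper, cen3_sites):
        seqs = [gen_recombinant(cen3_pair, "simple", breakpoint_column=40)[0]] * 97
        seqs += [gen_recombinant(cen3_pair, "simple", breakpoint_column=12)[0],
                 gen_recombinant(cen3_pair, "simple", breakpoint_column=75)[0]]
        calls = cen3_mapper.predict(seqs)
        bins = bin_breakpoints(calls, cen3_sites)
        assert bins["24-68"] == 97
        assert sum(bins.values()) == 99

    def test_empty_input_gives_zero_histogram(self, cen3_sites):
        bins = bin_breakpoints([], cen3_sites)
        assert sum(bins.values()) == 0
        assert "24-68" in bins

    def test_non_simple_rejected_with_index(self, cen3_sites):
        bad = map_breakpoint(("W",) * 7, cen3_sites)
        with pytest.raises(ValueError, match="index 0"):
            bin_breakpoints([bad], cen3_sites)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_histogram_equals_direct_tally(self, cen3_pair, cen3_mapper,
                                           cen3_sites, seed):
        rng = np.random.default_rng(seed)
        cols = rng.integers(14, 101, size=50)
        seqs = [gen_recombinant(cen3_pair, "simple", breakpoint_column=int(c))[0]
                for c in cols]
        calls = cen3_mapper.predict(seqs)
        bins = bin_breakpoints(calls, cen3_sites)
        tally: dict[str, int] = {}
        for c in calls:
            key = f"{c.breakpoint[0]}-{c.breakpoint[1]}"
            tally[key] = tally.get(key, 0) + 1
        assert {k: v for k, v in bins.items() if v} == tally
        assert sum(bins.values()) == 50


class TestAcentricRu:
    def test_perfect_fusion_detected(self, cen3_pair):
        construct = cen3_construct(cen3_pair)
        seq, _ = gen_recombinant(cen3_pair, "acentric_RU", construct=construct)
        assert detect_acentric_ru(seq, cen3_pair, construct)

    def test_intact_centromere_not_ru(self, cen3_pair):
        construct = cen3_construct(cen3_pair)
        seq, _ = gen_recombinant(cen3_pair, "simple", breakpoint_column=40)
        assert not detect_acentric_ru(seq, cen3_pair, construct)

    def test_single_inserted_base_breaks_perfect_deletion(self, cen3_pair):
        construct = cen3_construct(cen3_pair)
        fusion = construct.ru_fusion()
        mutated = fusion[:10] + "A" + fusion[10:]
        assert not detect_acentric_ru(mutated, cen3_pair, construct)
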