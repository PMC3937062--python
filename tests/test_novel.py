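"""Novel miRNA discovery: exact mapping, window extraction, folding (with
an independent max-pairing oracle), hairpin evaluation, star detection."""

from functools import lru_cache
from itertools import combinations

import pytest

from vitismir.novel import (
    PAIRABLE,
    HairpinCriteria,
    discover_hairpins,
    detect_star,
    evaluate_hairpin,
    extract_windows,
    fold,
    map_exact,
)
from vitismir.preprocess import TagLibrary
from vitismir.seqio import GenomicInterval, reverse_complement


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def oracle_max_pairs(seq, min_loop=3):
    """Independent maximum-pairing recursion: condition on whether the LAST
    base of the interval is paired (the implementation conditions on the
    first), memoized on intervals."""

    @lru_cache(maxsize=None)
    def f(i, j):
        if j - i < min_loop + 1:
            return 0
        best = f(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in PAIRABLE:
                best = max(best, 1 + f(i, k - 1) + f(k + 1, j - 1))
        return best

    return f(0, len(seq) - 1)


def enumerate_all_structures_max_pairs(seq, min_loop=3):
    """Ground-truth-of-the-oracle: explicit enumeration of every valid pair
    set for very short sequences."""
    n = len(seq)
    candidates = [
        (i, j)
        for i, j in combinations(range(n), 2)
        if j - i > min_loop and (seq[i], seq[j]) in PAIRABLE
    ]

    best = 0

    def extend(chosen, remaining):
        nonlocal best
        best = max(best, len(chosen))
        for idx, (i, j) in enumerate(remaining):
            ok = True
            for a, b in chosen:
                distinct = len({i, j, a, b}) == 4
                non_crossing = not (a < i < b < j or i < a < j < b)
                if not (distinct and non_crossing):
                    ok = False
                    break
            if ok:
                extend(chosen + [(i, j)], remaining[idx + 1 :])

    extend([], candidates)
    return best


class TestMapExact:
    def test_planted_tag_found_at_locus(self, rng):
        genome = {"chr1": _random_seq(rng, 3000)}
        tag = genome["chr1"][500:521]
        hits = map_exact(tag, genome)
        assert GenomicInterval("chr1", 500, 521, "+") in hits

    def test_forward_and_reverse_plantings(self, rng):
        background = _random_seq(rng, 2000)
        tag = _random_seq(rng, 21)
        genome = {
            "chr1": background[:800]
            + tag
            + background[800:1500]
            + reverse_complement(tag)
            + background[1500:]
        }
        hits = map_exact(tag, genome)
        assert GenomicInterval("chr1", 800, 821, "+") in hits
        assert GenomicInterval("chr1", 1521, 1542, "-") in hits

    def test_no_hit_is_empty(self, rng):
        genome = {"chr1": "A" * 500}
        assert map_exact("CGCGCGCGCGCGCGCGCGCGC", genome) == []

    def test_matches_naive_all_positions_scan(self, rng):
        """Oracle equivalence on random 21-mers vs a 10-kb genome."""
        genome = {"chr1": _random_seq(rng, 10_000)}
        seq = genome["chr1"]
        tags = [seq[i : i + 21] for i in rng.integers(0, 9979, size=25)]
        tags += [_random_seq(rng, 21) for _ in range(25)]
        for tag in tags:
            rc = reverse_complement(tag)
            expected = sorted(
                [
                    GenomicInterval("chr1", i, i + 21, "+")
                    for i in range(len(seq) - 20)
                    if seq[i : i + 21] == tag
                ]
                + [
                    GenomicInterval("chr1", i, i + 21, "-")
                    for i in range(len(seq) - 20)
                    if seq[i : i + 21] == rc
                ]
            )
            assert sorted(map_exact(tag, genome)) == expected


class TestExtractWindows:
    def test_window_arithmetic(self, rng):
        genome = {"chr1": _random_seq(rng, 2000)}
        locus = GenomicInterval("chr1", 500, 521, "+")
        win_a, win_b = extract_windows(locus, genome, flank=150, pad=20)
        assert win_a.interval == GenomicInterval("chr1", 350, 541, "+")
        assert win_b.interval == GenomicInterval("chr1", 480, 671, "+")
        assert len(win_a) == len(win_b) == 191

    def test_edge_clamp_no_error(self, rng):
        genome = {"chr1": _random_seq(rng, 2000)}
        locus = GenomicInterval("chr1", 10, 31, "+")
        win_a, _ = extract_windows(locus, genome, flank=150)
        assert win_a.interval.start == 0

    def test_locus_outside_contig_errors(self, rng):
        genome = {"chr1": _random_seq(rng, 100)}
        with pytest.raises(ValueError):
            extract_windows(GenomicInterval("chr1", 90, 120, "+"), genome)

    def test_minus_strand_window_is_reverse_complemented(self, rng):
        genome = {"chr1": _random_seq(rng, 1000)}
        tag = reverse_complement(genome["chr1"][400:421])
        locus = map_exact(tag, genome)[0]
        assert locus.strand == "-"
        _, win_b = extract_windows(locus, genome, flank=50, pad=10)
        assert tag in win_b.seq

    def test_downstream_window_contains_planted_hairpin(self, rng):
        """A 5p-arm mature needs the downstream flank to cover loop+star."""
        mature = _random_seq(rng, 21)
        hairpin = mature + _random_seq(rng, 10) + reverse_complement(mature)
        genome = {"chr1": _random_seq(rng, 500) + hairpin + _random_seq(rng, 500)}
        locus = GenomicInterval("chr1", 500, 521, "+")
        _, win_b = extract_windows(locus, genome, flank=150, pad=20)
        assert hairpin in win_b.seq


class TestFold:
    def test_small_stem(self):
        assert fold("GGGAAACCC").pair_count == 3

    def test_unpairable_sequence(self):
        s = fold("AAAAAAA")
        assert s.pair_count == 0
        assert s.dotbracket == "......."

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            fold("ACG")

    def test_oracle_of_the_oracle(self, rng):
        """The interval recursion agrees with full structure enumeration on
        very short sequences, grounding the oracle itself."""
        for _ in range(30):
            seq = _random_seq(rng, int(rng.integers(6, 13)))
            assert oracle_max_pairs(seq) == enumerate_all_structures_max_pairs(seq)

    def test_dp_equals_oracle_up_to_30nt(self, rng):
        for _ in range(100):
            seq = _random_seq(rng, int(rng.integers(8, 31)))
            assert fold(seq).pair_count == oracle_max_pairs(seq)

    def test_structures_are_valid(self, rng):
        for _ in range(30):
            seq = _random_seq(rng, 40)
            s = fold(seq)
            for i, j in s.pairs:
                assert (seq[i], seq[j]) in PAIRABLE
                assert j - i > 3  # hairpin loop >= min_loop
            flat = [x for ij in s.pairs for x in ij]
            assert len(flat) == len(set(flat))  # each base in one pair
            for (i, j), (a, b) in combinations(s.pairs, 2):
                assert not (i < a < j < b or a < i < b < j)  # non-crossing
            assert s.dotbracket.count("(") == s.pair_count


def _perfect_hairpin(rng, mature_len=21, loop=8, flank=12):
    mature = "T" + _random_seq(rng, mature_len - 1)
    window = (
        _random_seq(rng, flank)
        + mature
        + _random_seq(rng, loop)
        + reverse_complement(mature)
        + _random_seq(rng, flank)
    )
    return mature, window


class TestEvaluateHairpin:
    def test_perfect_inverted_repeat_accepted_with_offset_star(self, rng):
        mature, window = _perfect_hairpin(rng)
        cand = evaluate_hairpin(window, mature, fold(window))
        assert cand is not None and cand.arm == "5p"
        # star = exact reverse complement region offset by the 2-nt overhang
        expected = window[12 + 21 + 8 + 2 : 12 + 21 + 8 + 2 + 21]
        assert cand.star == expected
        assert cand.five_prime_u is True

    def test_mature_spanning_terminal_loop_rejected(self, rng):
        arm = _random_seq(rng, 21)
        loop = _random_seq(rng, 8)
        window = (
            _random_seq(rng, 12)
            + arm
            + loop
            + reverse_complement(arm)
            + _random_seq(rng, 12)
        )
        mature = window[12 + 12 : 12 + 12 + 21]  # straddles the loop
        assert evaluate_hairpin(window, mature, fold(window)) is None

    def test_paired_base_threshold_boundary(self):
        """Exactly min_paired_mature paired bases accepted; one fewer not.

        The mature's tail is poly-C and the loop poly-A, so only the
        provided partial star can pair the mature and the paired count is
        controlled exactly.
        """
        mature = "TAGTGATGGTCAGAG" + "C" * 6
        criteria = HairpinCriteria(min_paired_mature=15, max_mismatches_in_duplex=6)
        for n_paired, accepted in ((15, True), (14, False)):
            partial_star = reverse_complement(mature[:n_paired])
            window = "C" * 8 + mature + "A" * 8 + partial_star + "C" * 8
            cand = evaluate_hairpin(window, mature, fold(window), criteria)
            assert (cand is not None) is accepted

    def test_five_prime_u_flag_on_printed_novel_sequence(self):
        mature = "TTGGCTTGGAGATGGATCATT"
        window = "GCAC" + mature + "CAAACAAA" + reverse_complement(mature) + "GTAC"
        cand = evaluate_hairpin(window, mature, fold(window))
        assert cand is not None and cand.five_prime_u is True

    def test_mature_not_in_window_errors(self, rng):
        _, window = _perfect_hairpin(rng)
        with pytest.raises(ValueError):
            evaluate_hairpin(window, "G" * 21, fold(window))


class TestDetectStar:
    def test_exact_star_detected_with_count(self, rng):
        mature, window = _perfect_hairpin(rng)
        cand = evaluate_hairpin(window, mature, fold(window))
        lib = TagLibrary("x", {cand.star: 7})
        assert detect_star(cand, lib) == 7

    def test_shifted_star_within_tolerance_detected(self, rng):
        mature, window = _perfect_hairpin(rng)
        cand = evaluate_hairpin(window, mature, fold(window))
        s0 = window.find(cand.star)
        shifted = window[s0 - 1 : s0 + len(cand.star) + 1]
        assert detect_star(cand, TagLibrary("x", {shifted: 3}), tolerance=2) == 3
        assert detect_star(cand, TagLibrary("x", {shifted: 3}), tolerance=0) is None

    def test_absent_star_returns_none(self, rng):
        mature, window = _perfect_hairpin(rng)
        cand = evaluate_hairpin(window, mature, fold(window))
        lib = TagLibrary("x", {_random_seq(rng, 21): 50})
        assert detect_star(cand, lib) is None

    def test_planted_stars_flagged_exactly(self, rng):
        """Stars planted for half of 20 hairpins: exactly those flagged."""
        hairpins = []
        genome_parts = []
        pos = 0
        for i in range(20):
            spacer = _random_seq(rng, 80)
            mature, window = _perfect_hairpin(rng)
            genome_parts += [spacer, window]
            pos += 80
            hairpins.append((mature, pos))
            pos += len(window)
        genome = {"chr1": "".join(genome_parts)}
        tags = {}
        star_truth = {}
        for i, (mature, start) in enumerate(hairpins):
            tags[mature] = 50
            cand = evaluate_hairpin(
                genome["chr1"][start : start + 74], mature, fold(genome["chr1"][start : start + 74])
            )
            star_truth[mature] = i % 2 == 0
            if i % 2 == 0:
                tags[cand.star] = 9
        lib = TagLibrary("all", tags)
        cands = discover_hairpins(
            {t: {"all": c} for t, c in tags.items()},
            genome,
            libraries=[lib],
        )
        flagged = {c.mature: c.star_detected for c in cands}
        for mature, expected in star_truth.items():
            assert flagged[mature] is expected


class TestDiscovery:
    def test_planted_hairpins_recovered_no_false_positives(
        self, small_bundle, small_tag_libraries, small_unannotated
    ):
        _, genome, truth, _ = small_bundle
        cands = discover_hairpins(
            small_unannotated,
            genome,
            libraries=list(small_tag_libraries.values()),
        )
        planted = {hp.mature for hp in truth.hairpins}
        recovered = {c.mature for c in cands} & planted
        assert len(recovered) == len(planted)

    def test_shuffled_genome_yields_no_candidates(
        self, small_bundle, small_tag_libraries, small_unannotated
    ):
        from vitismir.simulate import shuffle_genome

        _, genome, _, _ = small_bundle
        shuffled = shuffle_genome(genome, 4242)
        cands = discover_hairpins(
            small_unannotated,
            shuffled,
            libraries=list(small_tag_libraries.values()),
        )
        assert cands == []

    def test_multi_locus_tag_yields_candidate_per_locus(self, rng):
        """The same mature planted at two distant loci is reported twice
        with shared (not multiplied) abundance."""
        mature, window = _perfect_hairpin(rng)
        genome = {
            "chr1": _random_seq(rng, 300)
            + window
            + _random_seq(rng, 600)
            + window
            + _random_seq(rng, 300)
        }
        lib = TagLibrary("all", {mature: 40})
        cands = discover_hairpins(
            {mature: {"all": 40}}, genome, libraries=[lib]
        )
        assert len(cands) == 2
        assert all(c.mature == mature for c in cands)
        assert all(c.mature_counts == {"all": 40} for c in cands)
        starts = {c.precursor_interval.start for c in cands}
        assert len(starts) == 2
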