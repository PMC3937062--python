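"""Target prediction against a brute-force scorer, and cleavage validation."""

import pytest

from vitismir.seqio import NucleotideSequence, reverse_complement
from vitismir.targets import (
    CleavageObservation,
    PairingRules,
    TargetSite,
    predict_targets,
    score_site,
    validate_cleavage,
)

COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def brute_force_sites(mirna, transcript, max_mismatch, positional):
    """Independent all-windows scorer re-deriving every rule from scratch."""
    n = len(mirna)
    out = []
    for start in range(len(transcript) - n + 1):
        window = transcript[start : start + n]
        total = 0.0
        seed = 0.0
        ok = True
        for p in range(1, n + 1):
            m, t = mirna[p - 1], window[n - p]
            if COMP[m] == t:
                cost = 0.0
            elif (m, t) in (("G", "T"), ("T", "G")):
                cost = 0.5
            else:
                cost = 1.0
            total += cost
            if positional and p in (10, 11) and cost > 0:
                ok = False
            if 2 <= p <= 12:
                seed += cost
        if positional and seed > 1.0:
            ok = False
        if ok and total <= max_mismatch:
            out.append((start, total))
    return out


class TestPredictTargets:
    def test_exact_reverse_complement_is_zero_mismatch_site(self, rng):
        mirna = _random_seq(rng, 21)
        tx = NucleotideSequence(
            "t1", _random_seq(rng, 100) + reverse_complement(mirna) + _random_seq(rng, 100)
        )
        sites = predict_targets(mirna, [tx])
        assert len(sites) == 1
        assert sites[0].start == 100 and sites[0].mismatches == 0.0

    def test_four_mismatches_excluded(self, rng):
        """The budget is strictly below four mismatches."""
        mirna = _random_seq(rng, 21)
        site = list(reverse_complement(mirna))
        # flip 4 positions outside the seed/cleavage-critical region
        for pos in (0, 2, 4, 6):  # transcript positions pair miRNA 16-21
            site[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[pos]]
        tx = NucleotideSequence("t1", "AC" * 30 + "".join(site) + "TG" * 30)
        assert predict_targets(mirna, [tx], max_mismatch=3, rules=None) == []

    def test_planted_sites_recovered_decoys_rejected(self, rng):
        """Sites planted at 0-3 mismatches found, 4-6-mismatch decoys not,
        matching the brute-force scorer exactly."""
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        mirna = _random_seq(rng, 21)
        rc = reverse_complement(mirna)
        for trial in range(30):
            n_mm = int(rng.integers(0, 7))
            site = list(rc)
            # mutate transcript positions pairing miRNA 13..21 (safe zone
            # for the positional rules), 9 slots — enough for 6 mismatches
            positions = rng.choice(9, size=n_mm, replace=False)
            for pos in positions:
                site[pos] = flip[site[pos]]
            tx = NucleotideSequence(
                f"t{trial}",
                _random_seq(rng, 50) + "".join(site) + _random_seq(rng, 50),
            )
            for positional in (True, False):
                rules = PairingRules() if positional else None
                got = sorted(
                    (s.start, s.mismatches)
                    for s in predict_targets(mirna, [tx], 3.0, rules)
                )
                expected = sorted(
                    brute_force_sites(mirna, tx.residues, 3.0, positional)
                )
                assert got == expected
                if n_mm <= 3:
                    assert (50, float(n_mm)) in got
                else:
                    assert (50, float(n_mm)) not in got

    def test_gu_wobble_counts_half(self, rng):
        mirna = "A" * 21  # pairs poly-T site
        site = list("T" * 21)
        site[0] = "G"  # A:G -> full mismatch? no: miRNA A vs t G -> mismatch 1
        tx = NucleotideSequence("t1", "".join(site))
        s = predict_targets(mirna, [tx], rules=None)
        assert s[0].mismatches == 1.0
        mirna2 = "G" + "A" * 20  # miRNA position 21 is G... site base T
        tx2 = NucleotideSequence("t2", "T" * 20 + "T")
        s2 = predict_targets(mirna2, [tx2], rules=None)
        assert s2[0].mismatches == 0.5  # G:U wobble

    def test_no_near_complement_yields_no_sites(self):
        mirna = "A" * 21
        tx = NucleotideSequence("t1", "A" * 200)  # A cannot pair A
        assert predict_targets(mirna, [tx], rules=None) == []

    def test_positional_rule_blocks_cleavage_site_mismatch(self, rng):
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        mirna = _random_seq(rng, 21)
        site = list(reverse_complement(mirna))
        site[11] = flip[site[11]]  # transcript base pairing miRNA position 10
        tx = NucleotideSequence("t1", "".join(site))
        assert predict_targets(mirna, [tx], rules=PairingRules()) == []
        assert len(predict_targets(mirna, [tx], rules=None)) == 1


class TestValidateCleavage:
    def _site(self, start=100, length=21, tid="t1"):
        return TargetSite("m1", tid, start, start + length, 0.0, "A" * length)

    def test_position_ten_supported(self):
        site = self._site()
        obs = CleavageObservation("t1", site.end - 10)
        status, pos = validate_cleavage(site, obs)
        assert (status, pos) == ("supported", 10)

    def test_position_two_unsupported(self):
        site = self._site()
        obs = CleavageObservation("t1", site.end - 2)
        status, pos = validate_cleavage(site, obs)
        assert (status, pos) == ("unsupported", 2)

    def test_sliding_coordinate_marks_exactly_three_supported(self):
        site = self._site()
        supported = [
            c
            for c in range(site.start - 5, site.end + 5)
            if validate_cleavage(site, CleavageObservation("t1", c))[0]
            == "supported"
        ]
        assert len(supported) == 3
        assert supported == [site.end - 11, site.end - 10, site.end - 9]

    def test_outside_site_unsupported_with_undefined_index(self):
        site = self._site()
        status, pos = validate_cleavage(site, CleavageObservation("t1", 5))
        assert (status, pos) == ("unsupported", None)

    def test_position_invariant_under_coordinate_shift(self):
        for shift in (0, 50, 1234):
            site = self._site(start=100 + shift)
            obs = CleavageObservation("t1", site.end - 10)
            assert validate_cleavage(site, obs)[1] == 10

    def test_wrong_transcript_errors(self):
        site = self._site()
        with pytest.raises(ValueError):
            validate_cleavage(site, CleavageObservation("other", 105))


def test_score_site_rejects_length_mismatch():
    with pytest.raises(ValueError):
        score_site("ACGTACGTACGTACGTACGTA", "ACGT")
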