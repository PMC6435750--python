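import numpy as np
import pytest
from hypothesis import given, strategies as st

import v4clades as v
from v4clades.primer_screen import InvalidIUPACError
from v4clades.signatures import IUPAC_SETS

codes = st.sampled_from(sorted(IUPAC_SETS))


class TestIupacMatch:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("R", "A", True), ("R", "G", True), ("R", "C", False), ("A", "A", True),
         ("A", "T", False), ("S", "W", False), ("K", "M", False), ("K", "S", True)],
    )
    def test_examples(self, a, b, expected):
        assert v.iupac_match(a, b) is expected

    @given(codes)
    def test_n_matches_everything(self, x):
        assert v.iupac_match("N", x) and v.iupac_match(x, "N")

    @given(codes, codes)
    def test_agrees_with_base_set_intersection_and_is_symmetric(self, a, b):
        expected = bool(IUPAC_SETS[a] & IUPAC_SETS[b])
        assert v.iupac_match(a, b) is expected is v.iupac_match(b, a)

    def test_invalid_code_rejected(self):
        with pytest.raises(InvalidIUPACError):
            v.iupac_match("X", "A")


class TestReverseComplement:
    def test_plain(self):
        assert v.reverse_complement("ACGT") == "ACGT"
        assert v.reverse_complement("AACGT") == "ACGTT"

    @given(st.text(alphabet=sorted(set(IUPAC_SETS) - {"U"}), min_size=1, max_size=40))
    def test_involution_on_dna_codes(self, seq):
        assert v.reverse_complement(v.reverse_complement(seq)) == seq

    def test_u_complements_like_t(self):
        assert v.reverse_complement("U") == "A"


class TestLocateAndCount:
    target = "GGGGG" + "ACGTACGTAC" + "TTTTT"

    def test_exact_presence_zero_mismatches(self):
        site = v.locate_and_count("ACGTACGTAC", self.target)
        assert site.mismatch_count == 0 and site.start == 6

    def test_single_planted_substitution_located(self):
        site = v.locate_and_count("ACGAACGTAC", self.target)
        assert site.mismatch_positions == (4,) and site.start == 6

    def test_degenerate_base_covers_target(self):
        assert v.locate_and_count("ACRT", "TTACGTTT").mismatch_count == 0

    def test_antisense_scans_reverse_complement(self):
        # oligo equals revcomp of a target segment
        oligo = v.reverse_complement("ACGTACGTAC")
        site = v.locate_and_count(oligo, self.target, orientation="antisense")
        assert site.mismatch_count == 0

    def test_tie_broken_leftmost(self):
        site = v.locate_and_count("AA", "CACACC")
        assert site.start == 1 and site.mismatch_count == 1

    def test_oligo_longer_than_target_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            v.locate_and_count("ACGTACGT", "ACG")

    def test_zero_mismatch_iff_pattern_window_match(self):
        rng = np.random.default_rng(6)
        bases = list("ACGT")
        for _ in range(50):
            target = "".join(rng.choice(bases, 40))
            oligo = "".join(rng.choice(bases, 8))
            site = v.locate_and_count(oligo, target)
            windows = [target[i:i + 8] for i in range(33)]
            exact = any(
                all(v.iupac_match(a, b) for a, b in zip(oligo, w)) for w in windows
            )
            assert (site.mismatch_count == 0) == exact


def planted_assay(rng=None):
    """A synthetic amplicon carrying perfect binding sites for a synthetic set."""
    fwd = "GCCATTCGAACTGTGAT"
    probe = "CCTACCGGACTAGGAT"
    rev_site = "GTACTGGACCTTAACGGA"  # on the sense strand
    pset = v.PrimerSet("SYN", fwd, probe, v.reverse_complement(rev_site))
    amplicon = fwd + "ACGTACGT" + probe + "TTGCAAGG" + rev_site
    return pset, amplicon


class TestEvaluatePrimerSet:
    def test_perfect_amplicon_zero_everywhere(self):
        pset, amplicon = planted_assay()
        report = v.evaluate_primer_set(pset, amplicon)
        assert report.total == 0
        assert all(r.binding_site_found for r in report.oligos.values())

    def test_planted_mismatch_pattern_recovered(self):
        # one substitution in the forward site (3' terminal), one in the probe
        # site, two in the reverse site: per-oligo counts 1/1/2, total 4
        pset, amplicon = planted_assay()
        mutated = list(amplicon)
        mutated[16] = "A"   # forward oligo position 17 (last base, 3' end)
        mutated[27] = "G"   # probe position 3
        mutated[51] = "C"   # reverse site -> reverse oligo
        mutated[55] = "T"
        report = v.evaluate_primer_set(pset, "".join(mutated))
        counts = {k: r.mismatch_count for k, r in report.oligos.items()}
        assert counts == {"forward": 1, "probe": 1, "reverse": 2}
        assert report.total == 4
        assert report.oligos["forward"].three_prime_flag
        assert not report.oligos["probe"].three_prime_flag

    def test_three_prime_window_is_configurable(self):
        pset, amplicon = planted_assay()
        mutated = list(amplicon)
        mutated[12] = "C"  # forward position 13 of 17: within window 5, not 3
        report3 = v.evaluate_primer_set(pset, "".join(mutated), three_prime_window=3)
        report5 = v.evaluate_primer_set(pset, "".join(mutated), three_prime_window=5)
        assert not report3.oligos["forward"].three_prime_flag
        assert report5.oligos["forward"].three_prime_flag

    def test_unplaceable_oligo_reported_not_raised(self):
        pset, amplicon = planted_assay()
        report = v.evaluate_primer_set(pset, amplicon[:10])
        assert not report.oligos["reverse"].binding_site_found
        assert report.oligos["reverse"].mismatch_count is None
        assert report.total is None

    def test_counts_invariant_under_joint_reverse_complement(self):
        rng = np.random.default_rng(3)
        bases = list("ACGTRYSWKMN")
        for _ in range(20):
            target = "".join(rng.choice(list("ACGT"), 40))
            oligo = "".join(rng.choice(bases, 8))
            direct = v.locate_and_count(oligo, target)
            flipped = v.locate_and_count(
                v.reverse_complement(oligo), v.reverse_complement(target)
            )
            assert direct.mismatch_count == flipped.mismatch_count

    def test_total_monotone_in_planted_substitutions(self):
        pset, amplicon = planted_assay()
        rng = np.random.default_rng(12)
        positions = rng.permutation(len(pset.forward))[:4]
        totals = []
        mutated = list(amplicon)
        for p in positions:
            old = mutated[p]
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
            totals.append(v.evaluate_primer_set(pset, "".join(mutated)).total)
        assert totals == sorted(totals)


class TestPrimerSetIO:
    def test_read_sets_from_tsv(self, tmp_path):
        p = tmp_path / "sets.tsv"
        p.write_text("name\tforward\tprobe\treverse\nOI\tACGT\tGGCC\tTTAA\n")
        sets = v.read_primer_sets(p)
        assert sets[0].name == "OI" and sets[0].reverse == "TTAA"

    def test_invalid_oligo_rejected(self):
        with pytest.raises(InvalidIUPACError):
            v.PrimerSet("bad", "ACGT", "AXGT", "ACGT")
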