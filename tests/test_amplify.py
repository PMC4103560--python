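import numpy as np
import pytest

from cladeamp import amplify, synthdata
from cladeamp.amplify import (
    MSPI,
    RestrictionEnzyme,
    digest,
    nested_screen,
    predict_amplicons,
    rflp_group,
)
from cladeamp.errors import ValidationError
from cladeamp.seqcore import NucleotideSequence, Primer, reverse_complement


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


FWD = Primer("fwd", "GGAAACTCATCAGGACAAGAAGATT", "forward")
REV = Primer("rev", "GGGCGATGTGTACATTTTG", "reverse")


def build_template(rng, insert_len=400, pad=50, fwd=FWD, rev=REV, tid="t"):
    """[pad, fwd site, insert, revcomp(rev) site, pad]"""
    return NucleotideSequence(
        tid,
        rand_seq(rng, pad) + fwd.sequence + rand_seq(rng, insert_len)
        + reverse_complement(rev.sequence) + rand_seq(rng, pad),
    )


class TestPredictAmplicons:
    def test_constructed_coordinates(self):
        rng = np.random.default_rng(1)
        t = build_template(rng)
        products = predict_amplicons(FWD, REV, [t], max_mismatches=0)
        assert len(products) == 1
        p = products[0]
        assert p.product_length == len(FWD) + 400 + len(REV)
        assert p.forward_site.start == 51
        assert p.product_sequence == t.residues[50 : 50 + p.product_length]

    def test_missing_reverse_site(self):
        rng = np.random.default_rng(2)
        t = NucleotideSequence("t", rand_seq(rng, 60) + FWD.sequence + rand_seq(rng, 300))
        assert predict_amplicons(FWD, REV, [t], max_mismatches=0) == []

    def test_3p_terminal_mismatch_toggles_amplification(self):
        rng = np.random.default_rng(3)
        t = build_template(rng)
        # mutate the forward primer's 3' terminal template base (T -> C)
        idx = 50 + len(FWD) - 1
        chars = list(t.residues)
        assert chars[idx] == "T"
        chars[idx] = "C"
        mutated = NucleotideSequence("t", "".join(chars))
        strict = predict_amplicons(FWD, REV, [mutated], max_mismatches=2,
                                   forbid_3p_terminal_mismatch=True)
        lenient = predict_amplicons(FWD, REV, [mutated], max_mismatches=2,
                                    forbid_3p_terminal_mismatch=False)
        assert strict == []
        assert len(lenient) == 1

    def test_exact_mode_agrees_with_substring_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = NucleotideSequence("t", rand_seq(rng, 300))
            products = predict_amplicons(FWD, REV, [t], max_mismatches=0)
            fstarts = [
                i for i in range(len(t.residues) - len(FWD) + 1)
                if t.residues[i:i + len(FWD)] == FWD.sequence
            ]
            rc = reverse_complement(REV.sequence)
            rstarts = [
                i for i in range(len(t.residues) - len(REV) + 1)
                if t.residues[i:i + len(REV)] == rc
            ]
            expected = sum(
                1 for f in fstarts for r in rstarts if r > f + len(FWD) - 1
            )
            assert len(products) == expected

    def test_length_bounds_filter(self):
        rng = np.random.default_rng(5)
        t = build_template(rng, insert_len=400)
        assert predict_amplicons(FWD, REV, [t], 0, True, (100, 200)) == []
        assert len(predict_amplicons(FWD, REV, [t], 0, True, (400, 500))) == 1

    def test_requires_proper_orientations(self):
        with pytest.raises(ValidationError):
            predict_amplicons(REV, REV, [], 0)


class TestNestedScreen:
    def test_planted_library_split(self):
        # 50 clones: 11 with both outer+inner sites, the rest outer-only
        rng = np.random.default_rng(11)
        outer_f = Primer("outerF", "AACCTGGTTGATCCTGCCAGT", "forward")
        target = NucleotideSequence(
            "peritrich",
            rand_seq(rng, 30) + outer_f.sequence + rand_seq(rng, 200)
            + FWD.sequence + rand_seq(rng, 400)
            + reverse_complement(REV.sequence) + rand_seq(rng, 30),
        )
        alga = NucleotideSequence(
            "alga",
            rand_seq(rng, 30) + outer_f.sequence + rand_seq(rng, 625)
            + reverse_complement(REV.sequence) + rand_seq(rng, 30),
        )
        clones = synthdata.generate_library(
            synthdata.LibrarySpec(
                templates=(target, alga), proportions=(0.22, 0.78),
                n_clones=50, chimera_fraction=0.0, seed=2,
            )
        )
        n_from_target = sum(1 for c in clones if c.parents == ("peritrich",))
        result = nested_screen(
            (outer_f, REV), (FWD, REV),
            [c.sequence for c in clones], max_mismatches=0,
        )
        inner_pos = sum(1 for r in result.values() if r["inner_positive"])
        outer_pos = sum(1 for r in result.values() if r["outer_product"])
        assert inner_pos == n_from_target
        assert outer_pos == 50

    def test_inner_without_outer_is_negative(self):
        rng = np.random.default_rng(12)
        outer_f = Primer("outerF", "AACCTGGTTGATCCTGCCAGT", "forward")
        t = build_template(rng)  # inner sites only
        result = nested_screen((outer_f, REV), (FWD, REV), [t], max_mismatches=0)
        assert result["t"] == {"outer_product": False, "inner_positive": False}

    def test_inner_positive_subset_of_outer_positive(self):
        rng = np.random.default_rng(13)
        outer_f = Primer("outerF", "AACCTGGTTGATCCTGCCAGT", "forward")
        templates = []
        for i in range(20):
            kind = rng.integers(3)
            if kind == 0:
                templates.append(build_template(rng, tid=f"t{i}"))
            elif kind == 1:
                templates.append(NucleotideSequence(f"t{i}", rand_seq(rng, 500)))
            else:
                templates.append(
                    NucleotideSequence(
                        f"t{i}",
                        rand_seq(rng, 20) + outer_f.sequence + rand_seq(rng, 300)
                        + reverse_complement(REV.sequence) + rand_seq(rng, 20),
                    )
                )
        result = nested_screen((outer_f, REV), (FWD, REV), templates)
        for r in result.values():
            assert not (r["inner_positive"] and not r["outer_product"])


class TestDigest:
    def test_mspi_worked_example(self):
        pattern = digest("AACCGGTT", MSPI, "linear")
        assert pattern.fragment_lengths == (5, 3)

    def test_no_site_single_fragment(self):
        assert digest("ATATATAT", MSPI).fragment_lengths == (8,)

    def test_circular_counts(self):
        # two sites on a circle -> two fragments
        mol = "CCGG" + "A" * 10 + "CCGG" + "T" * 6
        assert len(digest(mol, MSPI, "circular").fragment_lengths) == 2
        assert digest("ATATAT", MSPI, "circular").fragment_lengths == (6,)

    def test_conservation_over_random_molecules(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(10, 2001))
            mol = rand_seq(rng, n)
            assert digest(mol, MSPI).total_length == n

    def test_iupac_site_awareness(self):
        # template carrying an N inside a potential site still cuts (N is
        # compatible with the recognition bases)
        assert digest("AACNGGTT", MSPI).fragment_lengths == (5, 3)

    def test_nonpalindromic_enzyme_cuts_both_strands(self):
        # site GACGT (made up, non-palindromic), offset 1
        enz = RestrictionEnzyme("toy", "GACGT", 1)
        mol = "TT" + "GACGT" + "TTTT" + reverse_complement("GACGT") + "TT"
        frags = digest(mol, enz).fragment_lengths
        assert sum(frags) == len(mol)
        assert len(frags) == 3

    def test_cut_offset_bounds(self):
        with pytest.raises(ValidationError):
            RestrictionEnzyme("bad", "CCGG", 5)


class TestRflpGroup:
    def _amplicon_set(self, patterns, rng):
        """Molecules whose MspI digests realise the given fragment patterns."""
        molecules = []
        for i, frags in enumerate(patterns):
            parts = []
            for j, f in enumerate(frags):
                if j == 0:
                    # first fragment ends right before a cut: ...C | CGG...
                    parts.append(self._free_of_site(rng, f - 1) + "C")
                else:
                    parts.append("CGG" + self._free_of_site(rng, f - 4) + "C")
            mol = "".join(parts)[:-1] + "A"  # drop trailing C to avoid a cut
            molecules.append(NucleotideSequence(f"m{i}", mol))
        return molecules

    @staticmethod
    def _free_of_site(rng, n):
        # A/T-only filler cannot create or extend a CCGG site
        return "".join(rng.choice(list("AT"), size=max(n, 0)))

    def test_identical_sequences_one_group(self):
        rng = np.random.default_rng(23)
        mol = NucleotideSequence("a", rand_seq(rng, 500))
        twin = NucleotideSequence("b", mol.residues)
        groups = rflp_group([mol, twin], MSPI, size_tolerance_bp=0)
        assert len(groups) == 1

    def test_planted_distinct_patterns(self):
        rng = np.random.default_rng(29)
        mols = self._amplicon_set([(200, 100), (150, 150), (300,)], rng)
        groups = rflp_group(mols, MSPI, size_tolerance_bp=0)
        assert len(groups) == 3

    def test_large_tolerance_merges_everything(self):
        rng = np.random.default_rng(31)
        mols = self._amplicon_set([(200, 100), (195, 105), (210, 90)], rng)
        assert len(rflp_group(mols, MSPI, size_tolerance_bp=1000)) == 1

    def test_group_count_nonincreasing_in_tolerance(self):
        rng = np.random.default_rng(37)
        mols = [NucleotideSequence(f"m{i}", rand_seq(rng, 800)) for i in range(30)]
        counts = [len(rflp_group(mols, MSPI, tol)) for tol in (0, 5, 10, 25, 100, 1000)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_under_permutation(self):
        rng = np.random.default_rng(41)
        mols = [NucleotideSequence(f"m{i}", rand_seq(rng, 600)) for i in range(15)]
        g1 = rflp_group(mols, MSPI, 10)
        g2 = rflp_group(list(reversed(mols)), MSPI, 10)
        assert g1 == g2
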