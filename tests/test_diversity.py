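"""Site spectrum, π, and Nei–Gojobori site / pathway counting."""

import itertools
import math
import random

import pytest

from sfbkit import (
    Alignment,
    CodonAlignment,
    SequenceRecord,
    jukes_cantor,
    ka_ks,
    ng_codon_differences,
    ng_site_counts,
    nucleotide_diversity,
    pi_syn_nonsyn,
    site_spectrum,
)
from sfbkit.alignment import STOP_CODONS, _STANDARD_TABLE
from sfbkit.diversity import (
    _codon_site_counts,
    classify_mutations,
    diversity_summary,
    diversity_table,
    largest_remainder_round,
    mean_pairwise_differences,
)

from conftest import make_alignment

SENSE_CODONS = sorted(_STANDARD_TABLE.forward_table)
AA = dict(_STANDARD_TABLE.forward_table)


class TestSiteSpectrum:
    def test_hand_enumerated_example(self, worked_examples):
        ex = worked_examples["site_spectrum_4seq"]
        spec = site_spectrum(ex["data"])
        m = ex["manifest"]
        assert (spec.S, spec.eta, spec.singletons, spec.parsimony_informative) == (
            m["S"], m["eta"], m["singletons"], m["parsimony_informative"]
        )

    def test_identical_sequences(self):
        spec = site_spectrum(make_alignment(["ACGT", "ACGT", "ACGT"]))
        assert spec.S == 0 and spec.eta == 0

    def test_triallelic_column_counts_two_mutations(self):
        aln = make_alignment(["A", "A", "C", "C", "G", "G"])
        spec = site_spectrum(aln)
        assert spec.S == 1 and spec.eta == 2

    def test_table3_identity_singletons_plus_informative(self):
        rng = random.Random(0)
        seqs = [
            "".join(rng.choice("ACGT") for _ in range(50)) if i == 0 else None
            for i in range(6)
        ]
        base = seqs[0]
        sample = [base]
        for _ in range(5):
            s = list(base)
            for _ in range(rng.randint(1, 8)):
                j = rng.randrange(50)
                s[j] = rng.choice("ACGT")
            sample.append("".join(s))
        spec = site_spectrum(make_alignment(sample))
        assert spec.singletons + spec.parsimony_informative == spec.S

    def test_order_invariance(self):
        seqs = ["AAGA", "ACGA", "ACGT", "AAGT"]
        specs = {
            site_spectrum(make_alignment(list(p)))
            for p in itertools.permutations(seqs)
        }
        assert len(specs) == 1

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            site_spectrum(make_alignment(["ACGT"]))


class TestNucleotideDiversity:
    def test_single_pair_proportion(self):
        aln = make_alignment(["AAAAAAAAAA", "AAAAAAAAAT"])
        assert nucleotide_diversity(aln) == pytest.approx(0.1)

    def test_jukes_cantor_closed_form(self):
        aln = make_alignment(["AAAAAAAAAA", "AAAAAAAAAT"])
        expected = -0.75 * math.log(1 - 0.4 / 3)
        assert nucleotide_diversity(aln, jc=True) == pytest.approx(expected)
        assert jukes_cantor(0.1) == pytest.approx(0.10732, abs=1e-5)

    def test_identical_sequences_zero(self):
        assert nucleotide_diversity(make_alignment(["ACGT"] * 4)) == 0.0

    def test_jc_undefined_above_three_quarters(self):
        aln = make_alignment(["AAAA", "CCCC"])
        with pytest.raises(ValueError, match="undefined"):
            nucleotide_diversity(aln, jc=True)

    def test_columnwise_identity_with_pairwise_definition(self):
        # π (jc off) = Σ_cols (pairwise mismatch fraction) / length
        rng = random.Random(1)
        seqs = ["".join(rng.choice("ACGT") for _ in range(20)) for _ in range(5)]
        aln = make_alignment(seqs)
        npairs = 5 * 4 / 2
        col_sum = 0.0
        for j in range(20):
            col = [s[j] for s in seqs]
            mism = sum(1 for a, b in itertools.combinations(col, 2) if a != b)
            col_sum += mism / npairs
        assert nucleotide_diversity(aln) == pytest.approx(col_sum / 20)


def brute_force_pathways(a, b):
    """Independent oracle: enumerate orderings explicitly as codon chains."""
    diff = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in itertools.permutations(diff):
        chain = [a]
        cur = a
        for pos in order:
            cur = cur[:pos] + b[pos] + cur[pos + 1 :]
            chain.append(cur)
        if any(c in STOP_CODONS for c in chain[1:-1]):
            continue
        nd = ns = 0
        for x, y in zip(chain, chain[1:]):
            if AA[x] == AA[y]:
                ns += 1
            else:
                nd += 1
        results.append((nd, ns))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestNeiGojobori:
    @pytest.mark.parametrize(
        "codon, syn, nonsyn",
        [
            ("TTT", 1 / 3, 8 / 3),  # only TTT->TTC synonymous
            ("ATG", 0.0, 3.0),      # Met: every change non-synonymous
        ],
    )
    def test_site_counts_examples(self, codon, syn, nonsyn):
        s, n = _codon_site_counts(codon)
        assert s == pytest.approx(syn) and n == pytest.approx(nonsyn)

    def test_stop_adjacent_codon_loses_sites(self):
        # TGG (Trp): TGA and TAG targets are stops, removed from denominators
        s, n = _codon_site_counts("TGG")
        assert s == 0.0 and n == pytest.approx(7 / 3)

    def test_site_totals_three_minus_stop_adjustment(self):
        for codon in SENSE_CODONS:
            s, n = _codon_site_counts(codon)
            stops = sum(
                1
                for pos in range(3)
                for alt in "ACGT"
                if alt != codon[pos]
                and codon[:pos] + alt + codon[pos + 1 :] in STOP_CODONS
            )
            assert s + n == pytest.approx(3 - stops / 3)

    @pytest.mark.parametrize(
        "a, b, nd, ns",
        [
            ("ATG", "ATA", 1.0, 0.0),
            ("TTT", "GTA", 1.5, 0.5),  # two 2-step pathways averaged
            ("AAA", "AAA", 0.0, 0.0),
        ],
    )
    def test_pathway_examples(self, a, b, nd, ns):
        assert ng_codon_differences(a, b) == (pytest.approx(nd), pytest.approx(ns))

    def test_pathways_sum_to_differing_positions(self):
        rng = random.Random(2)
        for _ in range(200):
            a, b = rng.sample(SENSE_CODONS, 2)
            nd, ns = ng_codon_differences(a, b)
            assert nd + ns == pytest.approx(sum(x != y for x, y in zip(a, b)))

    def test_site_counts_average_over_identical_sequences(self):
        aln = make_alignment(["ATGGAAATC"] * 3)
        sites = ng_site_counts(CodonAlignment(aln))
        s1, _ = _codon_site_counts("ATG")
        s2, _ = _codon_site_counts("GAA")
        s3, _ = _codon_site_counts("ATC")
        assert sites.syn_sites == pytest.approx(s1 + s2 + s3)


class TestPiPartition:
    def test_identical_alignment_is_zero_zero(self):
        caln = CodonAlignment(make_alignment(["ATGGAAATC"] * 3))
        assert pi_syn_nonsyn(caln) == (0.0, 0.0)

    def test_pure_synonymous_variation(self):
        # GAA vs GAG: synonymous third-position change, 100 codons context
        s1 = "GAA" * 50 + "GAA" + "ATG" * 49
        s2 = "GAA" * 50 + "GAG" + "ATG" * 49
        ps, pa = pi_syn_nonsyn(CodonAlignment(make_alignment([s1, s2])))
        assert pa == 0.0 and ps > 0.0

    def test_pure_nonsynonymous_variation(self):
        s1 = "ATG" * 50 + "GAA" * 50
        s2 = "ATG" * 49 + "ATA" + "GAA" * 50
        ps, pa = pi_syn_nonsyn(CodonAlignment(make_alignment([s1, s2])))
        assert ps == 0.0 and pa > 0.0


class TestKaKs:
    def test_identical_comparator_zero(self):
        seq = "ATGGAAATC" * 10
        caln = CodonAlignment(make_alignment([seq, seq]))
        comp = Alignment((SequenceRecord("out", seq),))
        assert ka_ks(caln, comp) == (0.0, 0.0)

    def test_ratio_of_printed_divergences(self):
        # the ratio field downstream of KA=0.025, KS=0.05
        assert 0.025 / 0.05 == pytest.approx(0.5)

    def test_empty_comparator_rejected(self):
        caln = CodonAlignment(make_alignment(["ATGGAA", "ATGGAG"]))
        with pytest.raises(ValueError):
            ka_ks(caln, make_alignment(["ATG"]))  # wrong length


class TestMutationClassification:
    def test_largest_remainder_preserves_total(self):
        assert largest_remainder_round([1.5, 2.5]) == [2, 2]
        assert largest_remainder_round([0.4, 0.6]) == [0, 1]
        assert largest_remainder_round([3.0, 4.0]) == [3, 4]

    def test_classification_order_invariant(self):
        seqs = ["ATGGAAATC", "ATGGAGATC", "ATGGAAATA", "ATGGAAATC"]
        base = classify_mutations(CodonAlignment(make_alignment(seqs)))
        for perm in itertools.permutations(seqs):
            caln = CodonAlignment(make_alignment(list(perm)))
            assert classify_mutations(caln) == base

    def test_summary_row_renders(self):
        seqs = ["ATGGAAATC", "ATGGAGATC", "ATGGAAGTA"]
        row = diversity_summary(CodonAlignment(make_alignment(seqs)), jc=False,
                                name="demo")
        tsv = diversity_table([row])
        header, data = tsv.strip().split("\n")
        assert header.startswith("Name\tN\tPoly.S")
        assert data.split("\t")[0] == "demo"
        assert row.syn_mut + row.nonsyn_mut == row.spectrum.eta


class TestMeanPairwiseDifferences:
    def test_two_sequences(self):
        aln = make_alignment(["AAAA", "AATT"])
        assert mean_pairwise_differences(aln) == 2.0
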