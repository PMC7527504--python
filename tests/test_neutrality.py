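"""Tajima's D, Fu & Li's D*/F* and the McDonald–Kreitman test."""

import itertools
import math

import pytest

from sfbkit import (
    Alignment,
    CodonAlignment,
    SequenceRecord,
    fu_li_no_outgroup,
    mk_test,
    tajima_D,
    tajima_D_partitioned,
    tajima_constants,
)
from sfbkit.neutrality import MKTable, neutrality_table

from conftest import make_alignment


class TestTajimaConstants:
    def test_harmonic_sum_n4(self):
        assert tajima_constants(4)["a1"] == pytest.approx(1 + 0.5 + 1 / 3)

    def test_n2_a1_is_one(self):
        assert tajima_constants(2)["a1"] == 1.0

    @pytest.mark.parametrize("n", [4, 5, 13, 50])
    def test_denominator_positive(self, n):
        c = tajima_constants(n)
        for S in (1, 5, 40):
            assert c["e1"] * S + c["e2"] * S * (S - 1) > 0

    def test_n3_single_site_variance_degenerate(self):
        # at n=3 the e1 coefficient vanishes exactly, so S=1 gives zero
        # variance and D is reported as undefined rather than infinite
        c = tajima_constants(3)
        assert c["e1"] == pytest.approx(0.0, abs=1e-15)
        res = tajima_D(make_alignment(["AAA", "AAT", "AAA"]))
        assert res.D is None and res.S == 1


class TestTajimaD:
    def test_no_variation_undefined(self):
        res = tajima_D(make_alignment(["ACGT"] * 5))
        assert res.D is None and res.S == 0

    def test_numerator_identity_gives_zero(self):
        # whenever k_hat equals S/a1 the statistic is exactly zero
        from sfbkit.neutrality import _tajima_from_counts

        c = tajima_constants(5)
        res = _tajima_from_counts(n=5, S=25, k_hat=25 / c["a1"])
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_two_sequences_variance_degenerate(self):
        # n=2 makes every variance coefficient vanish; D is undefined
        res = tajima_D(make_alignment(["AAAAAA", "AATTAA"]))
        assert res.D is None and res.k_hat == res.S == 2

    def test_excess_singletons_negative(self):
        base = "A" * 30
        seqs = [base] * 10
        # 8 singleton variants on distinct sites in distinct sequences
        seqs = [
            (base[:i] + "T" + base[i + 1 :]) if i < 8 else base
            for i in range(10)
        ]
        res = tajima_D(make_alignment(seqs))
        assert res.D is not None and res.D < 0

    def test_column_order_invariance(self):
        seqs = ["AAGT", "ACGT", "ACGA", "AAGA"]
        ref = tajima_D(make_alignment(seqs)).D
        perm = [s[::-1] for s in seqs]
        assert tajima_D(make_alignment(perm)).D == pytest.approx(ref)


class TestTajimaPartitioned:
    def test_pure_synonymous_leaves_nonsyn_undefined(self):
        s1 = "GAA" * 30
        variants = [s1, "GAG" + "GAA" * 29,
                    "GAA" * 15 + "GAG" + "GAA" * 14, s1]
        d_s, d_a = tajima_D_partitioned(CodonAlignment(make_alignment(variants)))
        assert d_a.D is None and d_a.S == 0
        assert d_s.D is not None and d_s.S == 2

    def test_monomorphic_both_undefined(self):
        d_s, d_a = tajima_D_partitioned(CodonAlignment(make_alignment(["ATGGAA"] * 4)))
        assert d_s.D is None and d_a.D is None

    def test_neutral_symmetry_over_replicates(self):
        # omega=1 simulations: D_S and D_A track each other on average
        from sfbkit.simulate import SimConfig, simulate_codon_sample

        ds_vals, da_vals = [], []
        for i in range(30):
            cfg = SimConfig(seed=4_000 + i, n=13, theta=30.0, L=300, omega=1.0)
            focal, _ = simulate_codon_sample(cfg)
            d_s, d_a = tajima_D_partitioned(focal)
            if d_s.D is not None and d_a.D is not None:
                ds_vals.append(d_s.D)
                da_vals.append(d_a.D)
        assert len(ds_vals) >= 20
        mean_gap = abs(sum(ds_vals) / len(ds_vals) - sum(da_vals) / len(da_vals))
        assert mean_gap < 0.4


class TestFuLi:
    def test_all_singletons_negative(self):
        base = "A" * 40
        seqs = [base[:i] + "T" + base[i + 1 :] for i in range(13)]
        res = fu_li_no_outgroup(make_alignment(seqs))
        assert res.eta_s == res.eta == 13
        assert res.D_star < 0 and res.F_star < 0

    def test_no_singletons_positive(self):
        base = "A" * 20
        variant = "T" * 5 + "A" * 15
        seqs = [variant] * 6 + [base] * 7  # all variants shared by 6 sequences
        res = fu_li_no_outgroup(make_alignment(seqs))
        assert res.eta_s == 0 and res.eta == 5
        assert res.D_star > 0 and res.F_star > 0

    def test_monomorphic_undefined(self):
        res = fu_li_no_outgroup(make_alignment(["ACGT"] * 5))
        assert res.D_star is None and res.F_star is None

    def test_requires_three_sequences(self):
        with pytest.raises(ValueError):
            fu_li_no_outgroup(make_alignment(["AA", "AT"]))


def hypergeometric_fisher(table):
    """Independent oracle: full enumeration of the conditional null."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


class TestMKTest:
    def _mk_inputs(self):
        # hand-built: focal polymorphic at codon 2 (GAA/GAG syn), codon 3
        # (ATC/ATA? no — AAA/ACA nonsyn); fixed difference at codon 1 vs outgroup
        focal = make_alignment([
            "ATGGAAAAA",
            "ATGGAGAAA",
            "ATGGAAACA",
            "ATGGAAAAA",
        ])
        outgroup = Alignment((SequenceRecord("anc", "CTGGAAAAA"),))  # ATG->CTG M->L
        return CodonAlignment(focal), outgroup

    def test_hand_classified_counts(self):
        caln, outgroup = self._mk_inputs()
        mk = mk_test(caln, outgroup)
        assert (mk.f_S, mk.f_A) == (0, 1)   # M->L fixed, non-synonymous
        assert (mk.P_S, mk.P_A) == (1, 1)   # GAA/GAG syn; AAA/ACA (K->T) nonsyn

    def test_polymorphic_wins_over_fixed(self):
        # focal varies at codon 1 AND differs from outgroup there: counted
        # polymorphic only
        focal = make_alignment(["ATGGAA", "ATAGAA"])
        outgroup = Alignment((SequenceRecord("anc", "CTGGAA"),))
        mk = mk_test(CodonAlignment(focal), outgroup)
        assert mk.f_S + mk.f_A == 0
        assert mk.P_A == 1

    def test_identical_to_outgroup_all_zero(self):
        seq = "ATGGAAATC"
        mk = mk_test(
            CodonAlignment(make_alignment([seq, seq])),
            Alignment((SequenceRecord("anc", seq),)),
        )
        assert (mk.f_S, mk.f_A, mk.P_S, mk.P_A) == (0, 0, 0, 0)
        assert mk.ratio_fixed is None and mk.p_value is None

    def test_sequence_order_invariance(self):
        caln, outgroup = self._mk_inputs()
        base = mk_test(caln, outgroup)
        seqs = [r.seq for r in caln.alignment]
        for perm in itertools.permutations(range(len(seqs))):
            aln = make_alignment([seqs[i] for i in perm])
            mk = mk_test(CodonAlignment(aln), outgroup)
            assert (mk.f_S, mk.f_A, mk.P_S, mk.P_A) == (
                base.f_S, base.f_A, base.P_S, base.P_A
            )

    @pytest.mark.parametrize(
        "table",
        [[[5, 18], [34, 118]], [[19, 31], [53, 141]], [[2, 7], [11, 3]],
         [[1, 1], [1, 1]], [[0, 5], [8, 2]]],
    )
    def test_fisher_matches_hypergeometric_enumeration(self, table):
        from scipy.stats import fisher_exact

        p_scipy = fisher_exact(table, alternative="two-sided")[1]
        assert p_scipy == pytest.approx(hypergeometric_fisher(table), abs=1e-9)

    def test_printed_ratio_fields(self):
        mk = MKTable(f_S=5, f_A=18, P_S=34, P_A=118)
        assert mk.ratio_fixed == pytest.approx(3.6)
        assert mk.ratio_poly == pytest.approx(118 / 34)
        assert mk.neutrality_index == pytest.approx((118 / 34) / 3.6)

    def test_table_renders_nulls_as_na(self):
        tsv = neutrality_table([{"name": "empty"}])
        row = tsv.strip().split("\n")[1].split("\t")
        assert row[0] == "empty" and set(row[1:]) == {"NA"}
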