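"""RSCU/RFSC, ENc, CAI, high-frequency and optimal codon determination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonuse.codons import CodonCountVector, aggregate_counts, count_codons
from codonuse.errors import InsufficientDataError, UndefinedMetricError
from codonuse.genetic_code import STANDARD_CODE, STOP
from codonuse.metrics import (
    build_reference_weights,
    compute_cai,
    compute_enc,
    compute_rfsc,
    compute_rscu,
    enc_expected,
    expression_libraries,
    gene_index_table,
    high_frequency_codons,
    optimal_codons,
    optimal_codons_between,
    relative_adaptiveness,
    shared_optimal_codons,
)

from conftest import make_counts

CODE = STANDARD_CODE


def random_counts(seed: int, low: int = 0, high: int = 40) -> CodonCountVector:
    rng = np.random.default_rng(seed)
    return CodonCountVector(scope=f"rnd{seed}", counts=rng.integers(low, high, 64))


def uniform_counts(n_per_codon: int = 100) -> CodonCountVector:
    counts = np.full(64, n_per_codon, dtype=np.int64)
    return CodonCountVector(scope="uniform", counts=counts)


class TestRscuRfsc:
    def test_glu_family_example(self):
        t = compute_rscu(make_counts({"GAA": 3, "GAG": 1}))
        assert t.rscu("GAA") == pytest.approx(1.5)
        assert t.rscu("GAG") == pytest.approx(0.5)
        assert t.rfsc("GAA") == pytest.approx(0.75)
        assert t.rfsc("GAG") == pytest.approx(0.25)

    def test_uniform_usage_gives_rscu_one(self):
        t = compute_rscu(uniform_counts())
        assert t.table["rscu"].to_numpy() == pytest.approx(np.ones(61))

    def test_single_codon_family_rfsc_one(self):
        t = compute_rfsc(make_counts({"ATG": 7}))
        assert t.rfsc("ATG") == 1.0 and t.rscu("ATG") == 1.0

    def test_absent_family_is_nan_not_zero(self):
        t = compute_rscu(make_counts({"GAA": 2, "GAG": 2}))
        assert math.isnan(t.rscu("TTT"))

    def test_stop_codons_excluded(self):
        t = compute_rscu(make_counts({"GAA": 1, "TAA": 5}))
        assert "TAA" not in t.table.index
        assert len(t.table) == 61

    def test_all_zero_counts_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_rscu(CodonCountVector.zeros())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rscu_rfsc_identity_and_family_normalisation(self, seed):
        counts = random_counts(seed, low=1)  # every family occupied
        t = compute_rscu(counts)
        for aa, fam in CODE.families.items():
            if aa == STOP:
                continue
            rows = t.table.loc[list(fam)]
            # rscu = rfsc * n_i, family mean rscu = 1, family sum rfsc = 1
            assert rows["rscu"].to_numpy() == pytest.approx(
                (rows["rfsc"] * len(fam)).to_numpy(), abs=1e-12
            )
            assert rows["rscu"].mean() == pytest.approx(1.0, abs=1e-9)
            assert rows["rfsc"].sum() == pytest.approx(1.0, abs=1e-9)


class TestRscuAgainstSeqinr:
    def test_matches_independent_r_implementation(self, tmp_path):
        """Dual-route check: RSCU from seqinr::uco on the same CDS."""
        import csv
        import subprocess

        from codonuse.simulate import at_preference_model, generate_cds_set

        seq = generate_cds_set(
            at_preference_model(), 1, 77, species="x"
        )[0].sequence
        script = tmp_path / "rscu.R"
        script.write_text(
            'suppressMessages(library(seqinr))\n'
            f'u <- uco(s2c(tolower("{seq}")), index="rscu")\n'
            'write.csv(data.frame(codon=toupper(names(u)), rscu=as.numeric(u)),\n'
            f'          "{tmp_path / "out.csv"}", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        with open(tmp_path / "out.csv") as fh:
            r_rscu = {row["codon"]: row["rscu"] for row in csv.DictReader(fh)}
        ours = compute_rscu(count_codons(seq))
        compared = 0
        for codon in CODE.sense_codons:
            if r_rscu[codon] == "NA":
                assert math.isnan(ours.rscu(codon))
            else:
                assert ours.rscu(codon) == pytest.approx(float(r_rscu[codon]), abs=1e-9)
                compared += 1
        assert compared > 50


class TestEnc:
    def test_one_codon_per_amino_acid_gives_20(self):
        # one codon used per family, each at least twice
        first = {fam[0]: 10 for aa, fam in CODE.families.items() if aa != STOP}
        assert compute_enc(make_counts(first)) == pytest.approx(20.0)

    def test_uniform_large_counts_reach_61(self):
        # F_hat < 1/k for equal finite counts, so the raw value exceeds 61
        # and the estimate clamps at the theoretical maximum
        assert compute_enc(uniform_counts(10000)) == 61.0

    def test_hand_evaluated_wright_formula(self):
        # Lys 3/1, Phe 2/2, Ile 2/1/0, Val 5/1/1/1, Leu TTA4/TTG2:
        # F2 = mean(0.5, 1/3) = 5/12; F3 = 1/3; F4 = 5/14; F6 = 7/15
        # ENc = 2 + 9/(5/12) + 3 + 14 + 45/7 = 47.02857142857143
        v = make_counts(
            {
                "AAA": 3, "AAG": 1,
                "TTT": 2, "TTC": 2,
                "ATT": 2, "ATC": 1,
                "GTT": 5, "GTC": 1, "GTA": 1, "GTG": 1,
                "TTA": 4, "TTG": 2,
            }
        )
        assert compute_enc(v) == pytest.approx(47.02857142857143, abs=1e-12)

    def test_missing_ile_class_falls_back_to_f2_f4_mean(self):
        # same fixture without Ile: F3 := (F2+F4)/2 = (5/12 + 5/14)/2 = 65/168
        v = make_counts(
            {
                "AAA": 3, "AAG": 1,
                "TTT": 2, "TTC": 2,
                "GTT": 5, "GTC": 1, "GTA": 1, "GTG": 1,
                "TTA": 4, "TTG": 2,
            }
        )
        expected = 2 + 9 / (5 / 12) + 168 / 65 + 14 + 45 / 7
        assert compute_enc(v) == pytest.approx(expected, abs=1e-12)

    def test_missing_other_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_enc(make_counts({"GAA": 5, "GAG": 3}))  # no 4- or 6-fold data

    @pytest.mark.parametrize("seed", range(5))
    def test_range_clamp(self, seed):
        enc = compute_enc(random_counts(seed, low=1))
        assert 20.0 <= enc <= 61.0

    def test_scale_invariance_in_large_count_limit(self):
        # the finite-count correction in F is O(1/n), so the change under
        # count doubling must shrink with scale and vanish in the limit
        base = random_counts(9, low=50, high=500).counts
        diffs = []
        for mult in (1, 10, 100):
            a = compute_enc(CodonCountVector(scope="a", counts=mult * base))
            b = compute_enc(CodonCountVector(scope="b", counts=2 * mult * base))
            diffs.append(abs(a - b))
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[1] < 0.01  # total > 200,000 codons


class TestEncExpected:
    @pytest.mark.parametrize("s, expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_closed_form_values(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)

    @given(st.floats(min_value=0.0, max_value=0.5))
    @settings(max_examples=50, deadline=None)
    def test_near_symmetric_and_maximal_near_half(self, s):
        # the 29/(s^2+(1-s)^2) term is symmetric; the +s term breaks exact
        # symmetry by at most 1 - 2s
        assert abs(enc_expected(s) - enc_expected(1 - s)) == pytest.approx(
            1 - 2 * s, abs=1e-9
        )
        assert enc_expected(0.5) + 0.5 >= enc_expected(s)


class TestCai:
    def test_gene_of_maximal_codons_scores_one(self):
        ref = random_counts(5, low=1)
        w = relative_adaptiveness(ref)
        best = {}
        for aa, fam in CODE.families.items():
            if aa == STOP or len(fam) == 1:
                continue
            best[max(fam, key=lambda c: w[c])] = 10
        assert compute_cai(make_counts(best), w) == pytest.approx(1.0)

    def test_constant_weights_give_that_constant(self):
        w = {c: 0.5 for c in CODE.codon_to_aa}
        gene = make_counts({"GAA": 7, "TTT": 3, "GGG": 2})
        assert compute_cai(gene, w) == pytest.approx(0.5)

    def test_met_trp_stop_excluded(self):
        w = {c: 0.2 for c in CODE.codon_to_aa}
        w["ATG"] = w["TGG"] = 1.0
        gene = make_counts({"ATG": 50, "TGG": 50, "GAA": 1})
        assert compute_cai(gene, w) == pytest.approx(0.2)

    def test_against_log_sum_oracle(self):
        rng = np.random.default_rng(17)
        ref = random_counts(23, low=1)
        w = relative_adaptiveness(ref)
        gene = CodonCountVector(scope="g", counts=rng.integers(0, 30, 64))
        # independent oracle: explicit log-sum over included codons
        num = den = 0.0
        for codon in CODE.synonymous_sense_codons:
            x = gene[codon]
            num += x * math.log(w[codon])
            den += x
        assert compute_cai(gene, w) == pytest.approx(math.exp(num / den), abs=1e-12)

    def test_length_invariance_for_fixed_composition(self):
        ref = random_counts(31, low=1)
        w = relative_adaptiveness(ref)
        gene = make_counts({"GAA": 3, "GAG": 1, "TTT": 2})
        scaled = CodonCountVector(scope="g10", counts=gene.counts * 10)
        assert compute_cai(gene, w) == pytest.approx(compute_cai(scaled, w))

    def test_no_informative_codons_undefined(self):
        w = {c: 0.5 for c in CODE.codon_to_aa}
        with pytest.raises(UndefinedMetricError):
            compute_cai(make_counts({"ATG": 5}), w)

    def test_reference_floor_applies_to_unseen_codons(self):
        ref = make_counts({"GAA": 10})  # GAG unseen; Phe family absent
        w = relative_adaptiveness(ref)
        assert w["GAA"] == 1.0
        assert w["GAG"] == 0.01 and w["TTT"] == 0.01


class TestExpressionLibraries:
    @staticmethod
    def rows(n, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            counts = CodonCountVector(
                scope=f"g{i:03d}", counts=rng.integers(1, 30, 64)
            )
            out.append((f"g{i:03d}", counts, float(20 + i)))
        return out

    def test_tail_sizes_use_ceiling(self):
        high, low = expression_libraries(self.rows(50))
        assert len(high) == len(low) == 5
        high, low = expression_libraries(self.rows(48))
        assert len(high) == len(low) == 5  # ceil(4.8)

    def test_high_library_is_lowest_enc(self):
        rows = self.rows(50)
        high, low = expression_libraries(rows)
        assert [r[0] for r in high] == [f"g{i:03d}" for i in range(5)]
        assert {r[0] for r in low} == {f"g{i:03d}" for i in range(45, 50)}

    def test_too_few_genes_rejected(self):
        with pytest.raises(InsufficientDataError):
            expression_libraries(self.rows(9))  # below the 10-gene minimum
        with pytest.raises(InsufficientDataError):
            expression_libraries(self.rows(10))  # tail of ceil(1.0) = 1 gene
        high, low = expression_libraries(self.rows(12))  # ceil(1.2) = 2: valid
        assert len(high) == len(low) == 2

    def test_reference_weights_max_one_per_family(self):
        w = build_reference_weights(self.rows(50, seed=4))
        for aa, fam in CODE.families.items():
            if aa == STOP:
                continue
            assert max(w[c] for c in fam) == pytest.approx(1.0)


class TestHighFrequencyCodons:
    def test_uniform_usage_flags_nothing(self):
        t = compute_rscu(uniform_counts())
        assert high_frequency_codons(t) == []

    def test_two_fold_family_80_20(self):
        t = compute_rscu(make_counts({"GAA": 8, "GAG": 2}))
        hf = high_frequency_codons(t)
        assert hf == ["GAA"]  # RFSC 0.8 > 0.6 and RSCU 1.6 >= 1.5

    def test_met_trp_never_flagged(self):
        t = compute_rscu(make_counts({"ATG": 100, "TGG": 100, "GAA": 1, "GAG": 1}))
        assert high_frequency_codons(t) == []

    def test_literal_mode_is_weaker(self):
        # Gly 35/30/25/10: RFSC 0.35/0.30/0.25/0.10, max RSCU 1.4 < 1.5 so the
        # default rule flags nothing; the literal rule (RFSC > 0.5/n = 0.125)
        # flags three of four codons
        t = compute_rscu(make_counts({"GGT": 35, "GGC": 30, "GGA": 25, "GGG": 10}))
        assert high_frequency_codons(t, mode="default") == []
        assert high_frequency_codons(t, mode="literal") == ["GGA", "GGC", "GGT"]


class TestOptimalCodons:
    def test_identical_libraries_yield_none(self):
        v = random_counts(2, low=1)
        results = optimal_codons_between(v, v)
        assert all(not r.is_optimal for r in results)
        assert all(r.delta_rscu == 0 for r in results)

    def test_delta_and_rscu_thresholds_both_strict(self):
        # Glu high 3:1 (RSCU 1.5/0.5), low 2.33:1.67 approximated by counts
        high = make_counts({"GAA": 30, "GAG": 10})
        low = make_counts({"GAA": 25, "GAG": 15})
        res = {r.codon: r for r in optimal_codons_between(high, low)}
        assert res["GAA"].is_optimal  # 1.5 > 1, delta 0.25 > 0.08
        assert not res["GAG"].is_optimal  # rscu_high < 1
        # delta exactly at threshold is rejected
        res2 = {
            r.codon: r
            for r in optimal_codons_between(high, low, delta_threshold=0.25)
        }
        assert not res2["GAA"].is_optimal

    def test_absent_family_never_optimal(self):
        high = make_counts({"GAA": 10})
        low = make_counts({"TTT": 10})
        for r in optimal_codons_between(high, low):
            assert not r.is_optimal

    def test_tail_selection_feeds_decision(self):
        # 20 genes: 2 lowest-ENc genes biased to GAA, 2 highest to GAG;
        # middle genes neutral -> GAA optimal
        rows = []
        for i in range(20):
            if i < 2:
                counts = make_counts({"GAA": 30, "GAG": 2, "TTT": 8, "TTC": 8})
            elif i >= 18:
                counts = make_counts({"GAA": 2, "GAG": 30, "TTT": 8, "TTC": 8})
            else:
                counts = make_counts({"GAA": 16, "GAG": 16, "TTT": 8, "TTC": 8})
            rows.append((f"g{i:02d}", counts, float(i)))
        opt = {r.codon for r in optimal_codons(rows) if r.is_optimal}
        assert "GAA" in opt and "GAG" not in opt


class TestSharedOptimalCodons:
    # optimal-codon sets of the three chloroplast genomes (printed inputs)
    ARABICA = {
        "AAA", "AAT", "ACA", "ACT", "AGA", "ATT", "CAA", "CGT", "GAA", "GCA",
        "GCT", "GGA", "GGT", "GTT", "TAT", "TCA", "TGT", "TTA", "TTG", "TTT",
    }
    CANEPHORA = {
        "AAA", "ACA", "ACT", "ATT", "CAA", "CGT", "CTT", "GAA", "GCA", "GCT",
        "GGT", "GTT", "TAA", "TAT", "TGT", "TTG", "TTT",
    }
    LIBERICA = {
        "AAA", "ACA", "ACT", "ATT", "CAA", "CGT", "GAA", "GCT", "GGA", "GGT",
        "GTT", "TAA", "TAT", "TCA", "TCT", "TGT", "TTA", "TTG", "TTT",
    }

    def test_three_species_share_fourteen(self):
        assert (len(self.ARABICA), len(self.CANEPHORA), len(self.LIBERICA)) == (
            20, 17, 19,
        )
        shared = shared_optimal_codons([self.ARABICA, self.CANEPHORA, self.LIBERICA])
        assert len(shared) == 14
        assert shared == {
            "AAA", "ACA", "ACT", "ATT", "CAA", "CGT", "GAA", "GCT", "GGT",
            "GTT", "TAT", "TGT", "TTG", "TTT",
        }

    def test_disjoint_and_subset_cases(self):
        assert shared_optimal_codons([{"AAA"}, {"GGG"}]) == set()
        assert shared_optimal_codons([{"AAA"}, {"AAA", "GGG"}]) == {"AAA"}
        with pytest.raises(InsufficientDataError):
            shared_optimal_codons([{"AAA"}])


class TestGeneIndexTable:
    def test_laa_counts_amino_acids_not_stops(self):
        v = count_codons("ATG" + "GAA" * 120 + "TAA", scope="g1")
        table = gene_index_table([v])
        assert table.loc["g1", "laa"] == 121

    def test_undefined_enc_becomes_nan(self):
        v = make_counts({"GAA": 30, "GAG": 3, "TAA": 1}, scope="tiny")
        table = gene_index_table([v])
        assert math.isnan(table.loc["tiny", "enc"])
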