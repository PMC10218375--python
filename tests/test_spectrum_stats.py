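import math

import numpy as np
import pandas as pd
import pytest

from mutaspec.exceptions import ConfigurationError, DataError, InapplicableTestError
from mutaspec.pipeline import merge_mnv
from mutaspec.spectrum_stats import (
    CATEGORIES,
    SpectrumSummary,
    aggregate,
    category_proportion,
    chi_squared_test,
    classify_variant,
    error_band,
    homozygous_fraction,
    length_class_breakdown,
    phenotype_proportions,
    significance_label,
    ts_tv_ratio,
    two_sample_t_test,
)
from mutaspec.variant_io import VariantCall

# published per-category counts used as aggregation inputs
CARBON_HOMO = {"SBS": 1392, "INDEL_deletion": 462, "INDEL_insertion": 84,
               "MNV": 41, "DEL_SV": 3, "DUP_SV": 0, "BND_SV": 6}
CARBON_ALL = {"SBS": 5677, "INDEL_deletion": 1892, "INDEL_insertion": 1379,
              "MNV": 139, "DEL_SV": 43, "DUP_SV": 77, "BND_SV": 488}
GAMMA_HOMO = {"SBS": 3903, "INDEL_deletion": 866, "INDEL_insertion": 385,
              "MNV": 123, "DEL_SV": 1, "DUP_SV": 1, "BND_SV": 0}
GAMMA_ALL = {"SBS": 8947, "INDEL_deletion": 2619, "INDEL_insertion": 1819,
             "MNV": 283, "DEL_SV": 40, "DUP_SV": 71, "BND_SV": 464}

PHENOTYPE_TABLE = pd.DataFrame(
    {
        "carbon": [94, 59, 23, 39, 34, 76],
        "gamma": [91, 73, 69, 35, 35, 33],
    },
    index=["leaf_color", "late_maturity", "dwarf", "precocity", "height", "infrequent"],
)


def sbs(ref, alt, sample="L", chrom="c1", pos=1):
    return VariantCall(sample, chrom, pos, ref, alt, af=0.5, qual=50.0)


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("A", "G", "SBS"), ("ACGT", "A", "INDEL_deletion"), ("A", "ACG", "INDEL_insertion"),
         ("AT", "GC", "MNV")],
    )
    def test_small_variants(self, ref, alt, expected):
        assert classify_variant(sbs(ref, alt)) == expected

    def test_symbolic_deletion_over_50bp(self):
        call = VariantCall("L", "c1", 100, "N", "<DEL>", gt="0/1", sv_type="DEL_SV", sv_end=300)
        assert classify_variant(call) == "DEL_SV"

    def test_unclassifiable_allele(self):
        call = VariantCall("L", "c1", 1, "A" * 60, "A", af=0.5)
        with pytest.raises(DataError):
            classify_variant(call)


class TestTsTv:
    def test_two_transitions_one_transversion(self):
        calls = [sbs("A", "G"), sbs("C", "T"), sbs("A", "C")]
        assert ts_tv_ratio(calls) == pytest.approx(2.0)

    def test_all_transitions_flagged_infinite(self):
        assert math.isinf(ts_tv_ratio([sbs("A", "G"), sbs("T", "C")]))

    def test_empty_input_flagged_nan(self):
        assert math.isnan(ts_tv_ratio([]))

    def test_random_fixture_matches_pair_tally_oracle(self):
        rng = np.random.default_rng(31)
        bases = "ACGT"
        calls = []
        for _ in range(500):
            ref = bases[rng.integers(4)]
            alt = rng.choice([b for b in bases if b != ref])
            calls.append(sbs(ref, str(alt)))
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        ts = sum((c.ref, c.alt) in transitions for c in calls)
        tv = len(calls) - ts
        assert ts_tv_ratio(calls) == pytest.approx(ts / tv)

    def test_mnv_constituents_never_enter_the_ratio(self):
        calls = [sbs("A", "C", pos=100), sbs("A", "C", pos=101), sbs("A", "G", pos=500)]
        mnvs, singles = merge_mnv(calls)
        assert len(mnvs) == 1
        assert math.isinf(ts_tv_ratio(singles))  # only the transition is left


class TestLengthClasses:
    def test_binning_rules(self):
        events = [
            sbs("AT", "A"),       # 1 bp deletion
            sbs("ATT", "A"),      # 2 bp deletion
            sbs("A", "AC"),       # 1 bp insertion
            sbs("A", "ACGT"),     # 3 bp insertion
        ]
        for e in events:
            e.category = classify_variant(e)
        out = length_class_breakdown(events)
        assert out["deletion_1bp"] == 1 and out["deletion_ge2bp"] == 1
        assert out["insertion_1bp"] == 1 and out["insertion_ge2bp"] == 1

    def test_mnv_split_at_2bp(self):
        runs = [
            [sbs("A", "C", pos=10), sbs("A", "C", pos=11)],
            [sbs("A", "C", pos=20), sbs("A", "C", pos=21), sbs("A", "C", pos=22)],
        ]
        mnvs = [merge_mnv(r)[0][0] for r in runs]
        out = length_class_breakdown(mnvs)
        assert out["mnv_2bp"] == 1 and out["mnv_ge3bp"] == 1

    def test_random_fixture_matches_binning_oracle(self):
        rng = np.random.default_rng(41)
        events = []
        for _ in range(120):
            length = int(rng.integers(1, 11))
            run = "A" * length
            if rng.random() < 0.5:
                e = sbs("C" + run, "C")
            else:
                e = sbs("C", "C" + run)
            e.category = classify_variant(e)
            events.append(e)
        out = length_class_breakdown(events)
        dels = [e for e in events if e.category == "INDEL_deletion"]
        ins = [e for e in events if e.category == "INDEL_insertion"]
        assert out["deletion_1bp"] == sum(len(e.ref) - 1 == 1 for e in dels)
        assert out["deletion_ge2bp"] == sum(len(e.ref) - 1 >= 2 for e in dels)
        assert out["insertion_1bp"] == sum(len(e.alt) - 1 == 1 for e in ins)
        assert out["insertion_ge2bp"] == sum(len(e.alt) - 1 >= 2 for e in ins)


class TestAggregation:
    def test_published_totals_from_category_counts(self):
        assert SpectrumSummary.from_counts(CARBON_HOMO).total == 1988
        assert SpectrumSummary.from_counts(GAMMA_HOMO).total == 5279
        assert SpectrumSummary.from_counts(CARBON_ALL).total == 9695
        assert SpectrumSummary.from_counts(GAMMA_ALL).total == 14243

    def test_homozygous_fractions(self):
        carbon = homozygous_fraction(
            SpectrumSummary.from_counts(CARBON_HOMO), SpectrumSummary.from_counts(CARBON_ALL)
        )
        gamma = homozygous_fraction(
            SpectrumSummary.from_counts(GAMMA_HOMO), SpectrumSummary.from_counts(GAMMA_ALL)
        )
        assert round(carbon, 2) == 20.51
        assert round(gamma, 2) == 37.06

    def test_sv_proportions(self):
        assert round(category_proportion(SpectrumSummary.from_counts(CARBON_ALL), "SV"), 2) == 6.27
        assert round(category_proportion(SpectrumSummary.from_counts(GAMMA_ALL), "SV"), 2) == 4.04
        assert round(category_proportion(SpectrumSummary.from_counts(CARBON_HOMO), "SV"), 2) == 0.45
        assert round(category_proportion(SpectrumSummary.from_counts(GAMMA_HOMO), "SV"), 2) == 0.04

    def test_proportions_sum_to_100(self):
        props = SpectrumSummary.from_counts(CARBON_ALL).proportions()
        assert sum(props.values()) == pytest.approx(100.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate([], "homozygous")

    def test_aggregate_counts_match_per_line_sums(self, noisy_line_sets):
        group = [noisy_line_sets[s] for s in sorted(noisy_line_sets) if s.startswith("carbon")]
        summary = aggregate(group, "homozygous+heterozygous", "carbon")
        for category in CATEGORIES:
            assert summary.counts[category] == sum(
                counter.get(category, 0) for counter in summary.per_line.values()
            )
        assert summary.sub_counts["ts"] + summary.sub_counts["tv"] == summary.counts["SBS"]

    def test_aggregate_is_order_invariant(self, noisy_line_sets):
        group = [noisy_line_sets[s] for s in sorted(noisy_line_sets) if s.startswith("gamma")]
        forward = aggregate(group, "homozygous", "gamma")
        backward = aggregate(group[::-1], "homozygous", "gamma")
        assert forward.counts == backward.counts
        assert forward.sub_counts == backward.sub_counts

    def test_scopes_nest(self, noisy_line_sets):
        group = list(noisy_line_sets.values())
        homo = aggregate(group, "homozygous")
        both = aggregate(group, "homozygous+heterozygous")
        for category in CATEGORIES:
            assert homo.counts[category] <= both.counts[category]


class TestChiSquared:
    def test_proportional_table_gives_zero(self):
        res = chi_squared_test([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_diagonal_2x2_hand_value(self):
        res = chi_squared_test([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1
        assert res.significant

    def test_matches_textbook_summation_oracle(self):
        rng = np.random.default_rng(57)
        for _ in range(20):
            table = rng.integers(5, 60, size=(rng.integers(2, 6), 2)).astype(float)
            res = chi_squared_test(table)
            total = table.sum()
            stat = 0.0
            for i in range(table.shape[0]):
                for j in range(table.shape[1]):
                    expected = table[i].sum() * table[:, j].sum() / total
                    stat += (table[i, j] - expected) ** 2 / expected
            assert res.statistic == pytest.approx(stat, rel=1e-10)
            assert res.df == (table.shape[0] - 1) * (table.shape[1] - 1)

    def test_phenotype_table_statistic_matches_oracle(self):
        table = PHENOTYPE_TABLE.to_numpy(float)
        res = chi_squared_test(table)
        total = table.sum()
        stat = sum(
            (table[i, j] - table[i].sum() * table[:, j].sum() / total) ** 2
            / (table[i].sum() * table[:, j].sum() / total)
            for i in range(table.shape[0])
            for j in range(table.shape[1])
        )
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        assert res.df == 5

    def test_zero_marginal_rejected(self):
        with pytest.raises(InapplicableTestError):
            chi_squared_test([[0, 0], [5, 5]])


class TestTTest:
    def test_identical_groups_not_significant(self):
        res = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.label == "N.S."

    def test_large_shift_is_significant(self):
        res = two_sample_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p_value < 0.001 and res.label == "***"

    def test_matches_pooled_variance_formula_oracle(self):
        rng = np.random.default_rng(61)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 1.2, 11)
        res = two_sample_t_test(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_oracle = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert res.df == na + nb - 2

    def test_zero_pooled_variance_inapplicable(self):
        with pytest.raises(InapplicableTestError):
            two_sample_t_test([5.0, 5.0], [5.0, 5.0])

    @pytest.mark.parametrize(
        "p,label", [(0.5, "N.S."), (0.03, "*"), (0.005, "**"), (0.0005, "***")]
    )
    def test_significance_labels(self, p, label):
        assert significance_label(p) == label


class TestPhenotypeProportions:
    def test_published_percentages(self):
        pct = phenotype_proportions(PHENOTYPE_TABLE)
        assert round(pct.loc["leaf_color", "carbon"], 1) == 28.9
        assert round(pct.loc["infrequent", "carbon"], 1) == 23.4
        assert round(pct.loc["leaf_color", "gamma"], 1) == 27.1
        assert round(pct.loc["dwarf", "gamma"], 1) == 20.5
        assert round(pct.loc["dwarf", "carbon"], 1) == 7.1
        assert round(pct.loc["infrequent", "gamma"], 1) == 9.8

    def test_columns_sum_to_100(self):
        pct = phenotype_proportions(PHENOTYPE_TABLE)
        assert pct.sum(axis=0).to_numpy() == pytest.approx([100.0, 100.0])

    def test_zero_column_rejected(self):
        with pytest.raises(ConfigurationError):
            phenotype_proportions(pd.DataFrame({"a": [0, 0]}))


class TestErrorBand:
    def test_constant_values(self):
        mean, half = error_band([3.0, 3.0, 3.0])
        assert (mean, half) == (3.0, 0.0)

    def test_hand_computed_pair(self):
        mean, half = error_band([0.0, 2.0])
        assert mean == pytest.approx(1.0)
        assert half == pytest.approx(1.97 * math.sqrt(2.0))

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(71)
        values = rng.normal(10, 3, 25)
        mean, half = error_band(values)
        n = len(values)
        mu = sum(values) / n
        sd = math.sqrt(sum((v - mu) ** 2 for v in values) / (n - 1))
        assert mean == pytest.approx(mu)
        assert half == pytest.approx(1.97 * sd)
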