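import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from crossase.ase_detection import (
    aggregate_to_genes,
    bh_adjust,
    binomial_p_values,
    binomial_test,
    call_ase_sites,
    exclude_imprinted,
    extract_allele_counts,
    filter_counts,
    final_ase_genes,
    pool_replicates,
    relabel_by_line,
    tissue_overlap_summary,
)
from crossase.io_formats.sam import AlignedRead


def _read(pos=100, cigar="100M", seq=None, quals=None, flag=0, mapq=60, chrom="chr1"):
    if seq is None:
        seq = "A" * sum(
            int(n) for n, op in __import__("re").findall(r"(\d+)([MIS=X])", cigar)
        )
    if quals is None:
        quals = [30] * len(seq)
    return AlignedRead(
        qname="r", flag=flag, chrom=chrom, pos=pos, mapq=mapq,
        cigar=cigar, seq=seq, quals=quals,
    )


def _sites(pos=111, ref="C", alt="T"):
    return pd.DataFrame({"chrom": ["chr1"], "pos": [pos], "ref": [ref], "alt": [alt]})


class TestExtractAlleleCounts:
    def test_alt_base_counted(self):
        # read starts at pos 100 (pos0 99); site at pos0 109 => offset 10
        seq = "A" * 10 + "T" + "A" * 89
        out = extract_allele_counts([_read(pos=100, seq=seq)], _sites(pos=110))
        assert out.loc[0, ["n_ref", "n_alt", "n_other"]].tolist() == [0, 1, 0]

    def test_ref_and_other(self):
        seq_ref = "A" * 10 + "C" + "A" * 89
        seq_other = "A" * 10 + "G" + "A" * 89
        out = extract_allele_counts(
            [_read(seq=seq_ref), _read(seq=seq_other)], _sites(pos=110)
        )
        assert out.loc[0, ["n_ref", "n_alt", "n_other"]].tolist() == [1, 0, 1]

    def test_deletion_skipped(self):
        # CIGAR 50M10D50M from pos0 99: deletion covers pos0 149..158
        out = extract_allele_counts(
            [_read(cigar="50M10D50M", seq="A" * 100)], _sites(pos=150, ref="A", alt="T")
        )
        assert out.loc[0, ["n_ref", "n_alt", "n_other"]].sum() == 0

    def test_insertion_shifts_query_offset(self):
        # CIGAR 10M5I90M, site at reference offset 12 -> query offset 17
        seq = list("A" * 105)
        seq[17] = "T"
        out = extract_allele_counts(
            [_read(cigar="10M5I90M", seq="".join(seq))],
            _sites(pos=112, ref="C", alt="T"),  # pos0 111 = 99 + 12
        )
        assert out.loc[0, "n_alt"] == 1

    @pytest.mark.parametrize("flag", [0x4, 0x100, 0x400, 0x800])
    def test_flagged_reads_skipped(self, flag):
        seq = "A" * 10 + "T" + "A" * 89
        out = extract_allele_counts([_read(seq=seq, flag=flag)], _sites(pos=110))
        assert out.loc[0, ["n_ref", "n_alt", "n_other"]].sum() == 0

    def test_low_mapq_and_baseq_skipped(self):
        seq = "A" * 10 + "T" + "A" * 89
        low_mapq = _read(seq=seq, mapq=5)
        quals = [30] * 100
        quals[10] = 5
        low_baseq = _read(seq=seq, quals=quals)
        out = extract_allele_counts([low_mapq, low_baseq], _sites(pos=110))
        assert out.loc[0, ["n_ref", "n_alt", "n_other"]].sum() == 0

    def test_site_chrom_absent_zero_counts(self):
        out = extract_allele_counts([_read()], _sites().assign(chrom="chrX"))
        assert out.loc[0, ["n_ref", "n_alt", "n_other"]].sum() == 0


class TestPoolingAndFiltering:
    @staticmethod
    def _counts(rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "individual", "tissue", "replicate",
                     "n_line_A", "n_line_B"],
        )

    def test_pool_sums_replicates(self):
        counts = self._counts(
            [("chr1", 10, "F1", "liver", 1, 10, 5), ("chr1", 10, "F1", "liver", 2, 8, 7)]
        )
        pooled = pool_replicates(counts)
        assert len(pooled) == 1
        assert pooled.loc[0, ["n_line_A", "n_line_B"]].tolist() == [18, 12]

    def test_pool_single_replicate_unchanged(self):
        counts = self._counts([("chr1", 10, "F1", "liver", 1, 10, 5)])
        pooled = pool_replicates(counts)
        assert pooled.loc[0, ["n_line_A", "n_line_B"]].tolist() == [10, 5]

    def test_separate_scheme_preserves_rows(self):
        counts = self._counts(
            [("chr1", 10, "F1", "liver", 1, 10, 5), ("chr1", 10, "F1", "liver", 2, 8, 7)]
        )
        assert len(pool_replicates(counts, scheme="separate")) == 2

    def test_filter_one_allele_below_20(self):
        counts = self._counts([("chr1", 10, "F1", "liver", 1, 19, 40)])
        assert filter_counts(counts).empty

    def test_filter_total_exactly_50_kept(self):
        counts = self._counts([("chr1", 10, "F1", "liver", 1, 25, 25)])
        assert len(filter_counts(counts)) == 1

    def test_filter_total_49_removed(self):
        counts = self._counts([("chr1", 10, "F1", "liver", 1, 25, 24)])
        assert filter_counts(counts).empty

    def test_major_mode_contrast(self):
        counts = self._counts([("chr1", 10, "F1", "liver", 1, 100, 5)])
        assert filter_counts(counts, mode="literal").empty
        assert len(filter_counts(counts, mode="major")) == 1

    def test_relabel_by_line(self):
        df = pd.DataFrame({"n_ref": [10, 3], "n_alt": [2, 30]})
        out = relabel_by_line(df, pd.Series([True, False]))
        assert out["n_line_A"].tolist() == [2, 3]
        assert out["n_line_B"].tolist() == [10, 30]
        assert (out["n_line_A"] + out["n_line_B"]).tolist() == (
            (df["n_ref"] + df["n_alt"]).tolist()
        )


def enumeration_oracle(k, n):
    """Two-sided minimum-likelihood p by full enumeration of outcomes."""
    pmf = [binom.pmf(i, n, 0.5) for i in range(n + 1)]
    threshold = pmf[k] * (1 + 1e-9)
    return min(1.0, sum(p for p in pmf if p <= threshold))


class TestBinomialTest:
    def test_symmetric_is_one(self):
        assert binomial_test(25, 25) == 1.0

    def test_extreme_closed_form(self):
        assert binomial_test(50, 0) == pytest.approx(2 * 0.5 ** 50, rel=1e-12)
        assert binomial_test(50, 0) == pytest.approx(1.7763568394002505e-15, rel=1e-12)

    def test_35_15_against_enumeration(self):
        assert binomial_test(35, 15) == pytest.approx(
            enumeration_oracle(35, 50), abs=1e-12
        )

    def test_all_totals_up_to_60(self):
        for n in range(1, 61):
            ks = np.arange(n + 1)
            ps = binomial_p_values(ks, n - ks)
            for k in ks:
                assert ps[k] == pytest.approx(enumeration_oracle(int(k), n), abs=1e-12)

    def test_doubling_equals_min_likelihood(self):
        # both constructions agree under the symmetric null
        for n, k in [(10, 3), (33, 20), (60, 31)]:
            doubled = min(1.0, 2 * min(binom.cdf(k, n, 0.5), binom.sf(k - 1, n, 0.5)))
            assert binomial_test(k, n - k) == pytest.approx(doubled, abs=1e-12)
            assert binomial_test(k, n - k) == pytest.approx(
                enumeration_oracle(k, n), abs=1e-12
            )

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            binomial_test(0, 0)


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @settings(max_examples=60, deadline=None)
    @given(
        ps=st.lists(
            st.floats(min_value=1e-12, max_value=1.0, allow_nan=False), min_size=1,
            max_size=40,
        )
    )
    def test_matches_statsmodels_and_is_monotone(self, ps):
        from statsmodels.stats.multitest import multipletests

        q = bh_adjust(ps)
        _, q_sm, _, _ = multipletests(ps, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in sorted-p order
        assert np.all((q > 0) & (q <= 1))


class TestCallAseSites:
    @staticmethod
    def _counts(pairs, tissue="liver"):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, len(pairs) + 1),
                "gene_id": "g",
                "individual": "F1",
                "tissue": tissue,
                "n_line_A": [a for a, _ in pairs],
                "n_line_B": [b for _, b in pairs],
            }
        )

    def test_ratio_exactly_07_never_called(self):
        calls = call_ase_sites(self._counts([(70, 30)]))
        assert calls.loc[0, "ratio"] == 0.7
        assert not calls.loc[0, "is_ase"]

    def test_imbalanced_in_null_batch_called(self):
        rng = np.random.default_rng(0)
        nulls = [(int(x), 100 - int(x)) for x in rng.binomial(100, 0.5, size=100)]
        calls = call_ase_sites(self._counts(nulls + [(90, 10)]))
        assert bool(calls.iloc[-1]["is_ase"])

    def test_mild_ratio_not_called_regardless_of_q(self):
        calls = call_ase_sites(self._counts([(600, 400)]))
        assert calls.loc[0, "q_value"] < 0.05
        assert not calls.loc[0, "is_ase"]

    def test_per_tissue_fdr_families(self):
        liver = self._counts([(90, 10), (51, 49)], tissue="liver")
        bone = self._counts([(50, 50)], tissue="bone")
        calls = call_ase_sites(pd.concat([liver, bone], ignore_index=True))
        liver_p = calls[calls["tissue"] == "liver"]["p_value"].to_numpy()
        liver_q = calls[calls["tissue"] == "liver"]["q_value"].to_numpy()
        np.testing.assert_allclose(liver_q, bh_adjust(liver_p))
        assert calls[calls["tissue"] == "bone"]["q_value"].iloc[0] == 1.0


class TestGeneAggregation:
    @staticmethod
    def _calls(rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "gene_id", "individual", "tissue", "is_ase"],
        )

    def test_single_ase_site_single_individual(self):
        genes = aggregate_to_genes(
            self._calls([("chr1", 1, "g1", "F1", "liver", True)])
        )
        assert bool(genes.loc[0, "is_ase_gene"])
        assert genes.loc[0, "n_tested_sites"] == 1

    def test_unassigned_sites_dropped(self):
        genes = aggregate_to_genes(self._calls([("chr1", 1, "", "F1", "liver", True)]))
        assert genes.empty

    def test_min_individuals_gate(self):
        genes = aggregate_to_genes(
            self._calls([("chr1", 1, "g1", "F1", "liver", True)]), min_individuals=2
        )
        assert not bool(genes.loc[0, "is_ase_gene"])

    def test_counts_distinct_sites_and_individuals(self):
        calls = self._calls(
            [
                ("chr1", 1, "g1", "F1", "liver", True),
                ("chr1", 1, "g1", "F2", "liver", True),
                ("chr1", 2, "g1", "F1", "liver", False),
            ]
        )
        genes = aggregate_to_genes(calls)
        row = genes.iloc[0]
        assert row["n_tested_sites"] == 2
        assert row["n_ase_sites"] == 1
        assert row["individuals_supporting"] == 2
        assert row["n_ase_sites"] <= row["n_tested_sites"]


class TestImprintedExclusion:
    @staticmethod
    def _genes(ids, tissue="liver"):
        return pd.DataFrame(
            {
                "gene_id": ids,
                "tissue": tissue,
                "n_tested_sites": 1,
                "n_ase_sites": 1,
                "individuals_supporting": 1,
                "is_ase_gene": True,
            }
        )

    def test_listed_gene_removed(self):
        out = exclude_imprinted(self._genes(["IGF2", "ACACA"]), ["IGF2"])
        assert sorted(final_ase_genes(out)["gene_id"]) == ["ACACA"]

    def test_empty_list_unchanged(self):
        out = exclude_imprinted(self._genes(["IGF2"]), [])
        assert len(final_ase_genes(out)) == 1

    def test_case_insensitive(self):
        out = exclude_imprinted(self._genes(["IGF2"]), ["igf2"])
        assert final_ase_genes(out).empty


class TestTissueOverlap:
    @staticmethod
    def _genes(mapping):
        rows = []
        for tissue, ids in mapping.items():
            for g in ids:
                rows.append(
                    {
                        "gene_id": g, "tissue": tissue, "n_tested_sites": 1,
                        "n_ase_sites": 1, "individuals_supporting": 1,
                        "is_ase_gene": True,
                    }
                )
        return pd.DataFrame(rows)

    def test_two_tissue_example(self):
        df, shared = tissue_overlap_summary(self._genes({"liver": ["A", "B"], "bone": ["B"]}))
        spec = dict(zip(df["tissue"], df["specificity"]))
        assert spec["liver"] == 0.5
        assert spec["bone"] == 0.0
        assert shared == {"B"}

    def test_single_tissue_specificity_one(self):
        df, shared = tissue_overlap_summary(self._genes({"liver": ["A", "B"]}))
        assert df.loc[0, "specificity"] == 1.0
        assert shared == {"A", "B"}

    def test_identical_sets_zero_specificity(self):
        df, shared = tissue_overlap_summary(
            self._genes({"liver": ["A"], "bone": ["A"], "fat": ["A"]})
        )
        assert (df["specificity"] == 0.0).all()
        assert shared == {"A"}

    def test_empty_tissue_nan(self):
        genes = self._genes({"liver": ["A"]})
        genes = pd.concat(
            [genes, pd.DataFrame([{"gene_id": "X", "tissue": "bone",
                                   "n_tested_sites": 1, "n_ase_sites": 0,
                                   "individuals_supporting": 0, "is_ase_gene": False}])],
            ignore_index=True,
        )
        df, _ = tissue_overlap_summary(genes)
        assert np.isnan(df[df["tissue"] == "bone"]["specificity"].iloc[0])
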