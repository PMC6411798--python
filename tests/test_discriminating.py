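import math

import numpy as np
import pytest

from conftest import make_site
from crossase import POP_A, POP_B
from crossase.discriminating_variants import (
    AssignmentReport,
    DiscriminatingSnp,
    GeneIndex,
    annotate_snp,
    annotate_snp_all,
    assign_discriminating_snps,
    classify_coding_change,
    filter_by_qual,
    per_gene_snp_counts,
    strict_discriminating_matrix,
    transition_transversion_summary,
)
from crossase.io_formats.gff import GeneModel


class TestFilterByQual:
    def test_just_below_threshold_removed(self):
        assert list(filter_by_qual([make_site(qual=29.9)])) == []

    def test_at_threshold_kept(self):
        assert len(list(filter_by_qual([make_site(qual=30.0)]))) == 1

    def test_empty(self):
        counter = {}
        assert list(filter_by_qual([], counter=counter)) == []
        assert counter["n_qual_filtered"] == 0


def _site(dos_a, dos_b, **kw):
    gt = {}
    pops = {}
    to_gt = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: None}
    for i, d in enumerate(dos_a):
        gt[f"a{i}"], pops[f"a{i}"] = to_gt[d], POP_A
    for i, d in enumerate(dos_b):
        gt[f"b{i}"], pops[f"b{i}"] = to_gt[d], POP_B
    return make_site(genotypes=gt, populations=pops, **kw)


class TestAssignDiscriminating:
    def test_fixed_difference_strict(self):
        (snp,) = assign_discriminating_snps([_site([0, 0], [2, 2])])
        assert snp.allele_of_line_A == snp.site.ref
        assert snp.allele_of_line_B == snp.site.alt

    def test_het_parent_breaks_strict(self):
        assert list(assign_discriminating_snps([_site([0, 1], [2, 2])])) == []

    def test_frequency_mode_085_diff(self):
        # line A alt freq 0.9 (10 samples), line B 0.05 (10 samples): diff 0.85 >= 0.8
        site = _site([2] * 8 + [1] * 2, [1] + [0] * 9)
        (snp,) = assign_discriminating_snps([site], mode="frequency", min_freq_diff=0.8)
        assert snp.allele_of_line_A == site.alt
        assert snp.allele_of_line_B == site.ref

    def test_frequency_mode_below_threshold(self):
        site = _site([2] * 8 + [1] * 2, [1] + [0] * 9)
        assert list(
            assign_discriminating_snps([site], mode="frequency", min_freq_diff=0.9)
        ) == []

    def test_empty_line_skipped_with_tally(self):
        report = AssignmentReport()
        out = list(assign_discriminating_snps([_site([-1, -1], [2, 2])], report=report))
        assert out == []
        assert report.n_skipped_empty_line == 1

    def test_missing_fraction_gate(self):
        site = _site([0, -1], [2, 2])
        assert list(assign_discriminating_snps([site], max_missing_frac=0.0)) == []
        (snp,) = assign_discriminating_snps([site], max_missing_frac=0.5)
        assert snp.n_missing_A == 1

    def test_strict_equals_exhaustive_oracle(self):
        # oracle: direct per-site enumeration over genotype states
        def oracle(dos_a, dos_b):
            geno_a = [d for d in dos_a if d >= 0]
            geno_b = [d for d in dos_b if d >= 0]
            if not geno_a or not geno_b:
                return None
            if len(geno_a) < len(dos_a) or len(geno_b) < len(dos_b):
                return None
            for allele_a, allele_b in ((0, 2), (2, 0)):
                if all(d == allele_a for d in geno_a) and all(
                    d == allele_b for d in geno_b
                ):
                    return allele_a == 2
            return None

        rng = np.random.default_rng(42)
        sites, expected = [], []
        for _ in range(500):
            dos_a = list(rng.integers(-1, 3, size=4))
            dos_b = list(rng.integers(-1, 3, size=3))
            sites.append(_site(dos_a, dos_b))
            expected.append(oracle(dos_a, dos_b))
        got = {id(s): None for s in sites}
        for snp in assign_discriminating_snps(sites):
            got[id(snp.site)] = snp.allele_of_line_A == snp.site.alt
        assert [got[id(s)] for s in sites] == expected

        # and the vectorized matrix path agrees
        mat_a = np.array([s.dosages(POP_A) for s in sites]).T
        mat_b = np.array([s.dosages(POP_B) for s in sites]).T
        mask, a_is_alt = strict_discriminating_matrix(mat_a, mat_b)
        assert list(mask) == [e is not None for e in expected]
        assert [bool(x) for x in a_is_alt[mask]] == [e for e in expected if e is not None]

    def test_type_invariants(self):
        with pytest.raises(ValueError):
            DiscriminatingSnp(site=make_site(), allele_of_line_A="A", allele_of_line_B="A")
        with pytest.raises(ValueError):
            DiscriminatingSnp(site=make_site(ref="A", alt="G"),
                              allele_of_line_A="C", allele_of_line_B="G")


@pytest.fixture
def gene_plus():
    return GeneModel(
        gene_id="gplus", biotype="protein_coding", chrom="chr1", strand="+",
        exons=[(1000, 1500), (2000, 3000)], cds=[(1100, 1400, 0)],
    )


@pytest.fixture
def index(gene_plus):
    return GeneIndex([gene_plus], flank=1000)


class TestAnnotateSnp:
    def test_exonic(self, index):
        ann = annotate_snp(make_site(pos=1201), index)  # pos0 = 1200
        assert ann.category == "exonic"
        assert ann.gene_id == "gplus"

    def test_upstream_500bp_plus_strand(self, index):
        ann = annotate_snp(make_site(pos=501), index)  # pos0 = 500, gene start 1000
        assert ann.category == "upstream"

    def test_downstream_plus_strand(self, index):
        ann = annotate_snp(make_site(pos=3501), index)  # pos0 = 3500, gene end 3000
        assert ann.category == "downstream"

    def test_intergenic_beyond_flank(self, index):
        assert annotate_snp(make_site(pos=50_000), index).category == "intergenic"

    def test_splice_region_at_2bp(self, index):
        # first intronic base after exon end 1500 is pos0 1500 (dist 1)
        assert annotate_snp(make_site(pos=1502), index).category == "splice_region"
        assert annotate_snp(make_site(pos=1503), index).category == "intronic"
        # left edge of next exon at 2000: pos0 1998 is 2 bp away
        assert annotate_snp(make_site(pos=1999), index).category == "splice_region"

    def test_strand_flips_upstream(self):
        gene = GeneModel(
            gene_id="gminus", biotype="protein_coding", chrom="chr1", strand="-",
            exons=[(1000, 2000)], cds=[],
        )
        idx = GeneIndex([gene], flank=1000)
        assert annotate_snp(make_site(pos=501), idx).category == "downstream"
        assert annotate_snp(make_site(pos=2501), idx).category == "upstream"

    def test_overlapping_genes_all_reported_precedence_single(self, gene_plus):
        other = GeneModel(
            gene_id="gother", biotype="protein_coding", chrom="chr1", strand="+",
            exons=[(1490, 2600)], cds=[],
        )
        idx = GeneIndex([gene_plus, other], flank=1000)
        site = make_site(pos=1495)  # pos0 1494: exonic in both
        hits = annotate_snp_all(site, idx)
        assert {h.gene_id for h in hits} == {"gplus", "gother"}
        site2 = make_site(pos=1700)  # pos0 1699: intron of gplus, exon of gother
        best = annotate_snp(site2, idx)
        assert best.category == "exonic" and best.gene_id == "gother"

    def test_partition_property(self, index):
        rng = np.random.default_rng(7)
        sites = [make_site(pos=int(p)) for p in rng.integers(1, 10_000, size=300)]
        cats = [annotate_snp(s, index).category for s in sites]
        assert len(cats) == 300  # every SNP gets exactly one category
        from collections import Counter

        assert sum(Counter(cats).values()) == 300


def _fetch_factory(seq, offset=0):
    def fetch(chrom, start, end):
        return seq[start - offset : end - offset]

    return fetch


class TestClassifyCodingChange:
    def _gene(self, cds, strand="+"):
        start = min(s for s, _, _ in cds)
        end = max(e for _, e, _ in cds)
        return GeneModel(
            gene_id="g", biotype="protein_coding", chrom="chr1", strand=strand,
            exons=[(start, end)], cds=cds,
        )

    def test_synonymous_gtt_to_gtc(self):
        gene = self._gene([(0, 9, 0)])
        fetch = _fetch_factory("GTTAAATGA")
        site = make_site(pos=3, ref="T", alt="C")  # third codon base
        assert classify_coding_change(site, gene, fetch) == "synonymous"

    def test_stopgain_tac_to_taa(self):
        gene = self._gene([(0, 9, 0)])
        fetch = _fetch_factory("TACAAATGA")
        site = make_site(pos=3, ref="C", alt="A")
        assert classify_coding_change(site, gene, fetch) == "stopgain"

    def test_stoploss_tga_to_tgc(self):
        gene = self._gene([(0, 9, 0)])
        fetch = _fetch_factory("ATGAAATGA")
        site = make_site(pos=9, ref="A", alt="C")  # TGA -> TGC
        assert classify_coding_change(site, gene, fetch) == "stoploss"

    def test_nonsynonymous(self):
        gene = self._gene([(0, 9, 0)])
        fetch = _fetch_factory("GTTAAATGA")
        site = make_site(pos=1, ref="G", alt="A")  # GTT(Val) -> ATT(Ile)
        assert classify_coding_change(site, gene, fetch) == "nonsynonymous"

    def test_utr_returns_none(self):
        gene = GeneModel(
            gene_id="g", biotype="protein_coding", chrom="chr1", strand="+",
            exons=[(0, 20)], cds=[(6, 15, 0)],
        )
        fetch = _fetch_factory("A" * 20)
        assert classify_coding_change(make_site(pos=2, ref="A", alt="G"), gene, fetch) == "none"

    def test_minus_strand_concrete(self):
        # reference revcomp("ATGGTTTAA") laid at 100..109 on a minus gene
        ref = "N" * 100 + "TTAAACCAT"
        gene = self._gene([(100, 109, 0)], strand="-")
        fetch = _fetch_factory(ref)
        # coding GTT -> GTC: genomic pos0 103, ref A alt G
        site = make_site(pos=104, ref="A", alt="G")
        assert classify_coding_change(site, gene, fetch) == "synonymous"

    def test_strand_metamorphic(self):
        rng = np.random.default_rng(3)
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            j = int(rng.integers(0, 30))
            alt = rng.choice([b for b in "ACGT" if b != seq[j]])
            plus = self._gene([(0, 30, 0)], strand="+")
            res_plus = classify_coding_change(
                make_site(pos=j + 1, ref=seq[j], alt=alt), plus, _fetch_factory(seq)
            )
            rc = seq.translate(comp)[::-1]
            minus = self._gene([(0, 30, 0)], strand="-")
            res_minus = classify_coding_change(
                make_site(pos=30 - j, ref=rc[29 - j], alt=alt.translate(comp)),
                minus,
                _fetch_factory(rc),
            )
            assert res_plus == res_minus

    def test_codon_spanning_exons(self):
        # CDS split 4 + 5: codon 2 spans the junction
        gene = GeneModel(
            gene_id="g", biotype="protein_coding", chrom="chr1", strand="+",
            exons=[(0, 4), (10, 15)], cds=[(0, 4, 0), (10, 15, 0)],
        )
        seq = "GTTG" + "N" * 6 + "TTTAA"
        fetch = _fetch_factory(seq)
        # second codon = G + TT; G->A at pos0 3: GTT(Val)->ATT(Ile)
        site = make_site(pos=4, ref="G", alt="A")
        assert classify_coding_change(site, gene, fetch) == "nonsynonymous"


class TestTsTv:
    def _snps(self, pairs):
        return [make_site(ref=r, alt=a) for r, a in pairs]

    def test_balanced(self):
        n_ts, n_tv, ratio = transition_transversion_summary(
            self._snps([("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")])
        )
        assert (n_ts, n_tv, ratio) == (2, 2, 1.0)

    def test_no_transversions_is_nan(self):
        n_ts, n_tv, ratio = transition_transversion_summary(self._snps([("A", "G")]))
        assert (n_ts, n_tv) == (1, 0)
        assert math.isnan(ratio)

    def test_six_ts_three_tv(self):
        pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "G"), ("C", "T"),
                 ("A", "C"), ("A", "T"), ("G", "C")]
        n_ts, n_tv, ratio = transition_transversion_summary(self._snps(pairs))
        assert (n_ts, n_tv, ratio) == (6, 3, 2.0)


class TestPerGeneCounts:
    def test_intronic_counted(self, index):
        snps = [make_site(pos=1700), make_site(pos=1750), make_site(pos=1800)]
        assert per_gene_snp_counts(snps, index) == {"gplus": 3}

    def test_intergenic_empty(self, index):
        assert per_gene_snp_counts([make_site(pos=90_000)], index) == {}

    def test_shared_exonic_snp_counted_for_both(self, gene_plus):
        other = GeneModel(
            gene_id="gother", biotype="protein_coding", chrom="chr1", strand="-",
            exons=[(1400, 2600)], cds=[],
        )
        idx = GeneIndex([gene_plus, other], flank=1000)
        counts = per_gene_snp_counts([make_site(pos=1450)], idx)
        assert counts == {"gplus": 1, "gother": 1}
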