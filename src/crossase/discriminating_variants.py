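"""Line-discriminating SNPs: quality filtering, assignment, annotation.

A discriminating SNP is a site where the two parental lines carry
distinguishable alleles, so every F1 allele's line of origin is known.
Strict mode (the default) requires fixed opposite homozygotes in the two
lines, which forces F1 heterozygosity; frequency mode accepts a large
allele-frequency contrast and records each line's majority allele.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
from Bio.Seq import Seq

from . import POP_A, POP_B
from .io_formats.gff import GeneModel
from .io_formats.vcf import VariantSite

CATEGORIES = (
    "exonic",
    "splice_region",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_PRECEDENCE = {cat: i for i, cat in enumerate(CATEGORIES)}

CODING_CHANGES = ("synonymous", "nonsynonymous", "stopgain", "stoploss", "none")

_TRANSITIONS = (frozenset("AG"), frozenset("CT"))

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class DiscriminatingSnp:
    site: VariantSite
    allele_of_line_A: str
    allele_of_line_B: str
    n_missing_A: int = 0
    n_missing_B: int = 0

    def __post_init__(self):
        if self.allele_of_line_A == self.allele_of_line_B:
            raise ValueError("line alleles must differ")
        alleles = {self.site.ref, self.site.alt}
        if self.allele_of_line_A not in alleles or self.allele_of_line_B not in alleles:
            raise ValueError("line alleles must be the site's ref/alt")


@dataclass
class SnpAnnotation:
    category: str
    coding_change: str = "none"
    gene_id: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")
        if self.coding_change != "none" and self.category != "exonic":
            raise ValueError("coding change implies exonic category")
        if self.category in ("exonic", "intronic", "splice_region") and not self.gene_id:
            raise ValueError(f"{self.category} annotation requires a gene_id")


@dataclass
class AssignmentReport:
    n_discriminating: int = 0
    n_not_discriminating: int = 0
    n_skipped_empty_line: int = 0
    n_skipped_missing: int = 0


# ---------------------------------------------------------------------------
# Filtering and assignment
# ---------------------------------------------------------------------------

def filter_by_qual(
    sites: Iterable[VariantSite], min_qual: float = 30.0, counter: Optional[dict] = None
) -> Iterator[VariantSite]:
    """Drop sites with QUAL below ``min_qual`` (QUAL < threshold removed)."""
    n_removed = 0
    for site in sites:
        if site.qual >= min_qual:
            yield site
        else:
            n_removed += 1
    if counter is not None:
        counter["n_qual_filtered"] = n_removed


def _line_summary(site: VariantSite, label: str):
    dosages = site.dosages(label)
    genotyped = [d for d in dosages if d >= 0]
    return dosages, genotyped, len(dosages) - len(genotyped)


def assign_discriminating_snps(
    sites: Iterable[VariantSite],
    mode: str = "strict",
    max_missing_frac: float = 0.0,
    min_freq_diff: float = 0.8,
    labels: Tuple[str, str] = (POP_A, POP_B),
    report: Optional[AssignmentReport] = None,
) -> Iterator[DiscriminatingSnp]:
    """Yield sites whose alleles separate the two parental lines.

    strict: every genotyped line-A parent homozygous for one allele and
    every genotyped line-B parent homozygous for the other, with each
    line's missing fraction <= ``max_missing_frac``. frequency: the
    lines' alt frequencies differ by >= ``min_freq_diff``; the majority
    allele of each line is recorded. Sites where a line has no genotyped
    sample are skipped and tallied.
    """
    if mode not in ("strict", "frequency"):
        raise ValueError(f"unknown mode {mode!r}")
    if report is None:
        report = AssignmentReport()

    for site in sites:
        dos_a, geno_a, miss_a = _line_summary(site, labels[0])
        dos_b, geno_b, miss_b = _line_summary(site, labels[1])
        if not geno_a or not geno_b:
            report.n_skipped_empty_line += 1
            continue
        if (
            miss_a / len(dos_a) > max_missing_frac
            or miss_b / len(dos_b) > max_missing_frac
        ):
            report.n_skipped_missing += 1
            continue

        if mode == "strict":
            a_fixed_ref = all(d == 0 for d in geno_a)
            a_fixed_alt = all(d == 2 for d in geno_a)
            b_fixed_ref = all(d == 0 for d in geno_b)
            b_fixed_alt = all(d == 2 for d in geno_b)
            if a_fixed_ref and b_fixed_alt:
                alleles = (site.ref, site.alt)
            elif a_fixed_alt and b_fixed_ref:
                alleles = (site.alt, site.ref)
            else:
                report.n_not_discriminating += 1
                continue
        else:
            freq_a = sum(geno_a) / (2 * len(geno_a))
            freq_b = sum(geno_b) / (2 * len(geno_b))
            if abs(freq_a - freq_b) < min_freq_diff:
                report.n_not_discriminating += 1
                continue
            allele_a = site.alt if freq_a >= 0.5 else site.ref
            allele_b = site.alt if freq_b >= 0.5 else site.ref
            if allele_a == allele_b:
                report.n_not_discriminating += 1
                continue
            alleles = (allele_a, allele_b)

        report.n_discriminating += 1
        yield DiscriminatingSnp(
            site=site,
            allele_of_line_A=alleles[0],
            allele_of_line_B=alleles[1],
            n_missing_A=miss_a,
            n_missing_B=miss_b,
        )


def strict_discriminating_matrix(
    dos_a: np.ndarray, dos_b: np.ndarray, max_missing_frac: float = 0.0
):
    """Vectorized strict assignment over (samples x sites) dosage matrices.

    Returns (mask, allele_A_is_alt): ``mask`` marks discriminating sites,
    ``allele_A_is_alt`` is True where line A is fixed for the alt allele.
    """
    dos_a = np.asarray(dos_a)
    dos_b = np.asarray(dos_b)

    def fixed(dos):
        genotyped = dos >= 0
        n_geno = genotyped.sum(axis=0)
        ok_missing = (dos.shape[0] - n_geno) <= max_missing_frac * dos.shape[0]
        all0 = (np.where(genotyped, dos, 0) == 0).all(axis=0) & (n_geno > 0)
        all2 = (np.where(genotyped, dos, 2) == 2).all(axis=0) & (n_geno > 0)
        return ok_missing, all0, all2

    ok_a, a0, a2 = fixed(dos_a)
    ok_b, b0, b2 = fixed(dos_b)
    mask = ok_a & ok_b & ((a0 & b2) | (a2 & b0))
    return mask, a2


# ---------------------------------------------------------------------------
# Annotation against gene models
# ---------------------------------------------------------------------------

class GeneIndex:
    """Per-chromosome interval lookup of gene spans plus flanks."""

    def __init__(self, gene_models: Iterable[GeneModel], flank: int = 1000):
        self.flank = flank
        self._by_chrom: Dict[str, List[GeneModel]] = {}
        for g in gene_models:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: Dict[str, List[int]] = {}
        self._max_len: Dict[str, int] = {}
        for chrom, genes in self._by_chrom.items():
            genes.sort(key=lambda g: g.start)
            self._starts[chrom] = [g.start for g in genes]
            self._max_len[chrom] = max(g.end - g.start for g in genes)

    def genes(self) -> List[GeneModel]:
        return [g for genes in self._by_chrom.values() for g in genes]

    def hits(self, chrom: str, pos0: int) -> List[GeneModel]:
        """Genes whose flanked span [start-flank, end+flank) contains pos0."""
        genes = self._by_chrom.get(chrom)
        if not genes:
            return []
        starts = self._starts[chrom]
        reach = self._max_len[chrom] + self.flank
        lo = bisect.bisect_left(starts, pos0 - reach)
        hi = bisect.bisect_right(starts, pos0 + self.flank)
        return [
            g
            for g in genes[lo:hi]
            if g.start - self.flank <= pos0 < g.end + self.flank
        ]


def _category_in_gene(gene: GeneModel, pos0: int, splice_bp: int) -> str:
    if gene.start <= pos0 < gene.end:
        if gene.in_exon(pos0):
            return "exonic"
        dist = math.inf
        for s, e in gene.exons:
            if pos0 < s:
                dist = min(dist, s - pos0)
            elif pos0 >= e:
                dist = min(dist, pos0 - e + 1)
        return "splice_region" if dist <= splice_bp else "intronic"
    five_prime = pos0 < gene.start if gene.strand == "+" else pos0 >= gene.end
    return "upstream" if five_prime else "downstream"


def annotate_snp_all(
    site,
    gene_index: GeneIndex,
    splice_bp: int = 2,
    seq_fetch: Optional[Callable[[str, int, int], str]] = None,
) -> List[SnpAnnotation]:
    """Annotations of a site against every overlapping (flanked) gene."""
    pos0 = site.pos - 1
    out = []
    for gene in gene_index.hits(site.chrom, pos0):
        category = _category_in_gene(gene, pos0, splice_bp)
        coding = "none"
        if (
            category == "exonic"
            and seq_fetch is not None
            and gene.cds
            and gene.in_cds(pos0)
        ):
            coding = classify_coding_change(site, gene, seq_fetch)
        out.append(SnpAnnotation(category=category, coding_change=coding, gene_id=gene.gene_id))
    return out


def annotate_snp(
    site,
    gene_index: GeneIndex,
    splice_bp: int = 2,
    seq_fetch: Optional[Callable[[str, int, int], str]] = None,
) -> SnpAnnotation:
    """Single annotation by precedence exonic > splice_region > intronic >
    upstream > downstream > intergenic (ANNOVAR-style)."""
    hits = annotate_snp_all(site, gene_index, splice_bp=splice_bp, seq_fetch=seq_fetch)
    if not hits:
        return SnpAnnotation(category="intergenic")
    return min(hits, key=lambda ann: _PRECEDENCE[ann.category])


def classify_coding_change(
    site, gene: GeneModel, seq_fetch: Callable[[str, int, int], str]
) -> str:
    """Effect of the alt allele on the codon it falls in.

    Rebuilds the affected codon from the CDS (handling exon-spanning
    codons, strand and phase), substitutes the alternate base and
    translates both with the standard genetic code. Returns 'none' for
    positions inside an exon but outside the CDS (UTR).
    """
    pos0 = site.pos - 1
    segments = sorted(gene.cds)
    if not any(s <= pos0 < e for s, e, _ in segments):
        return "none"

    # genomic positions of the CDS in transcription order
    if gene.strand == "-":
        tx_segments = segments[::-1]
    else:
        tx_segments = segments
    coding_positions: List[int] = []
    for s, e, _ in tx_segments:
        block = range(s, e) if gene.strand == "+" else range(e - 1, s - 1, -1)
        coding_positions.extend(block)
    frame = tx_segments[0][2]
    coding_positions = coding_positions[frame:]

    try:
        offset = coding_positions.index(pos0)
    except ValueError:
        return "none"  # trimmed by an incomplete leading codon
    codon_index = offset // 3
    codon_positions = coding_positions[codon_index * 3 : codon_index * 3 + 3]
    if len(codon_positions) < 3:
        return "none"  # incomplete trailing codon

    def base_at(gpos: int, override: Optional[str] = None) -> str:
        raw = override if gpos == pos0 and override else seq_fetch(site.chrom, gpos, gpos + 1)
        raw = raw.upper()
        return raw.translate(_COMPLEMENT) if gene.strand == "-" else raw

    ref_codon = "".join(base_at(p) for p in codon_positions)
    alt_codon = "".join(base_at(p, override=site.alt) for p in codon_positions)
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_ref != "*" and aa_alt == "*":
        return "stopgain"
    if aa_ref == "*" and aa_alt != "*":
        return "stoploss"
    return "nonsynonymous"


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def transition_transversion_summary(snps: Iterable) -> Tuple[int, int, float]:
    """(n_transitions, n_transversions, ratio); ratio NaN when no transversions."""
    n_ts = n_tv = 0
    for snp in snps:
        site = snp.site if isinstance(snp, DiscriminatingSnp) else snp
        if frozenset((site.ref, site.alt)) in _TRANSITIONS:
            n_ts += 1
        else:
            n_tv += 1
    ratio = n_ts / n_tv if n_tv else float("nan")
    return n_ts, n_tv, ratio


def per_gene_snp_counts(
    snps: Iterable, gene_index: GeneIndex, splice_bp: int = 2
) -> Dict[str, int]:
    """Count SNPs per gene over genic annotations (exonic/intronic/splice).

    A SNP overlapping two genes is counted for both.
    """
    counts: Dict[str, int] = {}
    for snp in snps:
        site = snp.site if isinstance(snp, DiscriminatingSnp) else snp
        seen = set()
        for ann in annotate_snp_all(site, gene_index, splice_bp=splice_bp):
            if ann.category in ("exonic", "intronic", "splice_region") and ann.gene_id not in seen:
                counts[ann.gene_id] = counts.get(ann.gene_id, 0) + 1
                seen.add(ann.gene_id)
    return counts
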