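"""VCF input/output restricted to biallelic SNPs with GT calls."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Tuple

import pysam

_BASES = frozenset("ACGT")

Genotype = Optional[Tuple[int, int]]  # None == missing


@dataclass
class VariantSite:
    """One biallelic SNP record.

    ``pos`` is the 1-based VCF position (kept as-is because this is a
    boundary type); use :meth:`pos0` for the internal 0-based coordinate.
    ``genotypes`` maps sample name to an allele-index pair or ``None``
    (missing); phase is deliberately discarded. ``populations`` maps each
    sample to its population label.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    genotypes: Dict[str, Genotype]
    populations: Dict[str, str]

    @property
    def pos0(self) -> int:
        return self.pos - 1

    def dosages(self, label: str) -> list:
        """Alt-allele dosages (0/1/2, -1 missing) for samples of one population."""
        out = []
        for sample, pop in self.populations.items():
            if pop != label:
                continue
            gt = self.genotypes.get(sample)
            out.append(-1 if gt is None else gt[0] + gt[1])
        return out

    def validate(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        for sample, gt in self.genotypes.items():
            if gt is not None and not all(a in (0, 1) for a in gt):
                raise ValueError(
                    f"illegal genotype {gt} for sample {sample} at {self.chrom}:{self.pos}"
                )


@dataclass
class VcfParseReport:
    """Tally of records skipped while streaming a VCF."""

    n_kept: int = 0
    n_indel: int = 0
    n_multiallelic: int = 0
    n_missing_gt: int = 0
    n_other: int = 0
    skipped: Dict[str, int] = field(default_factory=dict)

    @property
    def n_skipped(self) -> int:
        return self.n_indel + self.n_multiallelic + self.n_missing_gt + self.n_other


def _normalize_gt(raw) -> Genotype:
    if raw is None:
        return None
    alleles = tuple(a for a in raw if a is not None)
    if len(alleles) != 2:
        return None
    return (alleles[0], alleles[1])


def read_vcf(
    path: str,
    population_map: Dict[str, str],
    report: Optional[VcfParseReport] = None,
) -> Iterator[VariantSite]:
    """Stream biallelic SNP records from a VCF v4.x file.

    Indel, multiallelic and GT-less records are skipped and tallied in
    ``report``. Phased genotypes are treated like unphased ones. Samples
    not present in ``population_map`` are ignored.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if report is None:
        report = VcfParseReport()

    vf = pysam.VariantFile(path)
    header_samples = set(vf.header.samples)
    missing = sorted(set(population_map) - header_samples)
    if missing:
        raise ValueError(f"samples in population_map absent from VCF header: {missing}")

    n_header_lines = str(vf.header).count("\n")
    record_index = 0
    samples = [s for s in vf.header.samples if s in population_map]
    populations = {s: population_map[s] for s in samples}
    try:
        for rec in vf:
            record_index += 1
            if rec.alts is None or len(rec.alts) != 1:
                report.n_multiallelic += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                report.n_indel += 1
                continue
            if ref not in _BASES or alt not in _BASES:
                report.n_other += 1
                continue
            if "GT" not in rec.format:
                report.n_missing_gt += 1
                continue
            genotypes = {s: _normalize_gt(rec.samples[s].get("GT")) for s in samples}
            site = VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=ref,
                alt=alt,
                qual=float(rec.qual) if rec.qual is not None else float("nan"),
                genotypes=genotypes,
                populations=populations,
            )
            site.validate()
            report.n_kept += 1
            yield site
    except (ValueError, OSError) as exc:
        raise ValueError(
            f"malformed VCF record near line {n_header_lines + record_index + 1} "
            f"of {path}: {exc}"
        ) from exc


def write_vcf(sites, path: str, contigs: Optional[Dict[str, int]] = None) -> int:
    """Write VariantSites as an uncompressed VCF v4.2 text file.

    Returns the number of records written. Sample order follows the
    ``populations`` mapping of the first site.
    """
    sites = list(sites)
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = list(sites[0].populations) if sites else []
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT" +
        ("\t" + "\t".join(samples) if samples else "")
    )
    for site in sites:
        gts = []
        for s in samples:
            gt = site.genotypes.get(s)
            gts.append("./." if gt is None else f"{gt[0]}/{gt[1]}")
        qual = "." if site.qual != site.qual else f"{site.qual:g}"
        row = [site.chrom, str(site.pos), ".", site.ref, site.alt, qual, ".", ".", "GT"]
        lines.append("\t".join(row + gts) if gts else "\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return len(sites)
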