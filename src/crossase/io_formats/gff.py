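"""GFF3 gene models, collapsed to one model per gene.

Multi-transcript genes are reduced to the union of their exons plus the
CDS of the transcript with the longest total coding length. All
intervals are stored 0-based half-open; GFF3's 1-based closed intervals
are converted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import gffutils

BIOTYPES = ("protein_coding", "noncoding_RNA", "pseudogene")


@dataclass
class GeneModel:
    gene_id: str
    biotype: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    cds: List[Tuple[int, int, int]] = field(default_factory=list)  # (start, end, frame)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def in_exon(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)

    def in_cds(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e, _ in self.cds)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: bad biotype {self.biotype!r}")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for s, e, frame in self.cds:
            if frame not in (0, 1, 2):
                raise ValueError(f"{self.gene_id}: bad frame {frame}")
            if not any(es <= s and e <= ee for es, ee in exons):
                raise ValueError(f"{self.gene_id}: CDS outside exons")


def _merge_intervals(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _biotype_of(feature) -> str:
    for key in ("biotype", "gene_biotype", "gene_type"):
        if key in feature.attributes:
            value = feature.attributes[key][0]
            if value in BIOTYPES:
                return value
    return "protein_coding"


def read_gene_models(path: str) -> List[GeneModel]:
    """Parse a GFF3 file into one collapsed GeneModel per gene.

    Transcripts (mRNA or any feature with a Parent pointing at a gene)
    contribute exons to the union; the longest-CDS transcript supplies
    the coding intervals. A CDS feature that cannot be traced to a gene
    raises a ValueError.
    """
    try:
        db = gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    gene_ids = {g.id for g in db.features_of_type("gene")}

    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds))
        if not parents or not any(
            p.id in gene_ids or p.featuretype == "gene" for p in parents
        ):
            raise ValueError(f"CDS {cds.id!r} has no parent gene")

    models: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exon_union: List[Tuple[int, int]] = []
        cds_by_tx: Dict[str, List[Tuple[int, int, int]]] = {}

        for exon in db.children(gene, featuretype="exon"):
            exon_union.append((exon.start - 1, exon.end))
        for cds in db.children(gene, featuretype="CDS"):
            tx_parents = [p.id for p in db.parents(cds, level=1)] or [gene.id]
            frame = int(cds.frame) if cds.frame not in (None, ".") else 0
            for tx in tx_parents:
                cds_by_tx.setdefault(tx, []).append((cds.start - 1, cds.end, frame))

        if not exon_union:  # gene with no exon features: use its own span
            exon_union = [(gene.start - 1, gene.end)]

        best_cds: List[Tuple[int, int, int]] = []
        if cds_by_tx:
            best_tx = max(
                sorted(cds_by_tx),
                key=lambda tx: sum(e - s for s, e, _ in cds_by_tx[tx]),
            )
            best_cds = sorted(cds_by_tx[best_tx])

        model = GeneModel(
            gene_id=gene.id,
            biotype=_biotype_of(gene),
            chrom=gene.seqid,
            strand=gene.strand if gene.strand in "+-" else "+",
            exons=_merge_intervals(exon_union),
            cds=best_cds,
        )
        model.validate()
        models.append(model)
    return models


def write_gff3(models: List[GeneModel], path: str) -> int:
    """Write GeneModels as a single-transcript-per-gene GFF3 file."""
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda g: (g.chrom, g.start)):
        attrs = f"ID={m.gene_id};biotype={m.biotype}"
        lines.append(
            "\t".join(
                [m.chrom, "crossase", "gene", str(m.start + 1), str(m.end), ".",
                 m.strand, ".", attrs]
            )
        )
        tx = f"{m.gene_id}.t1"
        lines.append(
            "\t".join(
                [m.chrom, "crossase", "mRNA", str(m.start + 1), str(m.end), ".",
                 m.strand, ".", f"ID={tx};Parent={m.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append(
                "\t".join(
                    [m.chrom, "crossase", "exon", str(s + 1), str(e), ".",
                     m.strand, ".", f"ID={tx}.e{i};Parent={tx}"]
                )
            )
        for i, (s, e, frame) in enumerate(m.cds, 1):
            lines.append(
                "\t".join(
                    [m.chrom, "crossase", "CDS", str(s + 1), str(e), ".",
                     m.strand, str(frame), f"ID={tx}.c{i};Parent={tx}"]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return len(models)
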