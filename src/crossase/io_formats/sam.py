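"""Plain-text SAM input/output.

Records are parsed per line with pysam so that one malformed record
raises an error naming the offending read instead of truncating the
whole stream.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import pysam

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")


@dataclass
class AlignedRead:
    """One mapped SAM record. ``pos`` is the 1-based leftmost position."""

    qname: str
    flag: int
    chrom: str
    pos: int
    mapq: int
    cigar: str
    seq: str
    quals: Optional[List[int]]  # None when QUAL column is '*'

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    def cigar_ops(self) -> List[Tuple[str, int]]:
        return [(op, int(n)) for n, op in _CIGAR_RE.findall(self.cigar)]

    def query_length_from_cigar(self) -> int:
        return sum(n for op, n in self.cigar_ops() if op in _QUERY_OPS)

    def reference_length_from_cigar(self) -> int:
        return sum(n for op, n in self.cigar_ops() if op in _REF_OPS)

    def query_offset_at(self, ref_pos0: int) -> Optional[int]:
        """Query offset aligned to 0-based reference position, or None.

        Walks the CIGAR; positions under deletions (D) or skipped
        segments (N) return None.
        """
        rpos = self.pos0
        qpos = 0
        for op, n in self.cigar_ops():
            if op in "M=X":
                if rpos <= ref_pos0 < rpos + n:
                    return qpos + (ref_pos0 - rpos)
                rpos += n
                qpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                if rpos <= ref_pos0 < rpos + n:
                    return None
                rpos += n
            # H and P consume nothing
        return None


@dataclass
class SamParseReport:
    n_kept: int = 0
    n_unmapped: int = 0
    references: Dict[str, int] = field(default_factory=dict)


def read_sam(path: str, report: Optional[SamParseReport] = None) -> Iterator[AlignedRead]:
    """Stream mapped reads from a text SAM file.

    Unmapped records (flag 0x4) are skipped and tallied. A CIGAR whose
    consumed query length disagrees with the sequence length raises a
    ValueError naming the read.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if report is None:
        report = SamParseReport()

    header_lines: List[str] = []
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if line.startswith("@"):
                header_lines.append(line)
            else:
                fh.seek(pos)
                break

        header_text = "".join(header_lines) or "@HD\tVN:1.6\n"
        header = pysam.AlignmentHeader.from_text(header_text)
        for name, length in zip(header.references, header.lengths):
            report.references[name] = length

        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            qname = line.split("\t", 1)[0]
            try:
                seg = pysam.AlignedSegment.fromstring(line, header)
            except ValueError as exc:
                raise ValueError(f"malformed SAM record for read {qname!r}: {exc}") from exc
            if seg.is_unmapped:
                report.n_unmapped += 1
                continue
            quals = list(seg.query_qualities) if seg.query_qualities is not None else None
            read = AlignedRead(
                qname=seg.query_name,
                flag=seg.flag,
                chrom=seg.reference_name,
                pos=seg.reference_start + 1,
                mapq=seg.mapping_quality,
                cigar=seg.cigarstring or "",
                seq=seg.query_sequence or "",
                quals=quals,
            )
            if read.query_length_from_cigar() != len(read.seq):
                raise ValueError(
                    f"CIGAR/sequence length mismatch for read {read.qname!r}: "
                    f"{read.cigar} vs {len(read.seq)} bases"
                )
            report.n_kept += 1
            yield read


def write_sam(reads, path: str, references: Dict[str, int]) -> int:
    """Write AlignedReads as a text SAM file with an @SQ header."""
    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for read in reads:
            qual = (
                "*"
                if read.quals is None
                else "".join(chr(q + 33) for q in read.quals)
            )
            fh.write(
                "\t".join(
                    [
                        read.qname,
                        str(read.flag),
                        read.chrom,
                        str(read.pos),
                        str(read.mapq),
                        read.cigar,
                        "*",
                        "0",
                        "0",
                        read.seq,
                        qual,
                    ]
                )
                + "\n"
            )
            n += 1
    return n
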