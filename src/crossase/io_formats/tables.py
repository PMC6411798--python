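"""TSV and BED helpers with exact round-trip behaviour."""

from __future__ import annotations

from typing import List, Tuple

import pandas as pd


def write_tsv(df: pd.DataFrame, path: str) -> None:
    """Write a DataFrame as a header-bearing TSV; NAs as 'NA'."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tsv(path: str) -> pd.DataFrame:
    """Read a TSV written by write_tsv; '#'-prefixed lines (the report
    tables' fingerprint stamp) are skipped."""
    return pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=True, comment="#"
    )


def write_bed(intervals: List[Tuple], path: str) -> None:
    """Write (chrom, start, end, *extra) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str) -> List[Tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            fields[1] = int(fields[1])
            fields[2] = int(fields[2])
            out.append(tuple(fields))
    return out
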