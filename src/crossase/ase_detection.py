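"""Allelic-imbalance detection at F1-heterozygous discriminating SNPs.

Counts alleles in RNA alignments, pools technical replicates, applies
the published depth gates (each allele >= 20 reads, total >= 50), tests
each site's line-A read fraction against 0.5 with an exact two-sided
binomial test, adjusts per tissue with Benjamini-Hochberg, and calls ASE
where the adjusted p falls below 0.05 AND the ratio leaves (0.3, 0.7).
Gene-level calls aggregate sites; known imprinted genes are excluded.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom

from .io_formats.sam import AlignedRead

COUNT_COLUMNS = ["n_ref", "n_alt", "n_other"]
KEY_COLUMNS = ["chrom", "pos", "ref", "alt", "gene_id", "individual", "tissue"]


# ---------------------------------------------------------------------------
# Allele counting from alignments
# ---------------------------------------------------------------------------

def extract_allele_counts(
    reads: Iterable[AlignedRead],
    sites: pd.DataFrame,
    min_mapq: int = 20,
    min_baseq: int = 20,
) -> pd.DataFrame:
    """Per-site ref/alt/other read counts from one alignment stream.

    ``sites`` needs columns chrom, pos (1-based), ref, alt; extra columns
    are carried through. Reads flagged unmapped/secondary/supplementary/
    duplicate are skipped, as are bases below ``min_baseq`` or reads
    below ``min_mapq``. Sites under a deletion or N-skip contribute
    nothing.
    """
    sites = sites.reset_index(drop=True)
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
        idx = sub.index.to_numpy()[order]
        by_chrom[str(chrom)] = (sub["pos"].to_numpy()[order] - 1, idx)

    n_ref = np.zeros(len(sites), dtype=int)
    n_alt = np.zeros(len(sites), dtype=int)
    n_other = np.zeros(len(sites), dtype=int)

    for read in reads:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.mapq < min_mapq
        ):
            continue
        entry = by_chrom.get(read.chrom)
        if entry is None:
            continue
        pos0s, idxs = entry
        start = read.pos0
        end = start + read.reference_length_from_cigar()
        lo = np.searchsorted(pos0s, start, side="left")
        hi = np.searchsorted(pos0s, end, side="left")
        for j in range(lo, hi):
            qoff = read.query_offset_at(int(pos0s[j]))
            if qoff is None:
                continue
            if read.quals is not None and read.quals[qoff] < min_baseq:
                continue
            base = read.seq[qoff].upper()
            row = idxs[j]
            if base == sites.at[row, "ref"]:
                n_ref[row] += 1
            elif base == sites.at[row, "alt"]:
                n_alt[row] += 1
            else:
                n_other[row] += 1

    out = sites.copy()
    out["n_ref"] = n_ref
    out["n_alt"] = n_alt
    out["n_other"] = n_other
    return out


# ---------------------------------------------------------------------------
# Pooling and depth filtering
# ---------------------------------------------------------------------------

def relabel_by_line(counts: pd.DataFrame, allele_a_is_alt: pd.Series) -> pd.DataFrame:
    """Attach n_line_A / n_line_B given each site's line-A allele.

    ``allele_a_is_alt`` is indexed like ``counts`` (True where line A
    carries the alt allele).
    """
    counts = counts.copy()
    a_is_alt = np.asarray(allele_a_is_alt, dtype=bool)
    counts["n_line_A"] = np.where(a_is_alt, counts["n_alt"], counts["n_ref"])
    counts["n_line_B"] = np.where(a_is_alt, counts["n_ref"], counts["n_alt"])
    return counts


def pool_replicates(counts: pd.DataFrame, scheme: str = "sum") -> pd.DataFrame:
    """Combine technical replicates of the same (individual, tissue, site)."""
    if scheme == "separate":
        return counts.copy()
    if scheme != "sum":
        raise ValueError(f"unknown scheme {scheme!r}")
    value_cols = [
        c for c in counts.columns
        if c in COUNT_COLUMNS or c in ("n_line_A", "n_line_B")
    ]
    key_cols = [c for c in counts.columns if c not in value_cols and c != "replicate"]
    pooled = counts.groupby(key_cols, sort=False, as_index=False, dropna=False)[
        value_cols
    ].sum()
    return pooled


def filter_counts(
    counts: pd.DataFrame,
    min_allele_depth: int = 20,
    min_total_depth: int = 50,
    mode: str = "literal",
) -> pd.DataFrame:
    """Depth gate on the two line-labelled allele counts.

    literal: keep iff min(n_line_A, n_line_B) >= min_allele_depth and
    total >= min_total_depth (a site with either allele below 20 reads or
    fewer than 50 reads overall is filtered out). major: only the larger
    allele count must reach ``min_allele_depth``.
    """
    a = counts["n_line_A"].to_numpy()
    b = counts["n_line_B"].to_numpy()
    total_ok = (a + b) >= min_total_depth
    if mode == "literal":
        allele_ok = np.minimum(a, b) >= min_allele_depth
    elif mode == "major":
        allele_ok = np.maximum(a, b) >= min_allele_depth
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return counts[total_ok & allele_ok].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Testing and multiple-testing correction
# ---------------------------------------------------------------------------

def binomial_p_values(n_a: np.ndarray, n_b: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided binomial p against 0.5.

    For the symmetric null this equals min(1, 2*min(lower, upper tail)),
    identical to the minimum-likelihood construction.
    """
    k = np.asarray(n_a, dtype=np.int64)
    n = k + np.asarray(n_b, dtype=np.int64)
    if np.any(n < 1):
        raise ValueError("binomial test needs at least one observation")
    lower = binom.cdf(k, n, 0.5)
    upper = binom.sf(k - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def binomial_test(n_a: int, n_b: int) -> float:
    """Exact two-sided binomial p-value for counts (n_a, n_b) vs 0.5."""
    if n_a + n_b < 1:
        raise ValueError("binomial test needs at least one observation")
    return float(binomial_p_values(np.array([n_a]), np.array([n_b]))[0])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to the
    input order. Inputs must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def call_ase_sites(
    counts: pd.DataFrame,
    q_threshold: float = 0.05,
    ratio_hi: float = 0.7,
    ratio_lo: float = 0.3,
    fdr_scope: str = "per_tissue",
) -> pd.DataFrame:
    """Per-site ASE calls: ratio, exact binomial p, BH q, is_ase.

    is_ase requires q < ``q_threshold`` AND a line-A read fraction
    strictly above ``ratio_hi`` or strictly below ``ratio_lo`` (a ratio
    of exactly 0.7 is never called). FDR families are tissues by default.
    """
    if fdr_scope not in ("per_tissue", "global"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    calls = counts.copy().reset_index(drop=True)
    a = calls["n_line_A"].to_numpy(dtype=float)
    b = calls["n_line_B"].to_numpy(dtype=float)
    calls["ratio"] = a / (a + b)
    calls["p_value"] = binomial_p_values(
        calls["n_line_A"].to_numpy(), calls["n_line_B"].to_numpy()
    )
    q = np.empty(len(calls))
    if fdr_scope == "per_tissue" and "tissue" in calls.columns:
        for _, idx in calls.groupby("tissue", sort=False).groups.items():
            loc = np.asarray(idx)
            q[loc] = bh_adjust(calls.loc[loc, "p_value"].to_numpy())
    else:
        q[:] = bh_adjust(calls["p_value"].to_numpy())
    calls["q_value"] = q
    calls["is_ase"] = (calls["q_value"] < q_threshold) & (
        (calls["ratio"] > ratio_hi) | (calls["ratio"] < ratio_lo)
    )
    return calls


# ---------------------------------------------------------------------------
# Gene-level aggregation
# ---------------------------------------------------------------------------

def aggregate_to_genes(
    ase_calls: pd.DataFrame,
    min_ase_sites: int = 1,
    min_individuals: int = 1,
) -> pd.DataFrame:
    """Collapse per-site calls to per-(gene, tissue) ASE status.

    A gene is ASE in a tissue iff it holds >= ``min_ase_sites`` distinct
    ASE sites supported by >= ``min_individuals`` distinct individuals.
    Rows without a gene assignment are dropped.
    """
    calls = ase_calls[
        ase_calls["gene_id"].notna() & (ase_calls["gene_id"] != "")
    ].copy()
    if calls.empty:
        return pd.DataFrame(
            columns=[
                "gene_id", "tissue", "n_tested_sites", "n_ase_sites",
                "individuals_supporting", "is_ase_gene",
            ]
        )
    calls["site_key"] = calls["chrom"].astype(str) + ":" + calls["pos"].astype(str)
    rows = []
    for (gene, tissue), sub in calls.groupby(["gene_id", "tissue"], sort=True):
        ase_sub = sub[sub["is_ase"]]
        rows.append(
            {
                "gene_id": gene,
                "tissue": tissue,
                "n_tested_sites": sub["site_key"].nunique(),
                "n_ase_sites": ase_sub["site_key"].nunique(),
                "individuals_supporting": ase_sub["individual"].nunique(),
            }
        )
    genes = pd.DataFrame(rows)
    genes["is_ase_gene"] = (genes["n_ase_sites"] >= min_ase_sites) & (
        genes["individuals_supporting"] >= min_individuals
    )
    return genes


def exclude_imprinted(
    gene_ase: pd.DataFrame, imprinted_list: Iterable[str]
) -> pd.DataFrame:
    """Flag genes on the imprinted list (case-insensitive symbol match)."""
    imprinted = {g.strip().lower() for g in imprinted_list if g.strip()}
    out = gene_ase.copy()
    out["imprint_excluded"] = out["gene_id"].str.lower().isin(imprinted)
    return out


def final_ase_genes(gene_ase: pd.DataFrame) -> pd.DataFrame:
    """ASE genes that survived imprinted-gene exclusion."""
    mask = gene_ase["is_ase_gene"]
    if "imprint_excluded" in gene_ase.columns:
        mask = mask & ~gene_ase["imprint_excluded"]
    return gene_ase[mask]


def tissue_overlap_summary(
    gene_ase: pd.DataFrame,
) -> Tuple[pd.DataFrame, Set[str]]:
    """Per-tissue ASE-gene specificity plus the everywhere-shared set.

    specificity(t) = fraction of tissue t's ASE genes found in no other
    tissue; NaN for tissues without ASE genes. The shared set is the
    intersection across all tissues present in the table.
    """
    final = final_ase_genes(gene_ase)
    tissues = sorted(gene_ase["tissue"].unique())
    sets: Dict[str, Set[str]] = {
        t: set(final[final["tissue"] == t]["gene_id"]) for t in tissues
    }
    rows = []
    for t in tissues:
        others: Set[str] = set().union(*(sets[s] for s in tissues if s != t)) if len(tissues) > 1 else set()
        own = sets[t]
        spec = len(own - others) / len(own) if own else float("nan")
        rows.append({"tissue": t, "n_ase_genes": len(own), "specificity": spec})
    shared = set.intersection(*sets.values()) if sets else set()
    return pd.DataFrame(rows), shared
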