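"""Windowed selective-sweep scan over two parental populations.

Per-site Weir & Cockerham (1984) variance components feed a weighted
window Fst (sum of a over sum of a+b+c, as VCFtools reports); pooled
heterozygosity Hp per population is 2*(sum maj)*(sum min)/(sum maj + sum
min)^2 over the window's per-site major/minor allele counts. Both are
standardized genome-wide (ZFst, ZHp) and the extreme tails are merged
into candidate regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats.gff import GeneModel

CRITERIA = ("high_zfst", "low_zhp_popA", "low_zhp_popB")


@dataclass
class SweepRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    peak_z: float
    criterion: str
    member_windows: List[Tuple[int, int]] = field(default_factory=list)
    genes: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components (two populations, biallelic site)
# ---------------------------------------------------------------------------

def wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
):
    """Vectorized W&C (1984) components a, b, c for two populations.

    ``n`` are genotyped sample counts, ``p`` alt-allele frequencies and
    ``h`` observed heterozygote frequencies. Sites where a population has
    no genotyped individuals, or where the mean sample size is <= 1, get
    NaN in all three components.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        n_total = n1 + n2
        nbar = n_total / 2.0
        nc = n_total - (n1 ** 2 + n2 ** 2) / n_total
        pbar = (n1 * p1 + n2 * p2) / n_total
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / n_total

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    invalid = (n1 < 1) | (n2 < 1) | (nbar <= 1.0) | (nc <= 0)
    a = np.where(invalid, np.nan, a)
    b = np.where(invalid, np.nan, b)
    c = np.where(invalid, np.nan, c)
    return a, b, c


def _pop_summaries(dosages: np.ndarray):
    """Per-site (n, p, h) from a (samples x sites) dosage matrix (-1 missing)."""
    dosages = np.asarray(dosages)
    genotyped = dosages >= 0
    n = genotyped.sum(axis=0).astype(float)
    alt = np.where(genotyped, dosages, 0).sum(axis=0).astype(float)
    het = np.where(genotyped, dosages == 1, False).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def fst_components_matrix(dos_a: np.ndarray, dos_b: np.ndarray):
    """W&C components for every site of two dosage matrices."""
    n1, p1, h1 = _pop_summaries(dos_a)
    n2, p2, h2 = _pop_summaries(dos_b)
    return wc_components(n1, p1, h1, n2, p2, h2)


def site_fst_components(site, pop_labels: Tuple[str, str]):
    """Components (a, b, c) for one VariantSite; None if a population is empty.

    Per-site Fst is a/(a+b+c) when the denominator is nonzero.
    """
    dos_a = np.array(site.dosages(pop_labels[0]))[:, None]
    dos_b = np.array(site.dosages(pop_labels[1]))[:, None]
    if (dos_a >= 0).sum() < 1 or (dos_b >= 0).sum() < 1:
        return None
    a, b, c = fst_components_matrix(dos_a, dos_b)
    if math.isnan(a[0]):
        return None
    return (float(a[0]), float(b[0]), float(c[0]))


def site_fst(site, pop_labels: Tuple[str, str]) -> float:
    comp = site_fst_components(site, pop_labels)
    if comp is None:
        return float("nan")
    a, b, c = comp
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


# ---------------------------------------------------------------------------
# Window statistics
# ---------------------------------------------------------------------------

def window_fst(window_site_components: Sequence[Sequence[Tuple[float, float, float]]]):
    """Weighted window Fst: sum(a) / sum(a+b+c) per window (NaN when empty)."""
    out = []
    for comps in window_site_components:
        num = sum(a for a, _, _ in comps)
        den = sum(a + b + c for a, b, c in comps)
        out.append(num / den if comps and den != 0 else float("nan"))
    return out


def window_hp(window_site_counts: Sequence[Sequence[Tuple[int, int]]]):
    """Pooled heterozygosity 2*Smaj*Smin/(Smaj+Smin)^2 per window."""
    out = []
    for counts in window_site_counts:
        smaj = sum(m for m, _ in counts)
        smin = sum(m for _, m in counts)
        total = smaj + smin
        out.append(2.0 * smaj * smin / total ** 2 if counts and total > 0 else float("nan"))
    return out


def z_transform(values, name: str = "statistic") -> np.ndarray:
    """Standardize to mean 0, sample sd 1 (ddof=1); NaNs pass through.

    Raises ValueError (naming the statistic) when fewer than two finite
    values exist or their spread is zero.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError(f"z-transform of {name}: need >= 2 finite values")
    mean = values[finite].mean()
    sd = values[finite].std(ddof=1)
    if sd == 0:
        raise ValueError(f"z-transform of {name}: zero spread")
    out = np.full_like(values, np.nan)
    out[finite] = (values[finite] - mean) / sd
    return out


def make_windows(chrom_len: int, window: int = 150_000, step: int = 75_000):
    """Windows anchored at multiples of ``step`` from 0, 0-based half-open."""
    starts = range(0, max(chrom_len - window, 0) + 1, step)
    wins = [(s, s + window) for s in starts]
    if not wins:
        wins = [(0, chrom_len)]
    return wins


def _major_minor(dosages: np.ndarray):
    genotyped = dosages >= 0
    n_alt = np.where(genotyped, dosages, 0).sum(axis=0).astype(float)
    n_tot = 2.0 * genotyped.sum(axis=0)
    n_ref = n_tot - n_alt
    return np.maximum(n_ref, n_alt), np.minimum(n_ref, n_alt)


def genome_scan(
    chroms: np.ndarray,
    pos0: np.ndarray,
    dos_a: np.ndarray,
    dos_b: np.ndarray,
    chrom_lens: Dict[str, int],
    window: int = 150_000,
    step: int = 75_000,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Full windowed scan: Fst, Hp per population, and Z-scores.

    ``dos_a``/``dos_b`` are (samples x sites) dosage matrices aligned to
    ``chroms``/``pos0``. Z-scores are computed over windows with at least
    ``min_snps`` SNPs; ineligible windows carry NaN Z-scores.
    """
    chroms = np.asarray(chroms)
    pos0 = np.asarray(pos0)
    a, b, c = fst_components_matrix(dos_a, dos_b)
    abc = a + b + c
    maj_a, min_a = _major_minor(np.asarray(dos_a))
    maj_b, min_b = _major_minor(np.asarray(dos_b))

    rows = []
    for chrom in chrom_lens:
        mask = chroms == chrom
        cpos = pos0[mask]
        order = np.argsort(cpos, kind="mergesort")
        cpos = cpos[order]

        def wsum(values, idx=mask, o=order):
            vals = np.nan_to_num(values[idx][o], nan=0.0)
            cum = np.concatenate([[0.0], np.cumsum(vals)])
            return cum

        cum_a = wsum(a)
        cum_abc = wsum(abc)
        cum_maj_a, cum_min_a = wsum(maj_a), wsum(min_a)
        cum_maj_b, cum_min_b = wsum(maj_b), wsum(min_b)

        for start, end in make_windows(chrom_lens[chrom], window, step):
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, end, side="left")
            n_snps = hi - lo
            num = cum_a[hi] - cum_a[lo]
            den = cum_abc[hi] - cum_abc[lo]
            fst = num / den if n_snps > 0 and den != 0 else float("nan")

            def hp(cmaj, cmin):
                smaj = cmaj[hi] - cmaj[lo]
                smin = cmin[hi] - cmin[lo]
                tot = smaj + smin
                return 2.0 * smaj * smin / tot ** 2 if n_snps > 0 and tot > 0 else float("nan")

            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": int(n_snps),
                    "fst": fst,
                    "hp_popA": hp(cum_maj_a, cum_min_a),
                    "hp_popB": hp(cum_maj_b, cum_min_b),
                }
            )

    stats = pd.DataFrame(rows)
    return add_z_scores(stats, min_snps=min_snps)


def add_z_scores(stats: pd.DataFrame, min_snps: int = 10) -> pd.DataFrame:
    """Attach z_fst / z_hp_popA / z_hp_popB over eligible windows."""
    stats = stats.copy()
    eligible = stats["n_snps"] >= min_snps
    for src, dst in (("fst", "z_fst"), ("hp_popA", "z_hp_popA"), ("hp_popB", "z_hp_popB")):
        vals = stats[src].to_numpy(dtype=float).copy()
        vals[~eligible.to_numpy()] = np.nan
        stats[dst] = z_transform(vals, name=src)
    stats["eligible"] = eligible
    return stats


# ---------------------------------------------------------------------------
# Extreme-window selection, region merging, gene overlap
# ---------------------------------------------------------------------------

def _nearest_rank_count(n: int, frac: float) -> int:
    return max(1, math.ceil(n * frac))


def select_extreme_windows(
    stats: pd.DataFrame,
    statistic: str,
    population: Optional[str] = None,
    top_frac: float = 0.01,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Windows in the extreme ``top_frac`` tail of one scan statistic.

    ``statistic`` is ``z_fst_high`` (upper tail of ZFst) or ``z_hp_low``
    (lower tail of ZHp for ``population`` in {"popA", "popB"}). Threshold
    is the nearest-rank empirical quantile; ties at the threshold are all
    included.
    """
    if statistic == "z_fst_high":
        column, lower_tail = "z_fst", False
    elif statistic == "z_hp_low":
        if population not in ("popA", "popB"):
            raise ValueError("z_hp_low needs population 'popA' or 'popB'")
        column, lower_tail = f"z_hp_{population}", True
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    eligible = stats[(stats["n_snps"] >= min_snps) & stats[column].notna()]
    if eligible.empty:
        warnings.warn(f"no eligible windows for {statistic}", stacklevel=2)
        return eligible
    k = _nearest_rank_count(len(eligible), top_frac)
    vals = np.sort(eligible[column].to_numpy())
    if lower_tail:
        threshold = vals[k - 1]
        return eligible[eligible[column] <= threshold]
    threshold = vals[len(vals) - k]
    return eligible[eligible[column] >= threshold]


def merge_regions(selected: pd.DataFrame, criterion: str) -> List[SweepRegion]:
    """Merge overlapping or bookended selected windows into regions.

    ``peak_z`` is the most extreme member Z (max for high_zfst, min for
    the low-ZHp criteria).
    """
    if criterion == "high_zfst":
        column, pick = "z_fst", max
    elif criterion == "low_zhp_popA":
        column, pick = "z_hp_popA", min
    elif criterion == "low_zhp_popB":
        column, pick = "z_hp_popB", min
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    regions: List[SweepRegion] = []
    ordered = selected.sort_values(["chrom", "start"])
    for _, row in ordered.iterrows():
        if (
            regions
            and regions[-1].chrom == row["chrom"]
            and row["start"] <= regions[-1].end
        ):
            reg = regions[-1]
            reg.end = max(reg.end, int(row["end"]))
            reg.peak_z = pick(reg.peak_z, float(row[column]))
            reg.member_windows.append((int(row["start"]), int(row["end"])))
        else:
            regions.append(
                SweepRegion(
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    peak_z=float(row[column]),
                    criterion=criterion,
                    member_windows=[(int(row["start"]), int(row["end"]))],
                )
            )
    return regions


def genes_in_regions(
    regions: Iterable[SweepRegion], gene_models: Iterable[GeneModel]
) -> List[SweepRegion]:
    """Attach every gene overlapping a region by >= 1 bp (half-open)."""
    genes = list(gene_models)
    for region in regions:
        region.genes = [
            g.gene_id
            for g in genes
            if g.chrom == region.chrom and g.start < region.end and region.start < g.end
        ]
    return list(regions)
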