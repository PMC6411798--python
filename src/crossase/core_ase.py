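"""Core genes: cis-regulated (ASE) AND inside a selective-sweep region.

Evidence from any of the three scan criteria (high ZFst, low ZHp in
either parental population) qualifies a gene. Also houses the ASE-vs-
rest expression comparison and the final report bundle.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import pandas as pd
from scipy.stats import mannwhitneyu

from .ase_detection import final_ase_genes
from .sweep_scan import SweepRegion


@dataclass
class CoreAseGene:
    gene_id: str
    tissues: Set[str]
    sweep_evidence: List[Tuple[str, float, str]] = field(default_factory=list)

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)


def intersect_core_ase(
    gene_ase: pd.DataFrame, regions: Iterable[SweepRegion]
) -> pd.DataFrame:
    """Genes ASE in >= 1 tissue that overlap >= 1 selected sweep region.

    Returns one row per core gene: the tissues with ASE, the tissue
    count, and every (criterion, peak_z, region) pair supporting it.
    """
    final = final_ase_genes(gene_ase)
    evidence: Dict[str, List[Tuple[str, float, str]]] = {}
    for region in regions:
        tag = f"{region.chrom}:{region.start}-{region.end}"
        for gene in region.genes:
            evidence.setdefault(gene, []).append(
                (region.criterion, region.peak_z, tag)
            )
    rows = []
    for gene, sub in final.groupby("gene_id", sort=True):
        if gene not in evidence:
            continue
        tissues = sorted(sub["tissue"].unique())
        rows.append(
            {
                "gene_id": gene,
                "tissues": ",".join(tissues),
                "n_tissues": len(tissues),
                "criteria": ";".join(
                    sorted({crit for crit, _, _ in evidence[gene]})
                ),
                "peak_z": max(abs(z) for _, z, _ in evidence[gene]),
                "regions": ";".join(sorted({tag for _, _, tag in evidence[gene]})),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "tissues", "n_tissues", "criteria", "peak_z", "regions"],
    )


def core_ase_matrix(
    core: pd.DataFrame, tissues: Iterable[str]
) -> pd.DataFrame:
    """Gene x tissue presence/absence matrix of the core genes."""
    tissues = list(tissues)
    rows = []
    for _, row in core.iterrows():
        present = set(row["tissues"].split(","))
        rows.append(
            {"gene_id": row["gene_id"], **{t: int(t in present) for t in tissues}}
        )
    return pd.DataFrame(rows, columns=["gene_id"] + tissues)


def expression_comparison(
    expression: pd.DataFrame,
    ase_gene_set: Iterable[str],
    fpkm_threshold: float = 0.01,
) -> dict:
    """Mean FPKM of ASE vs other genes (one tissue) with a rank-sum p.

    ``expression`` needs columns gene_id and fpkm (replicate rows are
    averaged per gene first). Genes whose mean FPKM is <= the threshold
    are dropped before the comparison. With fewer than two genes in
    either group the means are still reported but p is NaN.
    """
    ase_genes = set(ase_gene_set)
    means = expression.groupby("gene_id", sort=True)["fpkm"].mean()
    expressed = means[means > fpkm_threshold]
    ase_vals = expressed[expressed.index.isin(ase_genes)]
    other_vals = expressed[~expressed.index.isin(ase_genes)]
    result = {
        "n_ase": int(len(ase_vals)),
        "n_other": int(len(other_vals)),
        "mean_ase": float(ase_vals.mean()) if len(ase_vals) else float("nan"),
        "mean_other": float(other_vals.mean()) if len(other_vals) else float("nan"),
        "p_value": float("nan"),
    }
    if len(ase_vals) >= 2 and len(other_vals) >= 2:
        result["p_value"] = float(
            mannwhitneyu(ase_vals, other_vals, alternative="two-sided").pvalue
        )
    return result


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def _write_report_table(df: pd.DataFrame, path: str, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def annotation_summary(
    ase_calls: pd.DataFrame, categories_by_site: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-tissue tallies of ASE-SNP annotation categories and coding changes.

    ``categories_by_site`` maps (chrom, pos) to category/coding_change;
    when absent, sites counted from the calls default to 'exonic'/'none'.
    """
    calls = ase_calls[ase_calls["is_ase"]].copy()
    calls["site_key"] = calls["chrom"].astype(str) + ":" + calls["pos"].astype(str)
    if categories_by_site is not None:
        ann = categories_by_site.copy()
        ann["site_key"] = ann["chrom"].astype(str) + ":" + ann["pos"].astype(str)
        calls = calls.merge(
            ann[["site_key", "category", "coding_change"]], on="site_key", how="left"
        )
        calls["category"] = calls["category"].fillna("intergenic")
        calls["coding_change"] = calls["coding_change"].fillna("none")
    else:
        calls["category"] = "exonic"
        calls["coding_change"] = "none"

    rows = []
    for tissue, sub in calls.groupby("tissue", sort=True):
        uniq = sub.drop_duplicates("site_key")
        entry = {"tissue": tissue, "total": len(uniq)}
        for cat in ("exonic", "intronic", "splice_region", "intergenic",
                    "upstream", "downstream"):
            entry[cat] = int((uniq["category"] == cat).sum())
        for change in ("synonymous", "nonsynonymous", "stopgain", "stoploss"):
            entry[change] = int((uniq["coding_change"] == change).sum())
        rows.append(entry)
    return pd.DataFrame(rows)


def gene_biotype_summary(
    gene_ase: pd.DataFrame, biotypes: Dict[str, str]
) -> pd.DataFrame:
    """Per-tissue tallies of ASE-gene biotypes (post imprint exclusion)."""
    final = final_ase_genes(gene_ase).copy()
    final["biotype"] = final["gene_id"].map(biotypes).fillna("protein_coding")
    rows = []
    for tissue, sub in final.groupby("tissue", sort=True):
        rows.append(
            {
                "tissue": tissue,
                "protein_coding": int((sub["biotype"] == "protein_coding").sum()),
                "noncoding_RNA": int((sub["biotype"] == "noncoding_RNA").sum()),
                "pseudogene": int((sub["biotype"] == "pseudogene").sum()),
                "total": len(sub),
            }
        )
    return pd.DataFrame(rows)


def per_snp_allele_table(ase_calls: pd.DataFrame, gene_id: str) -> pd.DataFrame:
    """Per-SNP, per-individual allele counts for one gene across tissues."""
    sub = ase_calls[ase_calls["gene_id"] == gene_id]
    cols = [
        "chrom", "pos", "ref", "alt", "individual", "tissue",
        "n_line_A", "n_line_B", "ratio", "q_value", "is_ase",
    ]
    return sub[[c for c in cols if c in sub.columns]].sort_values(
        ["pos", "individual", "tissue"]
    ).reset_index(drop=True)


def build_report(
    outdir: str,
    *,
    fingerprint: str,
    seed: int,
    window_stats: pd.DataFrame,
    ase_calls: pd.DataFrame,
    gene_ase: pd.DataFrame,
    core: pd.DataFrame,
    tissues: Iterable[str],
    biotypes: Dict[str, str],
    categories_by_site: Optional[pd.DataFrame] = None,
    expression: Optional[pd.DataFrame] = None,
    focus_gene: Optional[str] = None,
) -> dict:
    """Write the report bundle; returns its manifest (also saved as JSON).

    Tables: annotation_summary, gene_biotype_summary, core_ase_matrix,
    focus-gene per-SNP allele table, and the window scan table. Each file
    opens with a comment carrying the run's config fingerprint and seed.
    Without an expression table the comparison is marked not computed.
    """
    os.makedirs(outdir, exist_ok=True)
    stamp = f"config_fingerprint={fingerprint} seed={seed}"
    tissues = list(tissues)

    tables = {
        "annotation_summary.tsv": annotation_summary(ase_calls, categories_by_site),
        "gene_biotype_summary.tsv": gene_biotype_summary(gene_ase, biotypes),
        "core_ase.tsv": core,
        "core_ase_matrix.tsv": core_ase_matrix(core, tissues),
        "windows.tsv": window_stats,
    }
    if focus_gene is None and not core.empty:
        focus_gene = core.iloc[0]["gene_id"]
    if focus_gene is not None:
        tables["focus_gene_alleles.tsv"] = per_snp_allele_table(ase_calls, focus_gene)

    manifest: dict = {
        "config_fingerprint": fingerprint,
        "seed": seed,
        "tables": {},
    }
    for name, df in tables.items():
        _write_report_table(df, os.path.join(outdir, name), stamp)
        manifest["tables"][name] = len(df)

    if expression is not None:
        rows = []
        ase_by_tissue = {
            t: set(final_ase_genes(gene_ase).query("tissue == @t")["gene_id"])
            for t in tissues
        }
        for tissue in tissues:
            sub = expression[expression["tissue"] == tissue]
            if sub.empty:
                continue
            cmp = expression_comparison(sub, ase_by_tissue[tissue])
            rows.append({"tissue": tissue, **cmp})
        df = pd.DataFrame(rows)
        _write_report_table(df, os.path.join(outdir, "expression_comparison.tsv"), stamp)
        manifest["tables"]["expression_comparison.tsv"] = len(df)
        manifest["expression_comparison"] = "computed"
    else:
        manifest["expression_comparison"] = "not computed"

    with open(os.path.join(outdir, "report_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
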