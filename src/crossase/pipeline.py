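"""End-to-end orchestration: simulate/ingest -> discriminate -> sweep scan
-> ASE calls -> core-gene intersection, in memory or from a dataset
directory on disk."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import POP_A, POP_B
from .ase_detection import (
    aggregate_to_genes,
    call_ase_sites,
    exclude_imprinted,
    filter_counts,
    final_ase_genes,
    pool_replicates,
    relabel_by_line,
)
from .core_ase import build_report, intersect_core_ase
from .discriminating_variants import strict_discriminating_matrix
from .io_formats.gff import GeneModel, read_gene_models
from .io_formats.tables import read_tsv
from .io_formats.vcf import read_vcf
from .sweep_scan import (
    CRITERIA,
    SweepRegion,
    genes_in_regions,
    genome_scan,
    merge_regions,
    select_extreme_windows,
)
from .synthetic_data import (
    SimulationConfig,
    TruthTable,
    informative_site_table,
    make_gene_models,
    simulate_allele_counts,
    simulate_f1,
    simulate_parent_genomes,
)


@dataclass
class AnalysisParams:
    min_qual: float = 30.0
    max_missing_frac: float = 0.0
    window: int = 150_000
    step: int = 75_000
    top_frac: float = 0.01
    min_snps: int = 10
    min_allele_depth: int = 20
    min_total_depth: int = 50
    filter_mode: str = "literal"
    q_threshold: float = 0.05
    ratio_hi: float = 0.7
    ratio_lo: float = 0.3
    fdr_scope: str = "per_tissue"
    pool_scheme: str = "sum"
    min_ase_sites: int = 1
    min_individuals: int = 1


@dataclass
class AnalysisResult:
    window_stats: pd.DataFrame
    selected: Dict[str, pd.DataFrame]
    regions: List[SweepRegion]
    discriminating: pd.DataFrame
    ase_calls: pd.DataFrame
    gene_ase: pd.DataFrame
    core: pd.DataFrame
    counters: Dict[str, int] = field(default_factory=dict)

    def final_ase_gene_ids(self) -> List[str]:
        return sorted(final_ase_genes(self.gene_ase)["gene_id"].unique())

    def sweep_gene_ids(self) -> List[str]:
        return sorted({g for r in self.regions for g in r.genes})

    def core_gene_ids(self) -> List[str]:
        return sorted(self.core["gene_id"]) if not self.core.empty else []


def assign_sites_to_genes(
    chroms: np.ndarray, pos0: np.ndarray, models: List[GeneModel]
) -> np.ndarray:
    """Gene id per site when the site falls in one of the gene's exons,
    else ''. (Synthetic gene models never overlap; with overlapping
    models the first gene in coordinate order wins.)"""
    out = np.full(len(pos0), "", dtype=object)
    for model in models:
        on_chrom = chroms == model.chrom
        for s, e in model.exons:
            hit = on_chrom & (pos0 >= s) & (pos0 < e) & (out == "")
            out[hit] = model.gene_id
    return out


def analyze(
    *,
    chroms: np.ndarray,
    pos0: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    qual: np.ndarray,
    dos_a: np.ndarray,
    dos_b: np.ndarray,
    counts: pd.DataFrame,
    f1_dos: np.ndarray,
    f1_samples: List[str],
    models: List[GeneModel],
    imprinted: List[str],
    chrom_lens: Dict[str, int],
    params: Optional[AnalysisParams] = None,
) -> AnalysisResult:
    """Run the full detection pipeline on array-backed inputs.

    ``counts`` holds observed RNA allele counts (chrom, pos, ref, alt,
    individual, tissue, replicate, n_ref, n_alt, n_other); ``f1_dos`` is
    the (individuals x sites) DNA dosage matrix used as the
    heterozygosity mask that guards against RNA-editing artefacts.
    """
    if params is None:
        params = AnalysisParams()
    counters: Dict[str, int] = {}

    # --- site quality filter ---------------------------------------------
    keep = qual >= params.min_qual
    counters["n_qual_filtered"] = int((~keep).sum())
    chroms, pos0, ref, alt = chroms[keep], pos0[keep], ref[keep], alt[keep]
    dos_a, dos_b, f1_dos = dos_a[:, keep], dos_b[:, keep], f1_dos[:, keep]

    # --- discriminating SNPs ---------------------------------------------
    disc_mask, a_is_alt = strict_discriminating_matrix(
        dos_a, dos_b, max_missing_frac=params.max_missing_frac
    )
    counters["n_discriminating"] = int(disc_mask.sum())
    discriminating = pd.DataFrame(
        {
            "chrom": chroms[disc_mask],
            "pos": pos0[disc_mask] + 1,
            "ref": ref[disc_mask],
            "alt": alt[disc_mask],
            "allele_A_is_alt": a_is_alt[disc_mask],
        }
    )
    discriminating["allele_A"] = np.where(
        discriminating["allele_A_is_alt"], discriminating["alt"], discriminating["ref"]
    )
    discriminating["allele_B"] = np.where(
        discriminating["allele_A_is_alt"], discriminating["ref"], discriminating["alt"]
    )

    # --- sweep scan -------------------------------------------------------
    window_stats = genome_scan(
        chroms, pos0, dos_a, dos_b, chrom_lens,
        window=params.window, step=params.step, min_snps=params.min_snps,
    )
    selected: Dict[str, pd.DataFrame] = {}
    regions: List[SweepRegion] = []
    for criterion in CRITERIA:
        if criterion == "high_zfst":
            sel = select_extreme_windows(
                window_stats, "z_fst_high",
                top_frac=params.top_frac, min_snps=params.min_snps,
            )
        else:
            pop = "popA" if criterion.endswith("popA") else "popB"
            sel = select_extreme_windows(
                window_stats, "z_hp_low", population=pop,
                top_frac=params.top_frac, min_snps=params.min_snps,
            )
        selected[criterion] = sel
        regions.extend(merge_regions(sel, criterion))
    regions = genes_in_regions(regions, models)

    # --- ASE at F1-het discriminating sites -------------------------------
    gene_of_site = assign_sites_to_genes(chroms, pos0, models)
    site_table = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos0 + 1,
            "gene_id": gene_of_site,
            "site_idx": np.arange(len(pos0)),
        }
    )
    obs = counts.merge(
        discriminating[["chrom", "pos", "ref", "alt", "allele_A_is_alt"]],
        on=["chrom", "pos", "ref", "alt"],
        how="inner",
    ).merge(site_table[["chrom", "pos", "gene_id", "site_idx"]], on=["chrom", "pos"], how="left")
    counters["n_count_rows_at_discriminating"] = len(obs)

    # heterozygosity mask from the F1 DNA genotypes
    sample_index = {s: i for i, s in enumerate(f1_samples)}
    ind_idx = obs["individual"].map(sample_index)
    if ind_idx.isna().any():
        raise ValueError("count table names individuals absent from the F1 genotypes")
    het = f1_dos[ind_idx.to_numpy(dtype=int), obs["site_idx"].to_numpy(dtype=int)] == 1
    obs = obs[het].drop(columns="site_idx").reset_index(drop=True)
    counters["n_count_rows_het"] = len(obs)

    obs = relabel_by_line(obs, obs["allele_A_is_alt"])
    pooled = pool_replicates(obs.drop(columns="allele_A_is_alt"), scheme=params.pool_scheme)
    filtered = filter_counts(
        pooled,
        min_allele_depth=params.min_allele_depth,
        min_total_depth=params.min_total_depth,
        mode=params.filter_mode,
    )
    counters["n_sites_tested"] = len(filtered)
    if len(filtered):
        calls = call_ase_sites(
            filtered,
            q_threshold=params.q_threshold,
            ratio_hi=params.ratio_hi,
            ratio_lo=params.ratio_lo,
            fdr_scope=params.fdr_scope,
        )
    else:
        calls = filtered.assign(ratio=[], p_value=[], q_value=[], is_ase=[])
    gene_ase = aggregate_to_genes(
        calls, min_ase_sites=params.min_ase_sites, min_individuals=params.min_individuals
    )
    gene_ase = exclude_imprinted(gene_ase, imprinted)
    core = intersect_core_ase(gene_ase, regions)

    return AnalysisResult(
        window_stats=window_stats,
        selected=selected,
        regions=regions,
        discriminating=discriminating,
        ase_calls=calls,
        gene_ase=gene_ase,
        core=core,
        counters=counters,
    )


# ---------------------------------------------------------------------------
# In-memory synthetic run
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    config: SimulationConfig
    parents: object
    f1: object
    models: List[GeneModel]
    truth: TruthTable
    counts: pd.DataFrame


def simulate_bundle(config: SimulationConfig) -> SimBundle:
    parents, truth = simulate_parent_genomes(config)
    f1 = simulate_f1(parents, config)
    models, gene_truth = make_gene_models(config)
    truth.genes = gene_truth
    het = informative_site_table(parents, f1, models, gene_truth, config)
    counts = simulate_allele_counts(het, config)
    return SimBundle(config, parents, f1, models, truth, counts)


def run_simulation(
    config: SimulationConfig, params: Optional[AnalysisParams] = None
) -> Tuple[SimBundle, AnalysisResult]:
    """Simulate a dataset and push it through the full pipeline in memory."""
    if params is None:
        params = AnalysisParams(window=config.window_size, step=config.step)
    bundle = simulate_bundle(config)
    observed = bundle.counts[
        ["chrom", "pos", "ref", "alt", "individual", "tissue", "replicate",
         "n_ref", "n_alt", "n_other"]
    ].copy()
    result = analyze(
        chroms=bundle.parents.chroms,
        pos0=bundle.parents.pos0,
        ref=bundle.parents.ref,
        alt=bundle.parents.alt,
        qual=bundle.parents.qual,
        dos_a=bundle.parents.dos_a,
        dos_b=bundle.parents.dos_b,
        counts=observed,
        f1_dos=bundle.f1.dos,
        f1_samples=config.sample_names["F1"],
        models=bundle.models,
        imprinted=sorted(config.imprinted_genes),
        chrom_lens=config.chrom_lens,
        params=params,
    )
    return bundle, result


# ---------------------------------------------------------------------------
# Truth-based evaluation
# ---------------------------------------------------------------------------

def sweep_recovery(result: AnalysisResult, truth: TruthTable) -> Dict[str, bool]:
    """Did every planted sweep window pass both screens (ZFst high, ZHp
    low in the swept population)?"""
    planted = truth.windows[truth.windows["is_sweep"]]
    ok_fst = True
    ok_hp = True
    fst_set = {
        (r["chrom"], r["start"], r["end"])
        for _, r in result.selected["high_zfst"].iterrows()
    }
    hp_sets = {
        POP_A: {
            (r["chrom"], r["start"], r["end"])
            for _, r in result.selected["low_zhp_popA"].iterrows()
        },
        POP_B: {
            (r["chrom"], r["start"], r["end"])
            for _, r in result.selected["low_zhp_popB"].iterrows()
        },
    }
    for _, row in planted.iterrows():
        key = (row["chrom"], row["start"], row["end"])
        if key not in fst_set:
            ok_fst = False
        if key not in hp_sets[row["target"]]:
            ok_hp = False
    return {"all_fst": ok_fst, "all_hp": ok_hp, "n_planted": len(planted)}


def core_metrics(result: AnalysisResult, truth: TruthTable) -> Dict[str, float]:
    """Precision/recall of the detected core set against planted truth."""
    predicted = set(result.core_gene_ids())
    true_core = set(truth.true_core_genes())
    tp = len(predicted & true_core)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(true_core) if true_core else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "n_predicted": len(predicted),
        "n_true": len(true_core),
    }


# ---------------------------------------------------------------------------
# File-based run
# ---------------------------------------------------------------------------

def _vcf_to_arrays(path: str, population_map: Dict[str, str], pops: List[str]):
    sites = list(read_vcf(path, population_map))
    chroms = np.array([s.chrom for s in sites], dtype=object)
    pos0 = np.array([s.pos0 for s in sites], dtype=int)
    ref = np.array([s.ref for s in sites], dtype=object)
    alt = np.array([s.alt for s in sites], dtype=object)
    qual = np.array([s.qual for s in sites], dtype=float)
    matrices = {}
    sample_lists = {}
    for pop in pops:
        samples = [s for s, p in population_map.items() if p == pop]
        mat = np.full((len(samples), len(sites)), -1, dtype=np.int8)
        for j, site in enumerate(sites):
            for i, sample in enumerate(samples):
                gt = site.genotypes.get(sample)
                if gt is not None:
                    mat[i, j] = gt[0] + gt[1]
        matrices[pop] = mat
        sample_lists[pop] = samples
    return chroms, pos0, ref, alt, qual, matrices, sample_lists


def run_dataset_dir(
    dataset_dir: str,
    outdir: Optional[str] = None,
    params: Optional[AnalysisParams] = None,
    fingerprint: str = "unknown",
    seed: int = -1,
) -> AnalysisResult:
    """Run the pipeline on a dataset directory written by write_dataset."""
    import pysam  # noqa: F401  (pulled in transitively; keeps import errors early)

    parents_vcf = os.path.join(dataset_dir, "parents.vcf")
    f1_vcf = os.path.join(dataset_dir, "f1.vcf")
    cfg_path = os.path.join(dataset_dir, "config.json")
    config = SimulationConfig.from_json(cfg_path) if os.path.exists(cfg_path) else None
    if params is None:
        params = (
            AnalysisParams(window=config.window_size, step=config.step)
            if config
            else AnalysisParams()
        )

    sample_names = (
        config.sample_names
        if config
        else None
    )
    if sample_names is None:
        raise ValueError("dataset directory lacks config.json; cannot infer samples")
    pmap = {s: POP_A for s in sample_names[POP_A]}
    pmap.update({s: POP_B for s in sample_names[POP_B]})
    chroms, pos0, ref, alt, qual, mats, _ = _vcf_to_arrays(parents_vcf, pmap, [POP_A, POP_B])

    f1_map = {s: "F1" for s in sample_names["F1"]}
    f_chroms, f_pos0, _, _, _, f_mats, f_samples = _vcf_to_arrays(f1_vcf, f1_map, ["F1"])
    if not (np.array_equal(f_chroms, chroms) and np.array_equal(f_pos0, pos0)):
        raise ValueError("parents.vcf and f1.vcf describe different sites")

    models = read_gene_models(os.path.join(dataset_dir, "genes.gff3"))
    with open(os.path.join(dataset_dir, "imprinted.txt")) as fh:
        imprinted = [line.strip() for line in fh if line.strip()]

    counts_dir = os.path.join(dataset_dir, "counts")
    frames = [
        read_tsv(os.path.join(counts_dir, name))
        for name in sorted(os.listdir(counts_dir))
        if name.endswith(".tsv")
    ]
    counts = pd.concat(frames, ignore_index=True)

    chrom_lens = (
        config.chrom_lens
        if config
        else {c: int(pos0[chroms == c].max()) + 1 for c in np.unique(chroms)}
    )
    result = analyze(
        chroms=chroms, pos0=pos0, ref=ref, alt=alt, qual=qual,
        dos_a=mats[POP_A], dos_b=mats[POP_B],
        counts=counts,
        f1_dos=f_mats["F1"], f1_samples=f_samples["F1"],
        models=models, imprinted=imprinted, chrom_lens=chrom_lens,
        params=params,
    )

    if outdir is not None:
        fpkm_path = os.path.join(dataset_dir, "fpkm.tsv")
        expression = read_tsv(fpkm_path) if os.path.exists(fpkm_path) else None
        if config is not None:
            fingerprint, seed = config.fingerprint(), config.seed
        build_report(
            outdir,
            fingerprint=fingerprint,
            seed=seed,
            window_stats=result.window_stats,
            ase_calls=result.ase_calls,
            gene_ase=result.gene_ase,
            core=result.core,
            tissues=config.tissues if config else sorted(counts["tissue"].unique()),
            biotypes={m.gene_id: m.biotype for m in models},
            expression=expression,
        )
        from .io_formats.tables import write_tsv

        write_tsv(result.discriminating, os.path.join(outdir, "discriminating_snps.tsv"))
        write_tsv(result.ase_calls, os.path.join(outdir, "ase_sites.tsv"))
        write_tsv(result.gene_ase, os.path.join(outdir, "ase_genes.tsv"))
        region_rows = [
            (r.chrom, r.start, r.end, r.criterion, f"{r.peak_z:.6g}", ",".join(r.genes))
            for r in result.regions
        ]
        from .io_formats.tables import write_bed

        write_bed(region_rows, os.path.join(outdir, "regions.bed"))
    return result
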