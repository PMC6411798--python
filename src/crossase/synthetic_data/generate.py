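"""Truth-labelled synthetic dataset generator.

Every output is a pure function of the :class:`SimulationConfig`
(including its seed); independent RNG streams per stage keep stages
reproducible regardless of which subset is generated.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .. import POP_A, POP_B
from ..io_formats.gff import GeneModel, write_gff3
from ..io_formats.sam import AlignedRead, write_sam
from ..io_formats.tables import write_tsv
from ..io_formats.vcf import VariantSite, write_vcf
from ..sweep_scan import make_windows
from .config import SimulationConfig, TruthTable

_BASES = np.array(list("ACGT"))

# rng stream ids per stage
_STREAM_PARENTS = 0
_STREAM_F1 = 1
_STREAM_COUNTS = 3
_STREAM_FPKM = 4
_STREAM_READS = 5

GENE_LENGTH = 24_000
_EXON_TEMPLATE = ((0, 6_000), (9_000, 15_000), (18_000, 24_000))
_CDS_TEMPLATE = ((102, 6_000, 0), (9_000, 15_000, 0), (18_000, 23_898, 0))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Parental genomes
# ---------------------------------------------------------------------------

@dataclass
class ParentGenomes:
    config: SimulationConfig
    chroms: np.ndarray  # per-site chromosome name
    pos0: np.ndarray  # 0-based positions
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    freq_a: np.ndarray  # true alt-allele frequency, line A
    freq_b: np.ndarray
    dos_a: np.ndarray  # (n_parents_A x n_sites) alt dosages
    dos_b: np.ndarray
    sweep_target: np.ndarray  # '' or population label per site

    @property
    def n_sites(self) -> int:
        return self.pos0.size

    @property
    def pos(self) -> np.ndarray:
        return self.pos0 + 1


@dataclass
class F1Genotypes:
    dos: np.ndarray  # (n_f1 x n_sites)
    allele_from_A: np.ndarray  # allele value (0/1) transmitted by the line-A parent
    allele_from_B: np.ndarray


def _site_positions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    per = config.sites_per_chrom
    spacing = config.site_spacing
    base = np.arange(per) * spacing
    jitter = spacing // 4 + rng.integers(0, max(spacing // 2, 1), size=per)
    return base + jitter


def simulate_parent_genomes(
    config: SimulationConfig,
) -> Tuple[ParentGenomes, TruthTable]:
    """Draw per-population allele frequencies and parental genotypes.

    Neutral sites take each population's alt frequency from Beta(0.5,
    0.5) independently; inside a planted sweep window the target
    population draws from Beta(40, 1) and the other from Beta(1, 40).
    Diploid genotypes are binomial in the population frequency.
    """
    rng = _rng(config, _STREAM_PARENTS)
    chrom_list: List[np.ndarray] = []
    pos_list: List[np.ndarray] = []
    for name in config.chrom_names:
        p = _site_positions(config, rng)
        chrom_list.append(np.full(p.size, name, dtype=object))
        pos_list.append(p)
    chroms = np.concatenate(chrom_list)
    pos0 = np.concatenate(pos_list)
    n = pos0.size

    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]
    qual = rng.uniform(*config.qual_range, size=n)

    freq_a = rng.beta(0.5, 0.5, size=n)
    freq_b = rng.beta(0.5, 0.5, size=n)
    sweep_target = np.full(n, "", dtype=object)
    for chrom, start, end, target in config.sweep_windows:
        mask = (chroms == chrom) & (pos0 >= start) & (pos0 < end)
        k = int(mask.sum())
        high = rng.beta(40, 1, size=k)
        low = rng.beta(1, 40, size=k)
        if target == POP_A:
            freq_a[mask], freq_b[mask] = high, low
        else:
            freq_b[mask], freq_a[mask] = high, low
        sweep_target[mask] = target

    dos_a = rng.binomial(2, freq_a, size=(config.n_parents_A, n))
    dos_b = rng.binomial(2, freq_b, size=(config.n_parents_B, n))

    parents = ParentGenomes(
        config=config,
        chroms=chroms,
        pos0=pos0,
        ref=ref,
        alt=alt,
        qual=qual,
        freq_a=freq_a,
        freq_b=freq_b,
        dos_a=dos_a,
        dos_b=dos_b,
        sweep_target=sweep_target,
    )

    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos0 + 1,
            "ref": ref,
            "alt": alt,
            "freq_A": freq_a,
            "freq_B": freq_b,
            "in_sweep": sweep_target != "",
            "sweep_target": sweep_target,
        }
    )
    win_rows = []
    for name in config.chrom_names:
        for start, end in make_windows(config.chrom_len, config.window_size, config.step):
            planted = [
                w for w in config.sweep_windows
                if w[0] == name and w[1] <= start and end <= w[2]
            ]
            win_rows.append(
                {
                    "chrom": name,
                    "start": start,
                    "end": end,
                    "is_sweep": bool(planted),
                    "target": planted[0][3] if planted else "",
                }
            )
    truth = TruthTable(sites=sites, windows=pd.DataFrame(win_rows))
    return parents, truth


def simulate_f1(parents: ParentGenomes, config: SimulationConfig) -> F1Genotypes:
    """Mendelian F1 genotypes: one allele from a line-A parent, one from
    a line-B parent (parents assigned round-robin, transmitted allele
    drawn per site)."""
    rng = _rng(config, _STREAM_F1)
    n = parents.n_sites
    from_a = np.empty((config.n_f1, n), dtype=np.int8)
    from_b = np.empty((config.n_f1, n), dtype=np.int8)
    for i in range(config.n_f1):
        pa = i % config.n_parents_A
        pb = i % config.n_parents_B
        from_a[i] = rng.binomial(1, parents.dos_a[pa] / 2.0)
        from_b[i] = rng.binomial(1, parents.dos_b[pb] / 2.0)
    return F1Genotypes(dos=from_a + from_b, allele_from_A=from_a, allele_from_B=from_b)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def make_gene_models(
    config: SimulationConfig,
) -> Tuple[List[GeneModel], pd.DataFrame]:
    """Deterministically placed, non-overlapping gene models.

    Three genes are laid inside every planted sweep window; the rest are
    spread along the chromosomes, keeping a 300 kb buffer around sweep
    windows so neutral genes never touch a selected region.
    """
    placements: List[Tuple[str, int]] = []
    per_chrom = {
        name: config.n_genes // config.n_chrom
        + (1 if i < config.n_genes % config.n_chrom else 0)
        for i, name in enumerate(config.chrom_names)
    }
    sweep_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end, _ in config.sweep_windows:
        sweep_by_chrom.setdefault(chrom, []).append((start, end))

    for chrom in config.chrom_names:
        wanted = per_chrom[chrom]
        chosen: List[int] = []
        for start, end in sweep_by_chrom.get(chrom, []):
            for s in range(start + 10_000, end - GENE_LENGTH + 1, 50_000):
                if len(chosen) < wanted:
                    chosen.append(s)
        buffer = 300_000
        lo, hi = 200_000, config.chrom_len - 100_000 - GENE_LENGTH
        remaining = wanted - len(chosen)
        pitch = max(
            GENE_LENGTH + 10_000,
            min(450_000, (hi - lo) // max(remaining, 1)) if hi > lo else 0,
        )
        slot = lo
        while len(chosen) < wanted:
            if slot > hi:
                raise ValueError(f"cannot place {wanted} genes on {chrom}")
            near_sweep = any(
                slot < e + buffer and s - buffer < slot + GENE_LENGTH
                for s, e in sweep_by_chrom.get(chrom, [])
            )
            if not near_sweep and all(
                abs(slot - c) >= GENE_LENGTH + 10_000 for c in chosen
            ):
                chosen.append(slot)
            slot += pitch
        placements.extend((chrom, s) for s in sorted(chosen))

    models: List[GeneModel] = []
    rows = []
    neutral_seen = 0
    for k, (chrom, start) in enumerate(placements):
        gene_id = f"gene_{k + 1:04d}"
        strand = "+" if k % 2 == 0 else "-"
        in_sweep = any(
            s < start + GENE_LENGTH and start < e
            for s, e in sweep_by_chrom.get(chrom, [])
        )
        biotype = "protein_coding"
        if not in_sweep:
            neutral_seen += 1
            if neutral_seen % 9 == 0:
                biotype = "noncoding_RNA"
            elif neutral_seen % 13 == 0:
                biotype = "pseudogene"
        exons = [(start + s, start + e) for s, e in _EXON_TEMPLATE]
        cds = (
            [(start + s, start + e, f) for s, e, f in _CDS_TEMPLATE]
            if biotype == "protein_coding"
            else []
        )
        model = GeneModel(
            gene_id=gene_id, biotype=biotype, chrom=chrom, strand=strand,
            exons=exons, cds=cds,
        )
        models.append(model)
        if gene_id in config.ase_genes:
            status, theta = "ase", config.ase_genes[gene_id]
        elif gene_id in config.imprinted_genes:
            status, theta = "imprinted", config.imprinted_genes[gene_id]
        else:
            status, theta = "neutral", 0.5
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "start": start,
                "end": start + GENE_LENGTH,
                "biotype": biotype,
                "status": status,
                "theta": theta,
                "in_sweep": in_sweep,
            }
        )
    return models, pd.DataFrame(rows)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Ready-to-run configuration with planted sweeps, ASE and imprinting.

    Two sweep windows (one per parental line) sit on the window grid;
    inside each, two genes carry cis imbalance (theta 0.85 and 0.2) and
    one is imprinted or neutral. A few genes away from any sweep are also
    given imbalance, and one far gene is imprinted near-monoallelically.
    """
    base = SimulationConfig(seed=seed, **overrides)
    if not base.sweep_windows and "sweep_windows" not in overrides:
        sweeps = []
        w, s = base.window_size, base.step
        anchors = [(name, (i + 1) * 50) for i, name in enumerate(base.chrom_names[:2])]
        for name, steps in anchors:
            start = steps * s
            if start + w <= base.chrom_len:
                sweeps.append((name, start, start + w, POP_A if len(sweeps) % 2 == 0 else POP_B))
        base = SimulationConfig(seed=seed, **{**overrides, "sweep_windows": sweeps})

    _, gene_truth = make_gene_models(base)
    ase: Dict[str, float] = {}
    imprinted: Dict[str, float] = {}
    sweep_ids = list(gene_truth[gene_truth["in_sweep"]]["gene_id"])
    neutral_ids = list(gene_truth[~gene_truth["in_sweep"]]["gene_id"])
    for w_idx in range(len(base.sweep_windows)):
        block = sweep_ids[w_idx * 3 : w_idx * 3 + 3]
        if len(block) > 0:
            ase[block[0]] = 0.85
        if len(block) > 1:
            ase[block[1]] = 0.2
        if len(block) > 2 and w_idx == 0:
            imprinted[block[2]] = 0.98
    coding_neutral = list(
        gene_truth[~gene_truth["in_sweep"] & (gene_truth["biotype"] == "protein_coding")][
            "gene_id"
        ]
    )
    if len(coding_neutral) >= 2:
        ase[coding_neutral[0]] = 0.8
        ase[coding_neutral[1]] = 0.65
    if len(coding_neutral) >= 3:
        imprinted[coding_neutral[2]] = 0.02
    del neutral_ids
    return SimulationConfig(
        seed=seed,
        **{**overrides, "sweep_windows": base.sweep_windows,
           "ase_genes": ase, "imprinted_genes": imprinted},
    )


# ---------------------------------------------------------------------------
# RNA allele counts
# ---------------------------------------------------------------------------

def informative_site_table(
    parents: ParentGenomes,
    f1: F1Genotypes,
    models: List[GeneModel],
    gene_truth: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """One row per (exonic site x F1 individual heterozygous there).

    These are the site/individual pairs at which RNA reads can reveal
    allelic imbalance; ``a_is_alt`` records which allele the line-A
    parent transmitted to that individual.
    """
    theta_by_gene = dict(zip(gene_truth["gene_id"], gene_truth["theta"]))
    site_gene = np.full(parents.n_sites, "", dtype=object)
    for model in models:
        on_chrom = parents.chroms == model.chrom
        for s, e in model.exons:
            inside = on_chrom & (parents.pos0 >= s) & (parents.pos0 < e)
            site_gene[inside] = model.gene_id
    informative = site_gene != ""

    frames = []
    individuals = config.sample_names["F1"]
    for i, name in enumerate(individuals):
        het = (f1.dos[i] == 1) & informative
        idx = np.flatnonzero(het)
        if idx.size == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "chrom": parents.chroms[idx],
                    "pos": parents.pos0[idx] + 1,
                    "ref": parents.ref[idx],
                    "alt": parents.alt[idx],
                    "gene_id": site_gene[idx],
                    "theta": [theta_by_gene[g] for g in site_gene[idx]],
                    "individual": name,
                    "a_is_alt": f1.allele_from_A[i, idx] == 1,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "gene_id", "theta", "individual", "a_is_alt"]
        )
    return pd.concat(frames, ignore_index=True)


def simulate_allele_counts(
    het_sites: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Beta-binomial allele counts per (site, individual, tissue, replicate).

    Total depth is Poisson(``depth_mean``); the line-A read count is
    Binomial(depth, q) with q = theta exactly when ``overdispersion`` is
    0, else q ~ Beta with mean theta and intra-class correlation
    ``overdispersion``. Only heterozygous (site, individual) rows may be
    passed in -- counts exist for no other pairs by contract.
    """
    if rng is None:
        rng = _rng(config, _STREAM_COUNTS)
    theta = het_sites["theta"].to_numpy(dtype=float)
    if np.any((theta <= 0) | (theta >= 1)):
        raise ValueError("theta must be in (0, 1)")

    n_base = len(het_sites)
    combos = [
        (t, r)
        for t in config.tissues
        for r in range(1, config.replicates_per_tissue + 1)
    ]
    reps = len(combos)
    base = het_sites.reset_index(drop=True)
    expanded = base.loc[np.repeat(np.arange(n_base), reps)].reset_index(drop=True)
    expanded["tissue"] = [t for _ in range(n_base) for t, _ in combos]
    expanded["replicate"] = [r for _ in range(n_base) for _, r in combos]

    m = len(expanded)
    depth = rng.poisson(config.depth_mean, size=m)
    theta_row = expanded["theta"].to_numpy(dtype=float)
    rho = config.overdispersion
    if rho > 0:
        scale = (1.0 - rho) / rho
        q = rng.beta(theta_row * scale, (1.0 - theta_row) * scale)
    else:
        q = theta_row
    n_line_a = rng.binomial(depth, q)
    n_line_b = depth - n_line_a

    a_is_alt = expanded["a_is_alt"].to_numpy(dtype=bool)
    expanded["n_ref"] = np.where(a_is_alt, n_line_b, n_line_a)
    expanded["n_alt"] = np.where(a_is_alt, n_line_a, n_line_b)
    expanded["n_other"] = 0
    expanded["true_n_line_A"] = n_line_a
    expanded["true_n_line_B"] = n_line_b
    return expanded


def simulate_fpkm(
    gene_truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Log-normal FPKM per (gene, individual, tissue); imbalanced genes
    are shifted up so the ASE-vs-rest expression contrast is real, and
    every seventh neutral gene is near-silent (below usual thresholds)."""
    rng = _rng(config, _STREAM_FPKM)
    genes = gene_truth["gene_id"].to_numpy()
    status = gene_truth["status"].to_numpy()
    individuals = config.sample_names["F1"]
    rows = []
    silent = {g for i, g in enumerate(genes) if status[i] == "neutral" and (i % 7) == 6}
    for tissue in config.tissues:
        for ind in individuals:
            fpkm = rng.lognormal(mean=1.0, sigma=1.0, size=genes.size)
            fpkm = np.where(status == "ase", fpkm * 4.0, fpkm)
            fpkm = np.array(
                [f * 1e-3 if g in silent else f for g, f in zip(genes, fpkm)]
            )
            rows.append(
                pd.DataFrame(
                    {"gene_id": genes, "individual": ind, "tissue": tissue, "fpkm": fpkm}
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Optional SAM realisation of the counts
# ---------------------------------------------------------------------------

def make_reference(
    config: SimulationConfig, parents: ParentGenomes
) -> Dict[str, str]:
    """Random reference sequence agreeing with every site's ref allele."""
    rng = _rng(config, _STREAM_READS)
    ref = {}
    for name in config.chrom_names:
        seq = rng.integers(0, 4, size=config.chrom_len)
        mask = parents.chroms == name
        base_idx = np.searchsorted(_BASES, parents.ref[mask])
        seq[parents.pos0[mask]] = base_idx
        ref[name] = "".join(_BASES[seq])
    return ref


def counts_to_reads(
    counts: pd.DataFrame,
    reference: Dict[str, str],
    config: SimulationConfig,
) -> Iterator[AlignedRead]:
    """Reads (CIGAR 100M, MAPQ 60, base quality 30) realizing the counts.

    Each read covers exactly one simulated site, centred when possible.
    """
    length = config.read_length
    serial = 0
    jobs = []
    for row in counts.itertuples(index=False):
        pos0 = row.pos - 1
        start = min(max(pos0 - length // 2, 0), len(reference[row.chrom]) - length)
        for base, n in ((row.ref, row.n_ref), (row.alt, row.n_alt)):
            for _ in range(int(n)):
                jobs.append((row.chrom, start, pos0, base))
    jobs.sort(key=lambda j: (j[0], j[1]))
    for chrom, start, pos0, base in jobs:
        serial += 1
        seq = reference[chrom][start : start + length]
        offset = pos0 - start
        seq = seq[:offset] + base + seq[offset + 1 :]
        yield AlignedRead(
            qname=f"r{serial:07d}",
            flag=0,
            chrom=chrom,
            pos=start + 1,
            mapq=60,
            cigar=f"{length}M",
            seq=seq,
            quals=[30] * length,
        )


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------

def _dosage_to_gt(d: int):
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}.get(int(d))


def _variant_sites(parents: ParentGenomes, matrices, populations) -> Iterator[VariantSite]:
    names = list(populations)
    for j in range(parents.n_sites):
        genotypes = {}
        for (sample_names, dos) in matrices:
            for s_idx, sample in enumerate(sample_names):
                genotypes[sample] = _dosage_to_gt(dos[s_idx, j])
        yield VariantSite(
            chrom=str(parents.chroms[j]),
            pos=int(parents.pos0[j] + 1),
            ref=str(parents.ref[j]),
            alt=str(parents.alt[j]),
            qual=float(parents.qual[j]),
            genotypes=genotypes,
            populations=dict(populations),
        )
    del names


def parent_variant_sites(parents: ParentGenomes) -> Iterator[VariantSite]:
    cfg = parents.config
    samples = cfg.sample_names
    pops = {s: POP_A for s in samples[POP_A]}
    pops.update({s: POP_B for s in samples[POP_B]})
    return _variant_sites(
        parents,
        [(samples[POP_A], parents.dos_a), (samples[POP_B], parents.dos_b)],
        pops,
    )


def f1_variant_sites(parents: ParentGenomes, f1: F1Genotypes) -> Iterator[VariantSite]:
    cfg = parents.config
    samples = cfg.sample_names["F1"]
    pops = {s: "F1" for s in samples}
    return _variant_sites(parents, [(samples, f1.dos)], pops)


COUNT_FILE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "individual", "tissue", "replicate",
    "n_ref", "n_alt", "n_other",
]


def write_dataset(config: SimulationConfig, outdir: str) -> dict:
    """Generate and write the full dataset; returns the manifest.

    Artifact classes: parents.vcf, f1.vcf, per-tissue counts TSV (or SAM
    files plus reference.fa when ``emit_sam``), genes.gff3,
    imprinted.txt, fpkm.tsv and truth/*.tsv. The manifest maps every
    file to its row count and is also written as manifest.json.
    """
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)

    parents, truth = simulate_parent_genomes(config)
    f1 = simulate_f1(parents, config)
    models, gene_truth = make_gene_models(config)
    truth.genes = gene_truth
    het = informative_site_table(parents, f1, models, gene_truth, config)
    counts = simulate_allele_counts(het, config)
    fpkm = simulate_fpkm(gene_truth, config)

    files: Dict[str, int] = {}
    files["parents.vcf"] = write_vcf(
        parent_variant_sites(parents), os.path.join(outdir, "parents.vcf"),
        contigs=config.chrom_lens,
    )
    files["f1.vcf"] = write_vcf(
        f1_variant_sites(parents, f1), os.path.join(outdir, "f1.vcf"),
        contigs=config.chrom_lens,
    )
    files["genes.gff3"] = write_gff3(models, os.path.join(outdir, "genes.gff3"))

    with open(os.path.join(outdir, "imprinted.txt"), "w") as fh:
        for g in sorted(config.imprinted_genes):
            fh.write(g + "\n")
    files["imprinted.txt"] = len(config.imprinted_genes)

    if config.emit_sam:
        reference = make_reference(config, parents)
        with open(os.path.join(outdir, "reference.fa"), "w") as fh:
            for name, seq in reference.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        files["reference.fa"] = len(reference)
        os.makedirs(os.path.join(outdir, "sam"), exist_ok=True)
        group_cols = ["individual", "tissue", "replicate"]
        for (ind, tissue, rep), sub in counts.groupby(group_cols, sort=True):
            rel = f"sam/{ind}_{tissue}_rep{rep}.sam"
            n = write_sam(
                counts_to_reads(sub, reference, config),
                os.path.join(outdir, rel),
                references=config.chrom_lens,
            )
            files[rel] = n
    else:
        os.makedirs(os.path.join(outdir, "counts"), exist_ok=True)
        for tissue in config.tissues:
            sub = counts[counts["tissue"] == tissue]
            rel = f"counts/{tissue}.tsv"
            write_tsv(
                sub[COUNT_FILE_COLUMNS].sort_values(
                    ["chrom", "pos", "individual", "replicate"]
                ),
                os.path.join(outdir, rel),
            )
            files[rel] = len(sub)

    write_tsv(fpkm, os.path.join(outdir, "fpkm.tsv"))
    files["fpkm.tsv"] = len(fpkm)
    write_tsv(truth.sites, os.path.join(outdir, "truth", "sites.tsv"))
    files["truth/sites.tsv"] = len(truth.sites)
    write_tsv(truth.windows, os.path.join(outdir, "truth", "windows.tsv"))
    files["truth/windows.tsv"] = len(truth.windows)
    write_tsv(gene_truth, os.path.join(outdir, "truth", "genes.tsv"))
    files["truth/genes.tsv"] = len(gene_truth)
    write_tsv(
        counts.drop(columns=["theta", "a_is_alt"]),
        os.path.join(outdir, "truth", "counts.tsv"),
    )
    files["truth/counts.tsv"] = len(counts)

    config.to_json(os.path.join(outdir, "config.json"))
    files["config.json"] = 1

    manifest = {
        "seed": config.seed,
        "config_fingerprint": config.fingerprint(),
        "files": dict(sorted(files.items())),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
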