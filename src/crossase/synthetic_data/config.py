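"""Simulation configuration and truth bookkeeping.

All generator distributions are artifact choices (the study the design
emulates gives no distributional description of its data): neutral
population allele frequencies are Beta(0.5, 0.5) per population; inside
a planted sweep window the target population draws its alt frequency
from Beta(40, 1) (near fixation, low heterozygosity) and the other from
Beta(1, 40) (high differentiation). RNA depth is Poisson; allele counts
are beta-binomial with intra-class correlation ``overdispersion``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .. import POP_A, POP_B

DEFAULT_TISSUES = ("liver", "bone", "muscle", "fat", "skin", "mammary")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 15_300_000
    n_parents_A: int = 6
    n_parents_B: int = 4
    n_f1: int = 9
    n_sites: int = 30_600
    sweep_windows: List[Tuple[str, int, int, str]] = field(default_factory=list)
    n_genes: int = 60
    ase_genes: Dict[str, float] = field(default_factory=dict)  # gene_id -> theta
    imprinted_genes: Dict[str, float] = field(default_factory=dict)
    depth_mean: float = 100.0
    overdispersion: float = 0.01
    tissues: Tuple[str, ...] = DEFAULT_TISSUES
    replicates_per_tissue: int = 2
    window_size: int = 150_000
    step: int = 75_000
    emit_sam: bool = False
    read_length: int = 100
    qual_range: Tuple[float, float] = (10.0, 1000.0)

    def __post_init__(self):
        self.sweep_windows = [tuple(w) for w in self.sweep_windows]
        self.tissues = tuple(self.tissues)
        self.qual_range = tuple(self.qual_range)
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for name in (
            "n_chrom", "chrom_len", "n_parents_A", "n_parents_B", "n_f1",
            "n_sites", "n_genes", "replicates_per_tissue", "window_size", "step",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.tissues:
            raise ValueError("need at least one tissue")
        if self.n_sites < self.n_chrom:
            raise ValueError("need at least one site per chromosome")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion must be in [0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        for gene, theta in {**self.ase_genes, **self.imprinted_genes}.items():
            if not 0.0 < theta < 1.0:
                raise ValueError(f"theta for {gene} must be in (0, 1), got {theta}")
        names = set(self.chrom_names)
        for chrom, start, end, target in self.sweep_windows:
            if chrom not in names:
                raise ValueError(f"sweep window on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chrom_len):
                raise ValueError(f"sweep window [{start}, {end}) outside chromosome")
            if target not in (POP_A, POP_B):
                raise ValueError(f"sweep target must be {POP_A} or {POP_B}")
        # jittered placement guarantees gaps of at least site_spacing/2
        if self.emit_sam and self.site_spacing <= 2 * self.read_length:
            raise ValueError("SAM output needs site spacing above twice the read length")

    # -- derived geometry --------------------------------------------------
    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def chrom_lens(self) -> Dict[str, int]:
        return {name: self.chrom_len for name in self.chrom_names}

    @property
    def sites_per_chrom(self) -> int:
        return self.n_sites // self.n_chrom

    @property
    def site_spacing(self) -> int:
        return self.chrom_len // self.sites_per_chrom

    @property
    def sample_names(self) -> Dict[str, List[str]]:
        return {
            POP_A: [f"A{i + 1}" for i in range(self.n_parents_A)],
            POP_B: [f"B{i + 1}" for i in range(self.n_parents_B)],
            "F1": [f"F{i + 1}" for i in range(self.n_f1)],
        }

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_windows"] = [list(w) for w in self.sweep_windows]
        d["tissues"] = list(self.tissues)
        d["qual_range"] = list(self.qual_range)
        return d

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def fingerprint(self) -> str:
        """Stable short hash of the full configuration (including seed)."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset.

    ``sites``: chrom, pos (1-based), ref, alt, freq_A, freq_B, in_sweep,
    sweep_target. ``windows``: every scan-grid window once with its sweep
    status. ``genes``: every gene once with status in {neutral, ase,
    imprinted}, its theta (line-A expression fraction) and sweep overlap.
    """

    sites: pd.DataFrame
    windows: pd.DataFrame
    genes: Optional[pd.DataFrame] = None

    def true_core_genes(self) -> List[str]:
        g = self.genes
        return sorted(g[(g["status"] == "ase") & g["in_sweep"]]["gene_id"])
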