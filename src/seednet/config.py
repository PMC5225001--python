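"""Run configuration: one YAML document drives the whole pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

STAGES = ("simulate", "preprocess", "de", "targets", "enrich", "network")


@dataclass
class RunConfig:
    """Paths, thresholds and stage toggles for one pipeline run.

    All thresholds default to the study gate: fold change > 2 or < 0.5 with
    p < 0.05 and FDR < 0.05, clean-read criteria Q20/30%/17 nt, seed-match
    emission score >= 2, and a mean-CPM floor of 10 for calling
    cross-species ("predicted") miRNAs differentially expressed.
    """

    outdir: str = "seednet_run"
    # inputs (populated by the simulate stage when enabled)
    reads: dict[str, str] = field(default_factory=dict)  # sample -> FASTQ path
    reference_fasta: str = ""
    utr_fasta: str = ""
    mrna_de_table: str = ""
    annotation_gmt: str = ""
    # sample roles
    treated: str = "treated"
    control: str = "control"
    # preprocess
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    q_threshold: int = 20
    q_fraction: float = 0.30
    min_len: int = 17
    species_order: tuple[str, ...] = ("dre", "rno", "mmu", "hsa")
    max_mismatches: int = 0
    # differential expression
    fc_min: float = 2.0
    alpha: float = 0.05
    fdr: float = 0.05
    min_cpm: float = 10.0
    # target prediction
    min_score: float = 2.0
    # simulation sizes
    depth: int = 50_000
    n_per_species: int = 75
    contaminant_fraction: float = 0.2
    n_genes: int = 1200
    utr_length: int = 400
    n_terms: int = 40
    decoys_per_mirna: int = 3
    # orchestration
    seed: int = 42
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.species_order = tuple(self.species_order)
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name, v, lo, hi in (
            ("q_fraction", self.q_fraction, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
            ("fdr", self.fdr, 0.0, 1.0),
            ("contaminant_fraction", self.contaminant_fraction, 0.0, 0.999),
        ):
            if not lo <= v <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}]")
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        if self.min_len <= 0 or self.q_threshold <= 0 or self.depth <= 0:
            raise ValueError("min_len, q_threshold and depth must be positive")
        paths = [p for p in [*self.reads.values(), self.reference_fasta, self.utr_fasta,
                             self.mrna_de_table, self.annotation_gmt] if p]
        if len(paths) != len(set(paths)):
            raise ValueError("declared input paths must be distinct")

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["species_order"] = list(self.species_order)
        d["stages"] = list(self.stages)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        return cls(**d)
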