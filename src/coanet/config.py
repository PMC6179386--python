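"""Pipeline configuration with study-default parameters.

A single structured config (JSON or YAML) drives the end-to-end run;
command-line flags override file values, which override the defaults below.
The defaults are the study parameters: 300 permutations, r >= 0.90 at 1% FDR,
PSM count > 10, 7 folds, co-abundance weight 0.4, 20 random-edge and 1000
random-node realizations, 10,000 rank permutations, top-500 omics filters,
Jaccard >= 0.1 and enrichment q < 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    # input paths (None -> must simulate)
    ppi_path: str | None = None
    abundance_paths: dict[str, str] = field(default_factory=dict)  # condition -> TSV
    psm_paths: dict[str, str] = field(default_factory=dict)
    seeds_path: str | None = None
    gene_sets_path: str | None = None
    expression_path: str | None = None
    baseline: str = "m0"
    stimulated: tuple[str, ...] = ("ifng", "il4")

    # analysis parameters (study defaults)
    n_perm: int = 300
    correlation_method: str = "pearson"
    r_threshold: float = 0.90
    q_max: float = 0.01
    psm_min: int = 10
    denoise: bool = False
    k_folds: int = 7
    w_coa: float = 0.4
    ratio_grid: tuple[float, ...] = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 4.0, 7.0, 10.0)
    optimize_ratio: bool = False
    method: str = "proximity"
    n_random_edges: int = 20
    n_random_nodes: int = 1000
    n_rank_perm: int = 10000
    top_k: int = 500
    jaccard_min: float = 0.1
    enrich_q: float = 0.05
    rng_seed: int = 0

    # simulation parameters (used with --simulate)
    simulate: bool = False
    sim_n_nodes: int = 2000
    sim_mean_degree: float = 12.0
    sim_n_seeds: int = 150
    sim_seed_locality: float = 0.5
    sim_module_size: int = 30
    sim_modules_per_condition: int = 3
    sim_n_background: int = 340
    sim_module_overlap: float = 0.6
    sim_noise_sd: float = 0.15
    sim_include_psms: bool = False

    def __post_init__(self) -> None:
        for name in ("n_perm", "psm_min", "k_folds", "n_random_edges", "n_random_nodes",
                     "n_rank_perm", "top_k"):
            if getattr(self, name) < 1 and name != "psm_min":
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.q_max <= 1 and 0 <= self.enrich_q <= 1):
            raise ValueError("FDR thresholds must be in [0, 1]")
        if not -1 <= self.r_threshold <= 1.01:
            raise ValueError("r_threshold out of range")
        self.stimulated = tuple(self.stimulated)
        self.ratio_grid = tuple(float(r) for r in self.ratio_grid)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stimulated"] = list(self.stimulated)
        d["ratio_grid"] = list(self.ratio_grid)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})

    def to_file(self, path) -> None:
        text = json.dumps(self.as_dict(), indent=2, sort_keys=True) + "\n"
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            text = yaml.safe_dump(self.as_dict(), sort_keys=True)
        Path(path).write_text(text)
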