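"""Pipeline configuration: one YAML document with per-stage sections.

The resolved configuration is written next to every run's outputs so any
result can be traced back to the exact parameters and seed that produced it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


def _domain_check(name: str, value, lo=None, hi=None, strict_lo=False):
    if lo is not None and (value <= lo if strict_lo else value < lo):
        raise ValueError(f"{name}={value} below its domain")
    if hi is not None and value > hi:
        raise ValueError(f"{name}={value} above its domain")


@dataclass
class SimulateParams:
    n_genomes: int = 50
    genes_min: int = 100
    genes_max: int = 300
    n_case: int = 60
    n_control: int = 60
    n_enriched: int = 5
    n_depleted: int = 5
    log2_fold_change: float = 2.0
    sequencing_depth: int = 100_000
    dispersion: float = 1.0
    zero_inflation: float = 0.02
    gene_weight_sd: float = 1.0


@dataclass
class ProfileParams:
    min_samples: int = 10
    renormalize_after_filter: bool = False


@dataclass
class MlgParams:
    cc_threshold: float = 0.6
    min_genes: int = 100


@dataclass
class StatsParams:
    q_cut: float = 0.05
    cc_min: float = 0.3
    n_perm: int = 999
    min_samples_ko: int = 5
    n_background: int = 1000
    distance_metric: str = "bray_curtis"


@dataclass
class MarkerParams:
    folds: int = 5
    repeats: int = 3
    max_panel: int = 25
    n_trees: int = 200
    assoc_n_perm: int = 499
    assoc_cc_min: float = 0.2
    assoc_p_max: float = 0.05
    assoc_repeats: int = 1
    assoc_n_trees: int = 100
    drug_repeats: int = 1
    drug_n_trees: int = 100
    drug_max_panel: int = 10


@dataclass
class PipelineConfig:
    """Everything a full run needs: paths, stage parameters, seed, toggles."""

    outdir: str = "mwas_out"
    counts_path: str | None = None
    metadata_path: str | None = None
    gene_to_genome_path: str | None = None
    gene_to_ko_path: str | None = None
    gene_to_enzyme_path: str | None = None
    module_map_path: str | None = None
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "profile", "mlg", "diff", "network",
            "ordinate", "permanova", "reporter", "classify", "associate", "drugs",
        ]
    )
    simulate: SimulateParams = field(default_factory=SimulateParams)
    profile: ProfileParams = field(default_factory=ProfileParams)
    mlg: MlgParams = field(default_factory=MlgParams)
    stats: StatsParams = field(default_factory=StatsParams)
    markers: MarkerParams = field(default_factory=MarkerParams)

    def validate(self) -> None:
        _domain_check("mlg.cc_threshold", self.mlg.cc_threshold, 0.0, 1.0, strict_lo=True)
        if self.mlg.cc_threshold >= 1.0:
            raise ValueError("mlg.cc_threshold must be < 1")
        _domain_check("profile.min_samples", self.profile.min_samples, 1)
        _domain_check("stats.q_cut", self.stats.q_cut, 0.0, 1.0)
        _domain_check("stats.n_perm", self.stats.n_perm, 1)
        _domain_check("markers.folds", self.markers.folds, 2)
        _domain_check("markers.repeats", self.markers.repeats, 1)
        _domain_check("markers.max_panel", self.markers.max_panel, 1)
        _domain_check("simulate.zero_inflation", self.simulate.zero_inflation, 0.0, 1.0)
        unknown = set(self.stages) - {
            "simulate", "profile", "mlg", "diff", "network", "ordinate",
            "permanova", "reporter", "classify", "associate", "drugs",
        }
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {
            "simulate": SimulateParams, "profile": ProfileParams, "mlg": MlgParams,
            "stats": StatsParams, "markers": MarkerParams,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sections:
                kwargs[key] = sections[key](**(value or {}))
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
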