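"""Pipeline configuration.

All tunable thresholds of the library-construction workflow live in one
frozen dataclass so that a run is fully described by (config, seed, inputs).
Defaults are the full-scale settings used to build a 5000-compound
chemogenomic library from a ChEMBL-style bioactivity dump; tests and the
synthetic workflow override the size parameters downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and sizes for every stage of the pipeline.

    Attributes
    ----------
    potency_threshold_nM:
        Strict upper bound on Ki/IC50 for a molecule-target pair to count
        as bioactive (default 1000 nM, i.e. below 1 uM).
    allowed_measures:
        Measure types that qualify a record (Ki and IC50 by default; EC50
        and others are ignored even when potent).
    required_assay_type:
        Only binding assays ("B") qualify by default.
    required_confidence:
        ChEMBL-style curation confidence required, 0-9 scale (default 9,
        direct single-protein target assignment).
    allowed_species:
        Species whose targets are retained before collapsing to
        species-agnostic protein entries.
    scaffold_level:
        Scaffold-tree level used for the selection path. Level 1 is the
        full ring framework; level 2 has one ring fewer.
    max_targets_per_scaffold:
        Promiscuity cut: scaffolds hitting more than this many protein
        entries are discarded.
    n_clusters:
        Number of scaffold clusters (one representative is picked per
        cluster).
    subset_size:
        Library size targeted by the genetic algorithm.
    ga_population, ga_iterations, ga_mutation_rate:
        Genetic-algorithm population size, generation count, and expected
        number of in/out swap mutations per individual per generation.
    corr_threshold:
        Morphological features with absolute pairwise Pearson correlation
        at or above this value are reduced to one survivor.
    p_cutoff:
        Bonferroni-adjusted significance cutoff for term enrichment.
    min_term_overlap:
        Minimum number of a compound's targets annotated to a term for the
        term to be tested.
    """

    potency_threshold_nM: float = 1000.0
    allowed_measures: frozenset[str] = frozenset({"Ki", "IC50"})
    required_assay_type: str = "B"
    required_confidence: int = 9
    allowed_species: frozenset[str] = frozenset({"human", "rat", "mouse"})
    scaffold_level: int = 2
    max_targets_per_scaffold: int = 6
    n_clusters: int = 5000
    subset_size: int = 5000
    ga_population: int = 1000
    ga_iterations: int = 600
    ga_mutation_rate: float = 0.1
    corr_threshold: float = 0.95
    p_cutoff: float = 0.1
    min_term_overlap: int = 2
    linkage: str = "average"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "potency_threshold_nM": self.potency_threshold_nM,
            "scaffold_level": self.scaffold_level,
            "n_clusters": self.n_clusters,
            "subset_size": self.subset_size,
            "ga_population": self.ga_population,
            "ga_iterations": self.ga_iterations,
            "corr_threshold": self.corr_threshold,
            "p_cutoff": self.p_cutoff,
            "min_term_overlap": self.min_term_overlap,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {value!r}")
        if self.max_targets_per_scaffold < 0:
            raise ConfigError("max_targets_per_scaffold must be non-negative")
        if not 0 <= self.required_confidence <= 9:
            raise ConfigError("required_confidence must lie in 0..9")
        if self.ga_mutation_rate < 0:
            raise ConfigError("ga_mutation_rate must be non-negative")
        if self.linkage not in {"average", "complete", "ward"}:
            raise ConfigError(f"unsupported linkage {self.linkage!r}")

    def with_overrides(self, **kwargs: Any) -> "PipelineConfig":
        for key in kwargs:
            if key not in self.__dataclass_fields__:
                raise ConfigError(f"unknown config key {key!r}")
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["allowed_measures"] = sorted(self.allowed_measures)
        d["allowed_species"] = sorted(self.allowed_species)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        for key in ("allowed_measures", "allowed_species"):
            if key in d:
                d[key] = frozenset(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


#: Desk-scale sizes used by the synthetic end-to-end workflow and the tests.
DESK_SCALE = dict(
    n_clusters=40,
    subset_size=50,
    ga_population=40,
    ga_iterations=60,
)
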