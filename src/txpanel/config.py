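"""Pipeline configuration.

All analysis constants live in :class:`PipelineConfig`: the discordance
threshold for concerted-change calls, the amplitude tiers, the baseline time
point, the external-validation fold-change filter, correlation and FDR
settings, and permutation-test sizes.  The on-disk representation is a flat
key/value YAML mapping with exactly these field names.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ValidationError

_FDR_FAMILIES = ("global", "per_agent")
_CORR_METHODS = ("spearman", "pearson")


@dataclass
class PipelineConfig:
    """Analysis constants for the drug-response transcriptomics pipeline.

    Parameters
    ----------
    discordance_threshold:
        Maximum number of cell lines allowed to change expression in the
        direction opposite to the majority for an experiment to be called
        a concerted change.
    min_cell_lines:
        Minimum number of cell lines with data for a concerted call to be
        eligible for the consensus table; smaller experiments are flagged
        insufficient.
    amplitude_tiers:
        Strictly increasing log2FC magnitudes defining the amplitude
        annotation of a concerted call.
    baseline_time_hr:
        Time point (hours) whose vehicle-control samples define baseline
        expression (median across agents).
    concordance_min_abs_fc:
        Strict |log2FC| filter applied to external-dataset fold changes
        before direction comparison.
    correlation_methods:
        Subset of {"spearman", "pearson"} used by the association screen.
    fdr_family:
        "global": one Benjamini-Hochberg family per method spanning all
        genes, agents, conditions and baseline; "per_agent": one family
        per method per agent.
    min_pairs:
        Minimum complete (x, y) pairs required for a correlation.
    n_perm:
        Number of gene-set permutations for the LS/KS enrichment tests.
    min_set_size / max_set_size:
        Admissible size range for a gene set after intersection with the
        analysis universe.
    rng_seed:
        Seed for every stochastic step (permutation nulls).
    """

    discordance_threshold: int = 15
    min_cell_lines: int = 40
    amplitude_tiers: tuple[float, ...] = (1.0, 2.5, 4.0)
    baseline_time_hr: int = 6
    concordance_min_abs_fc: float = 0.1
    correlation_methods: tuple[str, ...] = ("spearman", "pearson")
    fdr_family: str = "global"
    min_pairs: int = 10
    n_perm: int = 10_000
    min_set_size: int = 5
    max_set_size: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.amplitude_tiers = tuple(float(t) for t in self.amplitude_tiers)
        self.correlation_methods = tuple(self.correlation_methods)
        self.validate()

    def validate(self) -> None:
        if self.discordance_threshold < 0:
            raise ValidationError("discordance_threshold must be non-negative")
        if self.min_cell_lines < 1:
            raise ValidationError("min_cell_lines must be positive")
        tiers = self.amplitude_tiers
        if not tiers or any(t <= 0 for t in tiers):
            raise ValidationError("amplitude_tiers must be positive")
        if any(b <= a for a, b in zip(tiers, tiers[1:])):
            raise ValidationError("amplitude_tiers must be strictly increasing")
        if self.concordance_min_abs_fc < 0:
            raise ValidationError("concordance_min_abs_fc must be non-negative")
        bad = set(self.correlation_methods) - set(_CORR_METHODS)
        if bad or not self.correlation_methods:
            raise ValidationError(
                f"correlation_methods must be a non-empty subset of {_CORR_METHODS}"
            )
        if self.fdr_family not in _FDR_FAMILIES:
            raise ValidationError(f"fdr_family must be one of {_FDR_FAMILIES}")
        if self.min_pairs < 3:
            raise ValidationError("min_pairs must be at least 3")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if not (0 < self.min_set_size <= self.max_set_size):
            raise ValidationError("require 0 < min_set_size <= max_set_size")

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a flat key/value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)
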