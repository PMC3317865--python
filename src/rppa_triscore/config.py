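"""Pipeline configuration: thresholds with study defaults, YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and sizes shared by all stages.

    Defaults follow the study conventions: FDR targeted at 5% and 1%,
    replicate correlation filter strictly above 0.5, trichotomization at
    the 25%/75% pooled quartiles, concordance majority strictly above 50%.
    """

    fdr_targets: list[float] = field(default_factory=lambda: [0.05, 0.01])
    replicate_corr_min: float = 0.5
    snr_min: float = 2.0
    quartile_lo: float = 0.25
    quartile_hi: float = 0.75
    majority_rule: float = 0.5
    seed: int = 0
    #: antibodies simulated by the synthetic pipeline
    n_proteins: int = 40
    #: margin by which a relabel must improve both replicate correlations
    swap_margin: float = 0.1
    #: explicit directive: apply detected label swaps before analysis
    apply_label_swaps: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.quartile_lo < self.quartile_hi < 1):
            raise ValueError("require 0 < quartile_lo < quartile_hi < 1")
        if not all(0 < f < 1 for f in self.fdr_targets):
            raise ValueError("fdr_targets must lie in (0,1)")
        if not (0 < self.majority_rule <= 1):
            raise ValueError("majority_rule must lie in (0,1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
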