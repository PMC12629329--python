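"""Analysis configuration with the study's documented defaults."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Pipeline-wide numerical settings.

    pseudocount
        Added to raw counts before log-ratio transforms (must be > 0).
    prevalence_threshold
        Minimum fraction of samples in which a genus must be detected to
        enter per-taxon statistical modelling; diversity, log-ratio and
        ordination analyses always use the unfiltered table.
    alpha, q_threshold
        Significance levels for single tests and for BH-adjusted screens.
    shannon_log_base
        Base of the logarithm in the Shannon index (natural log default).
    """

    pseudocount: float = 1.0
    prevalence_threshold: float = 0.15
    alpha: float = 0.05
    q_threshold: float = 0.05
    shannon_log_base: float = 2.718281828459045
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not 0.0 <= self.prevalence_threshold <= 1.0:
            raise ValueError("prevalence_threshold must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
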