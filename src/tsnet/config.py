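"""Pipeline configuration: one flat key-value namespace.

A configuration may be loaded from a YAML file and overridden key-by-key
from CLI flags; every stage reads its parameters from here so that a
single file reproduces a full run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # preprocessing
    normalization: str = "zscore_gene"  # none | zscore_gene | zscore_patient_gene
    # discretization
    discretizer: str = "hmmgmm"  # hmmgmm | average | midrange | max_x_max | top_x | efp
    scope: str = "row"           # baseline discretizers: all | row | col
    x_percent: float = 10.0      # max_x_max / top_x threshold parameter
    Q: int = 3                   # number of qualitative states
    sigma_floor_frac: float = 1e-3   # sigma floor as a fraction of pooled value sd
    em_max_iter: int = 100
    em_tol: float = 1e-4         # relative log-likelihood improvement
    per_patient_model: bool = False
    # biclustering
    ml: int = 2                  # minimum window length (time points)
    mo: int = 2                  # minimum number of genes
    # network scoring
    aggregator: str = "mean1mp"  # mean1mp | geomean | minp
    # patient similarity
    sim_aggregation: str = "bestmatch"  # bestmatch | doublesum
    # classifier
    K: int = 7
    C: float = 1.0
    select_grid: dict | None = None  # e.g. {"K": [3,5,7,9], "C": [0.1,1,10]}
    folds: int = 4
    reps: int = 10
    seed: int = 42

    def override(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given non-None keys replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load a YAML config file (or defaults) and apply overrides.

    Unknown keys in the file raise, so typos do not silently fall back
    to defaults.
    """
    cfg = PipelineConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = replace(cfg, **data)
    return cfg.override(**overrides)
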