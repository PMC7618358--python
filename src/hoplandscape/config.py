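"""Run configuration and deterministic seed fan-out."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from hoplandscape.errors import ConfigurationError

# ordered pipeline stages; each gets its own child seed from the run seed
STAGES = ("hopping", "sort", "reads", "bootstrap", "contacts", "flow", "decay")


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the single run seed."""
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Parameters of a reproducible end-to-end run.

    Mirrors the pipeline flags; round-trips losslessly through YAML and
    rejects unknown keys.
    """

    seed: int = 0
    outdir: str = "run_output"
    n_cells: int = 8_000
    n_replicates: int = 2
    step: int = 500
    window_bins: int = 10
    min_integrations: int = 3
    bootstrap: int = 5000
    strand: str = "both"
    deletion: str | None = None  # "chrom:start-end", 1-based inclusive
    with_contacts: bool = False
    contact_bins: int = 200
    contact_resolution: int = 8000
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
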