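"""Resolved run configuration shared by the CLI and pipeline wrappers.

Every tunable parameter of the pipeline lives here with a provenance tag:
``published-default`` for the published operating point of the method (100-kb
windows, 50-kb step, >10 Mb LCNA length, HRD-high at score >= 10) and
``package-default`` for choices the method leaves open.  Reports embed the
fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

__version__ = "0.1.0"

PROVENANCE = {
    "window_size": "published-default",
    "step": "published-default",
    "lcna_min_length": "published-default",
    "hrd_threshold": "published-default",
    "min_mapq": "package-default",
    "lowess_frac": "package-default",
    "low_signal_floor": "package-default",
    "alpha": "package-default",
    "n_perm": "package-default",
    "min_width": "package-default",
    "merge_delta": "package-default",
    "alt_threshold": "package-default",
    "lcna_mode": "package-default",
    "recenter": "package-default",
    "seed": "package-default",
}


@dataclass
class RunConfig:
    window_size: int = 100_000
    step: int = 50_000
    min_mapq: int = 30
    lowess_frac: float = 0.3
    low_signal_floor: float = 0.1
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 3
    merge_delta: float = 0.3
    alt_threshold: float = 0.2
    lcna_min_length: int = 10_000_000
    hrd_threshold: int = 10
    lcna_mode: str = "altered"
    recenter: str = "median"
    seed: int = 0
    provenance: dict = field(default_factory=lambda: dict(PROVENANCE))

    def replace(self, **kwargs) -> "RunConfig":
        cfg = dataclasses.replace(self, **kwargs)
        for key in kwargs:
            if key in cfg.provenance:
                cfg.provenance[key] = "user"
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.pop("version", None)
        provenance = data.pop("provenance", None)
        cfg = cls().replace(**data)
        if provenance:
            cfg.provenance.update(provenance)
        return cfg


def shallowhrd_like(config: RunConfig | None = None) -> RunConfig:
    """Comparison profile classifying at score >= 15 (no claim of matching
    that tool's segmentation)."""
    cfg = config or RunConfig()
    return cfg.replace(hrd_threshold=15)
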