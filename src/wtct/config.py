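"""Pipeline configuration: the printed constants in one auditable place."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .enrichment import DE_PRESETS


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and sizes applied across the pipeline.

    The DE significance presets are (log_pv_min, abs_fc_min):
    ``rna`` = (1, .37) and ``proteomics`` = (1.3, .37); regions must carry
    an adjusted p below ``region_fdr_max`` (default 0.1) to be scored.
    """

    window: int = 100_000
    wtct_mode: str = "weighted"
    de_preset: str = "rna"
    de_thresholds: dict = field(default_factory=lambda: dict(DE_PRESETS))
    region_fdr_max: float = 0.1
    bin_size: int = 1_000
    n_boot: int = 1000
    jaccard_k: int = 100
    seed: int = 0
    state: str | None = None

    def __post_init__(self) -> None:
        if self.window <= 0 or self.bin_size <= 0 or self.n_boot <= 0:
            raise ValueError("window, bin_size and n_boot must be positive")
        if not 0.0 < self.region_fdr_max < 1.0:
            raise ValueError("region_fdr_max must lie in (0,1)")
        if self.wtct_mode not in ("unweighted", "weighted", "binary"):
            raise ValueError(f"unknown wtct_mode: {self.wtct_mode!r}")
        if self.de_preset not in self.de_thresholds:
            raise ValueError(f"unknown de_preset: {self.de_preset!r}")

    @property
    def sig_thresholds(self) -> tuple[float, float]:
        lo, hi = self.de_thresholds[self.de_preset]
        return float(lo), float(hi)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["de_thresholds"] = {
            k: list(v) for k, v in d["de_thresholds"].items()
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "de_thresholds" in data:
            data["de_thresholds"] = {
                k: tuple(v) for k, v in data["de_thresholds"].items()
            }
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
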