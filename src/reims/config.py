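"""Run configuration: defaults, validation, hashing and YAML round-trip.

Defaults pin the analysis constants of the ex-vivo protocol: the m/z 600-1000
binning window, the SNR exclusion threshold of 1500 and the FDR cutoff of
0.05.  Every artifact written by the CLI embeds the configuration hash so a
report can refuse to combine artifacts produced under different settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    # binning axis
    mz_low: float = 600.0
    mz_high: float = 1000.0
    bin_width: float = 0.1
    # quality gate
    snr_threshold: float = 1500.0
    # model
    n_pred: int | None = None  # default: n_classes - 1
    n_orth: int = 1
    binary_mode: str = "refit"  # refit (dedicated 2-class model) | collapse
    # feature testing
    bh_alpha: float = 0.05
    # layer indicator
    gpl_window: tuple[float, float] = (650.0, 850.0)
    tg_window: tuple[float, float] = (850.0, 1000.0)
    ratio_upper: float = 2.0
    ratio_lower: float = 0.5
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if not self.mz_high > self.mz_low:
            errors.append("mz_high must exceed mz_low")
        if self.bin_width <= 0:
            errors.append("bin_width must be > 0")
        if self.snr_threshold < 0:
            errors.append("snr_threshold must be >= 0")
        if not (0 < self.bh_alpha < 1):
            errors.append("bh_alpha must be in (0, 1)")
        if self.binary_mode not in ("refit", "collapse"):
            errors.append("binary_mode must be 'refit' or 'collapse'")
        if self.ratio_lower > self.ratio_upper:
            errors.append("ratio_lower must be <= ratio_upper")
        if self.n_orth < 0 or (self.n_pred is not None and self.n_pred < 1):
            errors.append("need n_orth >= 0 and n_pred >= 1")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    def axis(self):
        from .spectra import BinAxis

        return BinAxis(self.mz_low, self.mz_high, self.bin_width)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    if "gpl_window" in data:
        data["gpl_window"] = tuple(data["gpl_window"])
    if "tg_window" in data:
        data["tg_window"] = tuple(data["tg_window"])
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
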