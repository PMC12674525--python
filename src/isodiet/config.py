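"""Structured run configuration (YAML) for the command-line workflow."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .inference import FitConfig
from .records import QCCriteria

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    """Everything a `fit` run needs, round-trippable through YAML.

    ``tef`` maps source → tracer → [mean, sd]; ``conc`` maps source →
    element → fraction. ``priors`` holds PriorConfig scalar overrides
    (alpha, tef_mode, propagate_source_variance).
    """

    consumers: Optional[str] = None
    sources: Optional[str] = None
    output_dir: str = "isodiet-output"
    subgroups: list = field(default_factory=list)
    tef: dict = field(default_factory=dict)
    conc: dict = field(default_factory=dict)
    qc: QCCriteria = field(default_factory=QCCriteria)
    fit: FitConfig = field(default_factory=FitConfig)
    alpha: Optional[list] = None
    tef_mode: str = "fixed"
    propagate_source_variance: bool = False
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "consumers": self.consumers,
            "sources": self.sources,
            "output_dir": self.output_dir,
            "subgroups": list(self.subgroups),
            "tef": self.tef,
            "conc": self.conc,
            "qc": {
                "min_pct_c": self.qc.min_pct_c,
                "min_pct_n": self.qc.min_pct_n,
                "cn_low": self.qc.cn_low,
                "cn_high": self.qc.cn_high,
                "min_yield": self.qc.min_yield,
            },
            "fit": {
                "chains": self.fit.chains,
                "warmup": self.fit.warmup,
                "draws": self.fit.draws,
                "seed": self.fit.seed,
                "nwalkers": self.fit.nwalkers,
            },
            "alpha": self.alpha,
            "tef_mode": self.tef_mode,
            "propagate_source_variance": self.propagate_source_variance,
            "verbosity": self.verbosity,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        qc = QCCriteria(**d.get("qc", {}))
        fit = FitConfig(**d.get("fit", {}))
        keep = {
            k: v
            for k, v in d.items()
            if k
            in (
                "consumers",
                "sources",
                "output_dir",
                "subgroups",
                "tef",
                "conc",
                "alpha",
                "tef_mode",
                "propagate_source_variance",
                "verbosity",
            )
        }
        return cls(qc=qc, fit=fit, **keep)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
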