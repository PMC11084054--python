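"""Run configuration and stage-tagged logging.

One :class:`RunConfig` holds every threshold and random seed used by a
study run; all stochastic stages draw from generators derived from its
seed, so a fixed seed gives byte-identical outputs end to end.
"""

from __future__ import annotations

import logging
import sys
import zlib
from dataclasses import asdict, dataclass

import numpy as np
import yaml


@dataclass
class RunConfig:
    """Thresholds, model choice, CV shape, and the master seed.

    Defaults mirror the analysis settings the pipeline is built around:
    20% species prevalence, 75% metabolite detection, KO floor of 0.001%
    relative abundance, FDR 0.1, 10x10 nested CV, 10,000 bootstrap draws.
    """

    species_prevalence: float = 0.20
    metabolite_detection: float = 0.75
    ko_prevalence: float = 0.20
    ko_floor: float = 1e-5  # 0.001% as a fraction
    pseudocount: float = 0.5
    fdr_level: float = 0.1
    model_id: int = 1
    ancom_alpha: float = 0.05
    ancom_cutoff: float = 0.7
    structural_zero_threshold: float = 0.99
    outer_folds: int = 10
    inner_folds: int = 10
    cv_repeats: int = 1
    n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("species_prevalence", "metabolite_detection", "ko_prevalence",
                     "fdr_level", "ancom_cutoff", "structural_zero_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.ko_floor <= 0:
            raise ValueError("ko_floor must be positive")
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")

    def rng(self, stage: str = "") -> np.random.Generator:
        """Stage-specific generator derived from the master seed."""
        if stage:
            # crc32 is stable across processes, unlike builtin str hashing
            ss = np.random.SeedSequence(self.seed, spawn_key=(zlib.crc32(stage.encode()),))
            return np.random.default_rng(ss)
        return np.random.default_rng(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def asdict(self) -> dict:
        return asdict(self)


def get_logger(stage: str, level: str = "INFO") -> logging.Logger:
    """Stage-tagged logger writing to stderr."""
    logger = logging.getLogger(f"lvddlink.{stage}")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(
            "%(asctime)s [%(name)s] %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.propagate = False
    logger.setLevel(level.upper())
    return logger
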