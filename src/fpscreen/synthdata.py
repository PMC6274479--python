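"""Class-structured synthetic sparse count-fingerprint datasets.

Each activity class owns a random "core" feature set; its actives carry
each core feature with probability ``core_retention`` and pad with random
background features up to the per-molecule non-zero budget implied by the
sparsity target (~90% zeros by default). Decoys carry background features
only. Non-zero counts follow a geometric law (heavy-tailed, mean
``count_mean``), loosely mimicking circular-fingerprint count statistics.

``core_retention`` presets: ``homogeneous`` (0.9, tight classes) and
``heterogeneous`` (0.5, diverse classes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

from .fingerprints import (
    DEFAULT_DIM,
    CountFingerprint,
    FingerprintDataset,
    MoleculeRecord,
)

__all__ = ["SynthConfig", "RETENTION_PRESETS", "generate", "config_from_yaml"]

RETENTION_PRESETS = {"homogeneous": 0.9, "heterogeneous": 0.5}


@dataclass(frozen=True)
class SynthConfig:
    M: int = DEFAULT_DIM
    n_classes: int = 5
    actives_per_class: int = 50
    n_decoys: int = 2000
    sparsity: float = 0.90
    class_core_size: int = 40
    core_retention: float = 0.9
    count_mean: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.sparsity < 1):
            raise ValueError(f"sparsity must be in (0, 1), got {self.sparsity}")
        if not (0 <= self.core_retention <= 1):
            raise ValueError("core_retention must be in [0, 1]")
        if self.count_mean < 1:
            raise ValueError("count_mean must be >= 1")
        if self.n_classes < 0 or self.actives_per_class < 0 or self.n_decoys < 0:
            raise ValueError("molecule counts must be non-negative")
        if self.class_core_size > self.nonzero_budget:
            raise ValueError(
                f"class_core_size={self.class_core_size} exceeds the non-zero "
                f"budget {self.nonzero_budget} implied by sparsity={self.sparsity}"
            )

    @property
    def nonzero_budget(self) -> int:
        """Non-zero features per molecule implied by the sparsity target."""
        return max(1, round(self.M * (1.0 - self.sparsity)))

    def with_preset(self, name: str) -> "SynthConfig":
        return replace(self, core_retention=RETENTION_PRESETS[name])


def _draw_counts(rng: np.random.Generator, size: int, mean: float) -> np.ndarray:
    # geometric on {1, 2, ...} with p = 1/mean
    return rng.geometric(1.0 / mean, size=size)


def generate(config: SynthConfig) -> FingerprintDataset:
    """Generate a labelled dataset; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed)
    budget = config.nonzero_budget
    all_features = np.arange(config.M)
    records: list[MoleculeRecord] = []

    cores = [
        rng.choice(config.M, size=config.class_core_size, replace=False)
        for _ in range(config.n_classes)
    ]
    for ci, core in enumerate(cores):
        label = f"class{ci:02d}"
        for ai in range(config.actives_per_class):
            kept = core[rng.random(core.size) < config.core_retention]
            n_bg = budget - kept.size
            pool = np.setdiff1d(all_features, kept, assume_unique=False)
            bg = rng.choice(pool, size=n_bg, replace=False)
            feats = np.concatenate([kept, bg])
            counts = _draw_counts(rng, feats.size, config.count_mean)
            fp = CountFingerprint(
                f"{label}_a{ai:03d}",
                {int(j): int(c) for j, c in zip(feats, counts)},
                M=config.M,
            )
            records.append(MoleculeRecord(fp, activity_class=label, is_active=True))

    for di in range(config.n_decoys):
        feats = rng.choice(config.M, size=budget, replace=False)
        counts = _draw_counts(rng, feats.size, config.count_mean)
        fp = CountFingerprint(
            f"decoy_{di:05d}",
            {int(j): int(c) for j, c in zip(feats, counts)},
            M=config.M,
        )
        records.append(MoleculeRecord(fp, activity_class=None, is_active=False))

    return FingerprintDataset(records, M=config.M)


def config_from_yaml(path) -> SynthConfig:
    """Load a :class:`SynthConfig` from a YAML mapping of field names."""
    import yaml

    with open(path, "rt", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("YAML config must be a mapping")
    preset = data.pop("preset", None)
    cfg = SynthConfig(**data)
    if preset is not None:
        cfg = cfg.with_preset(preset)
    return cfg
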