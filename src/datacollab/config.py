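"""Run configuration: one structured file (YAML) drives a whole run.

A single master seed deterministically derives the per-stage seeds
(simulation, experiments), so a config file plus its seed reproduces a
run exactly; the manifest written next to the results records the
config hash for verification.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .experiments import DCParams, MODELS, MODES, SUBSETS
from .features import FPG_THRESHOLD, HBA1C_THRESHOLD


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "results"
    # input visit CSVs; None means "simulate with the default profiles"
    checkup_visits: str | None = None
    hospital_visits: str | None = None
    # synthetic-profile overrides (e.g. {"checkup": {"n_samples": 200}})
    profile_overrides: dict = field(default_factory=dict)
    # preprocessing
    hba1c_threshold: float = HBA1C_THRESHOLD
    fpg_threshold: float = FPG_THRESHOLD
    max_feature_missing: float = 0.5
    min_sample_fraction: float = 0.5
    # collaboration
    dc_method: str = "pca"
    dc_l: int | None = None
    dc_k: int | None = None
    dc_r: int = 1000
    dc_anchor_strategy: str = "uniform"
    # experiment grid
    modes: tuple = MODES
    subsets: tuple = SUBSETS
    models: tuple = MODELS
    n_replicates: int = 100
    test_size: int = 99
    lr_C: float = 1.0

    def __post_init__(self) -> None:
        if self.hba1c_threshold <= 0 or self.fpg_threshold <= 0:
            raise ValueError("diagnostic thresholds must be positive")
        for v in (self.max_feature_missing, self.min_sample_fraction):
            if not 0 < v <= 1:
                raise ValueError("filter thresholds must lie in (0, 1]")
        bad = set(self.modes) - set(MODES)
        bad |= set(self.subsets) - set(SUBSETS)
        bad |= set(self.models) - set(MODELS)
        if bad:
            raise ValueError(f"unknown grid entries: {sorted(bad)}")
        if self.n_replicates < 1 or self.test_size < 1:
            raise ValueError("n_replicates and test_size must be >= 1")

    # -- seeds -----------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed."""
        digest = hashlib.sha256(stage.encode()).digest()
        key = int.from_bytes(digest[:4], "big")
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % (2**31))

    @property
    def dc_params(self) -> DCParams:
        return DCParams(method=self.dc_method, l=self.dc_l, k=self.dc_k,
                        r=self.dc_r, anchor_strategy=self.dc_anchor_strategy)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("modes", "subsets", "models"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("modes", "subsets", "models"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write_manifest(self, path, extra: dict | None = None) -> None:
        import importlib.metadata

        versions = {}
        for pkg in ("datacollab", "numpy", "scipy", "pandas",
                    "scikit-learn", "lightgbm"):
            try:
                versions[pkg] = importlib.metadata.version(pkg)
            except importlib.metadata.PackageNotFoundError:  # pragma: no cover
                versions[pkg] = "unknown"
        manifest = {
            "config": self.to_dict(),
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "versions": versions,
        }
        if extra:
            manifest.update(extra)
        Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
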