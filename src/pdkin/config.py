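"""Pipeline configuration: schema, defaults, validation and run manifests.

Defaults reproduce the reference analysis settings: 4-s windows with 1-s
overlap, 5-fold x 50-repeat cross-validation with 50/20/30
train/validation/test fractions, freeze band 3-8 Hz, locomotor band
0.5-3 Hz.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import SchemaError


@dataclass
class PipelineConfig:
    input_dir: str = "data"
    output_dir: str = "out"
    window_s: float = 4.0
    overlap_s: float = 1.0
    axis_convention: str = "X=mediolateral,Y=vertical,Z=anterior"
    freeze_band: tuple[float, float] = (3.0, 8.0)
    locomotor_band: tuple[float, float] = (0.5, 3.0)
    spectral_band: tuple[float, float] = (0.5, 12.0)
    wavelet: str = "db4"
    wavelet_level: int = 4
    sessions: list[str] = field(default_factory=lambda: ["walk_thru", "turn_360", "tug"])
    feature_families: list[str] = field(default_factory=lambda: ["kinematic", "gait"])
    models: list[str] = field(default_factory=lambda: ["rf", "rbfsvm", "mlp"])
    schemes: list[str] = field(default_factory=lambda: ["user_independent", "user_dependent"])
    fog_filters: list[bool] = field(default_factory=lambda: [True, False])
    fractions: tuple[float, float, float] = (0.50, 0.20, 0.30)
    n_folds: int = 5
    n_repeats: int = 50
    n_search: int = 25
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.window_s <= self.overlap_s or self.overlap_s < 0:
            problems.append("window_s/overlap_s")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            problems.append("fractions")
        for name in ("n_folds", "n_repeats", "n_search"):
            if getattr(self, name) < 1:
                problems.append(name)
        for name in ("freeze_band", "locomotor_band", "spectral_band"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                problems.append(name)
        bad_models = set(self.models) - {"rf", "rbfsvm", "mlp"}
        if bad_models:
            problems.append(f"models ({sorted(bad_models)})")
        bad_schemes = set(self.schemes) - {"user_independent", "user_dependent"}
        if bad_schemes:
            problems.append(f"schemes ({sorted(bad_schemes)})")
        bad_sessions = set(self.sessions) - {"walk_thru", "turn_360", "tug"}
        if bad_sessions:
            problems.append(f"sessions ({sorted(bad_sessions)})")
        if problems:
            raise SchemaError("invalid config key(s): " + ", ".join(problems))


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config file must contain a mapping")
    valid_keys = set(PipelineConfig().__dataclass_fields__)
    unknown = sorted(set(raw) - valid_keys)
    if unknown:
        raise SchemaError("unknown config key(s): " + ", ".join(unknown))
    for key in ("freeze_band", "locomotor_band", "spectral_band", "fractions"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of a config for run manifests."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_manifest(out_dir: str | Path, cfg: PipelineConfig,
                   extra: dict | None = None) -> Path:
    """Write a reproducibility manifest (config hash, seed, version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "pdkin_version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "config": asdict(cfg),
        **(extra or {}),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
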