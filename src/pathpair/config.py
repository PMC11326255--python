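"""Run configuration and logging for the command-line workflow."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import Hyperparameters


@dataclass
class RunConfig:
    """Everything one end-to-end run needs, loadable from a YAML file.

    ``levels`` restricts the pathway hierarchy levels used; ``scaled``
    toggles per-iteration feature-wise min/max scaling; ``size_threshold``
    / ``size_metric`` filter small pathways out of the training universe
    before evaluation (0 = keep everything).
    """

    molfile_dir: str | None = None
    membership: str | None = None
    out_dir: str = "pathpair_out"
    levels: tuple[str, ...] = ("L2", "L3")
    scaled: bool = True
    size_threshold: int = 0
    size_metric: str = "compounds"
    n_iterations: int = 10
    test_fraction: float = 0.10
    seed: int = 0
    stratify_key: str = "pathway_label"
    tune_trials: int = 0
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.size_metric not in ("compounds", "atoms"):
            raise ValueError("size_metric must be 'compounds' or 'atoms'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        hp = raw.pop("hyperparameters", None)
        cfg = cls(**raw)
        if hp:
            if "hidden_layer_sizes" in hp:
                hp["hidden_layer_sizes"] = tuple(hp["hidden_layer_sizes"])
            cfg.hyperparameters = Hyperparameters(**hp)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["levels"] = list(self.levels)
        d["hyperparameters"]["hidden_layer_sizes"] = list(
            self.hyperparameters.hidden_layer_sizes
        )
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Record config hash, seeds and package version so a run is reproducible."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "pathpair_version": __version__,
        **(extra or {}),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Timestamped, leveled logging to stderr and optionally a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
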