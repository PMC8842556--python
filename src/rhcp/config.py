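"""Run configuration shared by the command-line entry points.

A run is fully described by a :class:`RunConfig`: where the fixture lives
(or how to generate it), which catalogue to use, the travel-time cutoffs,
the outlier-cleaning multiplier, the averaging switch and the random seed.
Configs load from YAML; CLI flags override config keys.  Every command
echoes its effective config as JSON next to its outputs so a run can be
reproduced from its artefacts.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import yaml
from pydantic import BaseModel, field_validator

logger = logging.getLogger("rhcp")


class RunConfig(BaseModel):
    fixture_dir: str = "fixture"
    catalogue: str = "default"
    cutoffs: tuple[float, ...] = (10.0, 15.0, 20.0)
    outlier_multiplier: float = 3.0
    quantile_rule: str = "linear"     # type-7: linear interpolation between order statistics
    population_weighted: bool = False
    seed: int = 0
    n_municipalities: int = 2122
    n_districts: int = 116
    log_level: str = "INFO"

    @field_validator("cutoffs")
    @classmethod
    def _cutoffs_increasing(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not v:
            raise ValueError("cutoffs must be non-empty")
        if any(c <= 0 for c in v):
            raise ValueError("cutoffs must be strictly positive")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        return v

    @field_validator("quantile_rule")
    @classmethod
    def _quantile_rule(cls, v: str) -> str:
        if v != "linear":
            raise ValueError("only the 'linear' (type-7) quantile rule is implemented")
        return v

    @classmethod
    def load(cls, path: str | Path | None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def echo(self, directory: str | Path, command: str) -> Path:
        """Write the effective config next to the outputs (reproducibility)."""
        path = Path(directory) / f"run_{command}.json"
        path.write_text(
            json.dumps({"command": command, **self.model_dump()}, indent=2, default=list),
            encoding="utf-8",
        )
        return path


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
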