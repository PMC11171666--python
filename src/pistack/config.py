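"""Structured run configuration, YAML round-trip, logging and provenance.

A serialized :class:`RunConfig` (plus the package version) is sufficient to
reproduce any run bitwise: every stochastic element is seeded from it.
"""
from __future__ import annotations

import dataclasses
import logging
import platform
import sys
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .dynamics import IntegratorConfig
from .forcefield import ConfigurationError, NonbondedConfig
from .smd import SMDConfig

__all__ = [
    "AnalysisConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "setup_logging",
    "provenance",
]


@dataclasses.dataclass
class AnalysisConfig:
    com_cutoff: float = 10.0  # A
    smooth_ps: float = 10.0
    drop_frac: float = 0.25
    min_drop_pN: float = 10.0
    plateau_threshold: float = 6.0  # A
    plateau_dwell: float = 50.0  # ps
    plateau_var_tol: float = 1.5  # A^2


@dataclasses.dataclass
class RunConfig:
    """Everything an end-to-end run needs, including the global seed."""

    system: str = "anthracene"
    scale: str = "desk"
    seed: int = 7
    out_dir: str = "pistack_out"
    n_replicas: int = 4
    nonbonded: NonbondedConfig = dataclasses.field(default_factory=NonbondedConfig)
    integrator: IntegratorConfig = dataclasses.field(default_factory=IntegratorConfig)
    smd: SMDConfig = dataclasses.field(default_factory=SMDConfig)
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, np.ndarray):
            return [float(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x

    return clean(d)


def save_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(_asdict(cfg), sort_keys=False))


def load_config(path: Union[str, Path]) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    try:
        nb = NonbondedConfig(**raw.pop("nonbonded", {}))
        integ = IntegratorConfig(**raw.pop("integrator", {}))
        smd = SMDConfig(**raw.pop("smd", {}))
        if smd.pull_direction is not None:
            smd.pull_direction = np.asarray(smd.pull_direction, dtype=float)
        if smd.origin is not None:
            smd.origin = np.asarray(smd.origin, dtype=float)
        ana = AnalysisConfig(**raw.pop("analysis", {}))
        return RunConfig(nonbonded=nb, integrator=integ, smd=smd, analysis=ana, **raw)
    except TypeError as exc:
        raise ConfigurationError(f"unknown or invalid config field: {exc}") from exc


def setup_logging(verbosity: int = 0, logfile: Optional[Union[str, Path]] = None) -> None:
    """Log to stderr, and optionally to a file, with run provenance at DEBUG."""
    level = logging.WARNING - 10 * min(verbosity, 2)
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def provenance(cfg: Optional[RunConfig] = None) -> dict:
    """Versions, platform and the full config — written next to every run."""
    from . import __version__

    info = {
        "pistack_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "platform": platform.platform(),
    }
    if cfg is not None:
        info["config"] = _asdict(cfg)
    return info
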