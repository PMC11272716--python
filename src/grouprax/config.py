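"""Run configuration: one YAML file carries every tunable.

Each CLI run resolves its configuration (defaults plus file overrides) and
logs the resolved values, so any result can be traced to the exact
thresholds that produced it.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "setup_logging"]


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults."""

    # perturbation / testing
    alpha: float = 0.05
    equal_var: bool = True
    collapse: bool = True
    normalise: bool = True
    transform: bool = True
    # preprocessing
    min_total: int = 10
    outlier_conf: float = 0.95
    # bootstrap
    scales: list[float] = field(default_factory=lambda: [round(0.5 + 0.1 * i, 1) for i in range(10)])
    n_boot: int = 10000
    seed: int = 0
    keep_archive: bool = False
    # structure
    si_threshold: float = 0.95
    restrict_to_nonzero: bool = False
    # xenobiotic
    ppm_tol: float = 5.0
    min_fc: float = 10.0
    corr_threshold: float = 0.8
    # read-across
    au_threshold: float = 0.80

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def log_resolved(self, logger: logging.Logger | None = None) -> None:
        logger = logger or logging.getLogger("grouprax")
        for k, v in sorted(asdict(self).items()):
            logger.info("config %s = %r", k, v)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Defaults, then YAML file values, then keyword overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
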