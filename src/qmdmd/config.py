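"""Run configuration: explicit defaults, strict parsing, provenance echo.

Defaults are the full sampling protocol: 5 annealing steps of 500 t.u. from
a 0.20 peak down to 0.10, a 10,000 t.u. production phase saved every
10 t.u. with heat exchange at 0.1 t.u.⁻¹, 5 clusters, 20 iterations.
Unknown or duplicate keys are errors, never silently ignored; the fully
resolved configuration is echoed to the output directory so a run can be
reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dmd import Schedule


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    n_iterations: int = 20
    k_clusters: int = 5
    coordination_cutoff: float = 2.6
    constraint_half_width: float = 0.01
    qm_tol: float = 1e-4
    schedule: Schedule = field(default_factory=Schedule)
    outdir: str | None = None

    def __post_init__(self):
        if self.k_clusters < 1:
            raise ConfigError("k_clusters must be >= 1")
        if self.n_iterations < 0:
            raise ConfigError("n_iterations must be >= 0")
        for name in ("coordination_cutoff", "constraint_half_width", "qm_tol"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("anneal_peak", "anneal_final", "anneal_step_tu",
                     "production_tu", "production_temperature",
                     "save_interval"):
            if getattr(self.schedule, name) <= 0:
                raise ConfigError(f"schedule.{name} must be positive")

    def driver_kwargs(self) -> dict:
        return dict(seed=self.seed, schedule=self.schedule,
                    k_clusters=self.k_clusters,
                    coordination_cutoff=self.coordination_cutoff,
                    constraint_half_width=self.constraint_half_width,
                    qm_tol=self.qm_tol)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


class _StrictLoader(yaml.SafeLoader):
    pass


def _no_duplicates(loader, node, deep=False):
    seen = set()
    for key_node, _v in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise ConfigError(f"duplicate key {key!r} in configuration")
        seen.add(key)
    return yaml.SafeLoader.construct_mapping(loader, node, deep)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_duplicates)


def load_config(path=None, text: str | None = None) -> RunConfig:
    """Parse a YAML run configuration; empty input yields the defaults."""
    if text is None:
        text = Path(path).read_text() if path is not None else ""
    data = yaml.load(text, Loader=_StrictLoader) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    sched_data = data.pop("schedule", {}) or {}
    sched_known = {f.name for f in dataclasses.fields(Schedule)}
    bad = set(sched_data) - sched_known
    if bad:
        raise ConfigError(f"unknown schedule keys: {sorted(bad)}")
    try:
        schedule = Schedule(**sched_data)
        return RunConfig(schedule=schedule, **data)
    except TypeError as e:
        raise ConfigError(str(e)) from e


def echo_config(config: RunConfig, outdir) -> None:
    """Write the fully resolved configuration next to the run's outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
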