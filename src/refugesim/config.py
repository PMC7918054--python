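"""Flat YAML run configuration: defaults, validation, lossless round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import ModelParams, ParameterError, Scenario

__all__ = ["RunConfig", "ConfigError", "load_config", "write_config", "preset_path"]


class ConfigError(ValueError):
    """Raised for unknown keys, out-of-range values, or malformed files."""


_RUN_KEYS = {
    "scenario", "seeds", "out_dir", "snapshot_at", "verbosity",
    "sa_design", "sa_levels", "sa_replicates", "sa_scale",
}


@dataclass
class RunConfig:
    """A complete, reproducible run description."""

    params: ModelParams = field(default_factory=ModelParams)
    scenario: Scenario = Scenario.NO_SPRAY
    seeds: list[int] = field(default_factory=lambda: [0])
    out_dir: str = "refugesim_out"
    snapshot_at: list[int] = field(default_factory=list)
    verbosity: int = 1
    sa_design: str = "hadamard"
    sa_levels: int = 2
    sa_replicates: int = 2
    sa_scale: bool = False

    def to_flat(self) -> dict:
        out = dict(self.params.to_flat())
        out.update(
            scenario=self.scenario.value,
            seeds=list(self.seeds),
            out_dir=self.out_dir,
            snapshot_at=list(self.snapshot_at),
            verbosity=self.verbosity,
            sa_design=self.sa_design,
            sa_levels=self.sa_levels,
            sa_replicates=self.sa_replicates,
            sa_scale=self.sa_scale,
        )
        return out

    @classmethod
    def from_flat(cls, flat: dict) -> "RunConfig":
        flat = dict(flat)
        run_kwargs = {}
        if "scenario" in flat:
            raw = flat.pop("scenario")
            try:
                run_kwargs["scenario"] = Scenario(str(raw).lower())
            except ValueError:
                raise ConfigError(
                    f"unknown scenario {raw!r}; choose from "
                    f"{[s.value for s in Scenario]}"
                ) from None
        for key in ("seeds", "snapshot_at"):
            if key in flat:
                v = flat.pop(key)
                run_kwargs[key] = [int(x) for x in (v if isinstance(v, list) else [v])]
        for key in ("out_dir", "verbosity", "sa_design", "sa_levels",
                    "sa_replicates", "sa_scale"):
            if key in flat:
                run_kwargs[key] = flat.pop(key)
        try:
            params = ModelParams.from_flat(flat)
        except ParameterError as exc:
            raise ConfigError(str(exc)) from exc
        return cls(params=params, **run_kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read a YAML run configuration; absent keys fall back to the defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a key-value mapping, got {type(raw)}")
    return RunConfig.from_flat(raw)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_flat(), sort_keys=True))


def preset_path(name: str) -> Path:
    """Path of a named parameter preset shipped with the package."""
    p = Path(__file__).parent / "presets" / f"{name}.yaml"
    if not p.exists():
        available = sorted(q.stem for q in p.parent.glob("*.yaml"))
        raise ConfigError(f"unknown preset {name!r}; available: {available}")
    return p
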