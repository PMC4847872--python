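"""Configuration loading and validation.

A config file is a flat YAML or TOML document: model-rate keys mirroring
:class:`~repliwave.core.SimulationParams` at top level, plus optional nested
blocks (``init``, ``run``, ``ablation``, ``scan``, ``strip``, ``grid``) for
experiment-specific settings.  Unknown keys are rejected with their full key
path; missing keys take the reference defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .core import InitSpec, SimulationParams, ValidationError, build_params
from .experiments import AblationSpec, ScanSpec

EXPERIMENTS = ("evolutionary", "beta-scan", "ecological", "disruption",
               "expansion", "coevolution", "well-mixed")

_PARAM_KEYS = {f.name for f in fields(SimulationParams) if f.init}
_INIT_KEYS = {f.name for f in fields(InitSpec)}
_RUN_KEYS = {"t_end", "sample_every", "snapshot_every", "bin_width"}
_ABLATION_KEYS = {f.name for f in fields(AblationSpec)}
_SCAN_KEYS = {f.name for f in fields(ScanSpec)}
_STRIP_KEYS = {"L_y", "window_L_x"}
_GRID_KEYS = {"ka_grid", "beta_grid", "t_measure", "replicates"}
_BLOCKS = {
    "init": _INIT_KEYS,
    "run": _RUN_KEYS,
    "ablation": _ABLATION_KEYS,
    "scan": _SCAN_KEYS,
    "strip": _STRIP_KEYS,
    "grid": _GRID_KEYS,
}


@dataclass
class Config:
    """A fully resolved experiment configuration."""

    experiment: str
    params: SimulationParams
    init: InitSpec
    run: dict
    ablation: AblationSpec | None = None
    scan: ScanSpec | None = None
    strip: dict | None = None
    grid: dict | None = None

    def to_dict(self) -> dict:
        out = {"experiment": self.experiment}
        p = dataclasses.asdict(self.params)
        p.pop("template_rate", None)
        p["ka_bounds"] = list(p["ka_bounds"])
        p["beta_bounds"] = list(p["beta_bounds"])
        out.update(p)
        init = dataclasses.asdict(self.init)
        if isinstance(init["ka_init"], tuple):
            init["ka_init"] = list(init["ka_init"])
        if isinstance(init["beta_init"], tuple):
            init["beta_init"] = list(init["beta_init"])
        if init["region"] is not None:
            init["region"] = list(init["region"])
        out["init"] = init
        out["run"] = dict(self.run)
        if self.ablation is not None:
            out["ablation"] = dataclasses.asdict(self.ablation)
        if self.scan is not None:
            s = dataclasses.asdict(self.scan)
            s["values"] = list(s["values"])
            out["scan"] = s
        if self.strip is not None:
            out["strip"] = dict(self.strip)
        if self.grid is not None:
            out["grid"] = dict(self.grid)
        return out


def _load_document(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".toml":
        import tomllib
        try:
            return tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise ValidationError(f"cannot parse {path}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValidationError(f"{path} must hold a mapping at top level")
    return doc


def _maybe_tuple(v):
    return tuple(v) if isinstance(v, (list, tuple)) else v


def resolve_config(doc: dict) -> Config:
    """Validate a raw config mapping and apply defaults."""
    doc = dict(doc)
    experiment = doc.pop("experiment", "evolutionary")
    if experiment not in EXPERIMENTS:
        raise ValidationError(
            f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}")
    blocks = {}
    for name, allowed in _BLOCKS.items():
        block = doc.pop(name, None)
        if block is None:
            blocks[name] = {}
            continue
        if not isinstance(block, dict):
            raise ValidationError(f"config block {name!r} must be a mapping")
        for key in block:
            if key not in allowed:
                raise ValidationError(f"unknown key: {name}.{key}")
        blocks[name] = dict(block)
    for key in doc:
        if key not in _PARAM_KEYS:
            raise ValidationError(f"unknown key: {key}")
    params = build_params(doc)
    init_kwargs = dict(blocks["init"])
    for k in ("ka_init", "beta_init", "region"):
        if k in init_kwargs:
            init_kwargs[k] = _maybe_tuple(init_kwargs[k])
    init = InitSpec(**init_kwargs)
    run = {"t_end": 1000.0, "sample_every": 50.0, "snapshot_every": None,
           "bin_width": 0.02}
    run.update(blocks["run"])
    ablation = AblationSpec(**blocks["ablation"]) if blocks["ablation"] else None
    scan = None
    if blocks["scan"]:
        sk = dict(blocks["scan"])
        if "values" in sk:
            sk["values"] = [float(v) for v in sk["values"]]
        scan = ScanSpec(**sk)
    strip = blocks["strip"] or None
    grid = blocks["grid"] or None
    if experiment == "disruption" and ablation is None:
        ablation = AblationSpec()
    return Config(experiment=experiment, params=params, init=init, run=run,
                  ablation=ablation, scan=scan, strip=strip, grid=grid)


def load_config(path: str | Path) -> Config:
    """Load and validate an experiment configuration file."""
    return resolve_config(_load_document(Path(path)))


def dump_config(config: Config, path: str | Path) -> None:
    """Write the resolved configuration next to a run's outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
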