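"""Configuration loading, run manifests and result bundles.

The configuration is a single flat key:value file (YAML scalars only, one
key per model parameter, synaptic weights as ``g_RRe`` ... ``g_NWi``).
Resolution precedence: packaged defaults < config file < explicit overrides.
Validation errors name the offending key, and sign-convention violations
(e.g. a positive inhibitory weight) are rejected at load time.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .params import ModelParameters, ParameterError
from .scoring import Hypnogram, MetricsRecord, metrics_to_frame, write_hypnogram
from .simulate import TimeSeries, write_timeseries

__all__ = ["ConfigError", "load_config", "default_config_text", "RunManifest",
           "write_results_bundle"]


class ConfigError(ValueError):
    """Configuration file or override problem, naming the offending key."""


def default_config_text() -> str:
    """The packaged default configuration file, verbatim."""
    return resources.files("somnet").joinpath("defaults.yaml").read_text()


def _parse_flat(text: str, source: str) -> dict[str, float]:
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{source}: not parseable as YAML ({exc})") from exc
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{source}: expected flat key: value mappings")
    out = {}
    for key, value in data.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"{source}: {key}: value must be a number, got {value!r}")
        out[str(key)] = float(value)
    return out


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, float] | None = None,
) -> ModelParameters:
    """Resolve parameters: packaged defaults, then the file, then overrides.

    An empty file yields the packaged defaults.  Unknown keys and invariant
    violations raise :class:`ConfigError` naming the key.
    """
    resolved = _parse_flat(default_config_text(), "packaged defaults")
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"{path}: config file does not exist")
        resolved.update(_parse_flat(path.read_text(), str(path)))
    if overrides:
        for key, value in overrides.items():
            try:
                resolved[str(key)] = float(value)
            except (TypeError, ValueError):
                raise ConfigError(f"override {key}: value must be a number, got {value!r}")
    try:
        return ModelParameters.from_flat_dict(resolved)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc


@dataclass
class RunManifest:
    """Reproducibility record written alongside every result bundle."""

    config_digest: str
    seeds: list[int | None]
    command: str = ""
    rng_algorithm: str = "numpy.random.Generator(PCG64)"
    software_version: str = __version__
    created: str = field(default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())
    outputs: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def write_results_bundle(
    out_dir: str | Path,
    manifest: RunManifest,
    timeseries: Mapping[str, TimeSeries] | None = None,
    hypnograms: Mapping[str, Hypnogram] | None = None,
    metrics: list[MetricsRecord] | None = None,
    stats=None,
) -> Path:
    """Write a deterministic file layout under ``out_dir``.

    The manifest (the only file carrying a timestamp) is always written;
    every other file is a function of its inputs alone, so re-running with
    identical inputs reproduces identical bytes.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: list[str] = []
    for name, ts in (timeseries or {}).items():
        p = out_dir / f"timeseries_{name}.tsv"
        write_timeseries(ts, p)
        written.append(p.name)
    for name, h in (hypnograms or {}).items():
        p = out_dir / f"hypnogram_{name}.csv"
        write_hypnogram(h, p)
        written.append(p.name)
    if metrics:
        p = out_dir / "metrics.csv"
        metrics_to_frame(metrics).to_csv(p, index=False)
        written.append(p.name)
    if stats is not None:
        p = out_dir / "stats.csv"
        stats.to_csv(p, index=False)
        written.append(p.name)
    manifest.outputs = sorted(written)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return out_dir
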