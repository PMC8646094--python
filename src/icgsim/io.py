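"""Configuration loading, result serialization and reproducibility manifests.

Configs are YAML or JSON documents with optional blocks
``reference_parameters``, ``individual``, ``protocol``, ``solver`` and
``cohort``; unknown keys are rejected with the nearest valid key suggested.
Result tables round-trip through CSV; every written table is accompanied by
a JSON manifest holding the config snapshot, root seed, package version and
SHA-256 digests of the outputs, so a manifest pins the full provenance of a
run.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .model import DoseProtocol, Individual, ModelParameters
from .population import CohortConfig, PhysiologyTrends, SexAnthropometry

__all__ = ["RunConfig", "RunManifest", "load_config", "write_results",
           "read_results", "ConfigError"]


class ConfigError(ValueError):
    """Config file violates the schema."""


_SOLVER_DEFAULTS = {"method": "LSODA", "rtol": 1e-8, "atol": 1e-10}


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level configuration for a simulation run."""

    reference_parameters: ModelParameters = field(default_factory=ModelParameters)
    individual: Individual = field(default_factory=Individual)
    protocol: DoseProtocol = field(default_factory=DoseProtocol)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    solver: dict = field(default_factory=lambda: dict(_SOLVER_DEFAULTS))
    seed: int = 0


def _check_keys(given: dict, valid: set[str], context: str) -> None:
    unknown = sorted(set(given) - valid)
    if unknown:
        msgs = []
        for key in unknown:
            close = difflib.get_close_matches(key, valid, n=1)
            hint = f" (did you mean {close[0]!r}?)" if close else ""
            msgs.append(f"{key!r}{hint}")
        raise ConfigError(f"unknown key(s) in {context}: {', '.join(msgs)}")


def _build(cls, data: dict, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(data, fields, context)
    kwargs = {name: data[name] for name in fields if name in data}
    for k, v in kwargs.items():
        if isinstance(v, list):
            kwargs[k] = tuple(v)
    return cls(**kwargs)


_NESTED_COHORT = {"male": SexAnthropometry, "female": SexAnthropometry,
                  "physiology": PhysiologyTrends}


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config; defaults fill absent blocks.

    Raises :class:`ConfigError` listing every offending key with its nearest
    valid alternative.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    _check_keys(data, {f.name for f in dataclasses.fields(RunConfig)}, "config")

    kwargs: dict[str, Any] = {}
    if "reference_parameters" in data:
        kwargs["reference_parameters"] = _build(
            ModelParameters, data["reference_parameters"], "reference_parameters")
    if "individual" in data:
        kwargs["individual"] = _build(Individual, data["individual"], "individual")
    if "protocol" in data:
        kwargs["protocol"] = _build(DoseProtocol, data["protocol"], "protocol")
    if "cohort" in data:
        cdata = dict(data["cohort"])
        for key, cls in _NESTED_COHORT.items():
            if key in cdata:
                cdata[key] = _build(cls, cdata[key], f"cohort.{key}")
            # tuples serialize as lists in YAML
        for k, v in list(cdata.items()):
            if isinstance(v, list):
                cdata[k] = tuple(v)
        kwargs["cohort"] = _build(CohortConfig, cdata, "cohort")
    if "solver" in data:
        _check_keys(data["solver"], set(_SOLVER_DEFAULTS), "solver")
        kwargs["solver"] = {**_SOLVER_DEFAULTS, **data["solver"]}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    return RunConfig(**kwargs)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


@dataclass
class RunManifest:
    """Provenance record written next to every result table."""

    config: dict
    seed: int
    version: str = __version__
    timestamp: str = ""
    digests: dict = field(default_factory=dict)

    @classmethod
    def from_config(cls, config, seed: int) -> "RunManifest":
        return cls(config=_jsonify(config), seed=seed,
                   timestamp=datetime.now(timezone.utc).isoformat())

    @property
    def config_digest(self) -> str:
        blob = json.dumps({"config": self.config, "seed": self.seed,
                           "version": self.version}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def write_results(table: pd.DataFrame, path, manifest: RunManifest) -> Path:
    """Write a result table as CSV plus a JSON manifest (``<path>.manifest.json``).

    The CSV is deterministic for a fixed table; the manifest records its
    SHA-256 digest so re-runs can be verified byte-for-byte.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        table.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed writing results to {path}: {exc}") from exc
    manifest.digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    mpath = path.with_suffix(path.suffix + ".manifest.json")
    mpath.write_text(json.dumps(dataclasses.asdict(manifest), indent=2,
                                sort_keys=True) + "\n")
    return path


def read_results(path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    return pd.read_csv(path)
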