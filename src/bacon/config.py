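"""Configuration loading, run manifests and output serialization."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .experiments import ExperimentSpec
from .params import ModelParams, ParameterError

__all__ = ["RunManifest", "load_config", "write_outputs"]

_SPEC_KEYS = {"name", "phases", "n_replicates", "base_seed", "overrides"}


@dataclass
class RunManifest:
    """Provenance record for one run: config, seeds and output checksums."""

    config: dict
    base_seed: int
    replicate_seeds: list
    outputs: dict = field(default_factory=dict)  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def load_config(path: str | Path) -> tuple[ModelParams, ExperimentSpec | None]:
    """Read a YAML/JSON configuration file.

    The file is a flat mapping of model parameter names (missing keys keep
    their defaults), optionally containing an ``experiment`` sub-mapping
    with :class:`~bacon.experiments.ExperimentSpec` fields.  Unknown keys
    are rejected by name.
    """
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a mapping")
    exp_data = data.pop("experiment", None)
    params = ModelParams.from_dict(data)
    spec = None
    if exp_data is not None:
        unknown = set(exp_data) - _SPEC_KEYS
        if unknown:
            raise ParameterError(
                f"unknown experiment key(s): {', '.join(sorted(unknown))}"
            )
        spec = ExperimentSpec(**exp_data)
    return params, spec


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(
    results: dict[str, pd.DataFrame],
    out_dir: str | Path,
    params: ModelParams,
    base_seed: int,
    replicate_seeds=(),
) -> RunManifest:
    """Write result tables as CSV plus a manifest (written last).

    Returns the manifest; re-running with identical inputs reproduces
    identical files and checksums.
    """
    if not results:
        raise ValueError("no results to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=params.to_dict(),
        base_seed=int(base_seed),
        replicate_seeds=[int(s) for s in replicate_seeds],
    )
    for name, frame in results.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest.outputs[path.name] = _sha256(path)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
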