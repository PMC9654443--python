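"""Readers and writers: delimited-text cohorts, model serialisation, manifests.

Interchange format everywhere is comma-separated UTF-8 text with a header
row and "." decimals; fitted models are stored as JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hmm import HmmParameters
from .synthetic import GeneratorConfig, SyntheticCohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_params",
    "read_params",
    "load_generator_config",
    "write_manifest",
]


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path, stem: str = "cohort") -> dict[str, Path]:
    """Write participant-level (and optional item-level) tables as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"cohort": out_dir / f"{stem}.csv"}
    cohort.to_frame().to_csv(paths["cohort"], index=False)
    if cohort.item_responses is not None:
        paths["items"] = out_dir / f"{stem}_items.csv"
        cohort.item_responses.to_csv(paths["items"], index=False)
    return paths


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_params(params: HmmParameters, path: str | Path, meta: dict | None = None) -> None:
    payload = params.to_dict()
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=2))


def read_params(path: str | Path) -> HmmParameters:
    return HmmParameters.from_dict(json.loads(Path(path).read_text()))


def _coerce_generator_config(raw: dict) -> GeneratorConfig:
    kwargs = dict(raw)
    for key in ("state_weights", "state_means", "state_covs"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = np.asarray(kwargs[key], dtype=float)
    if "ces_state_intervals" in kwargs:
        kwargs["ces_state_intervals"] = tuple(tuple(iv) for iv in kwargs["ces_state_intervals"])
    return GeneratorConfig(**kwargs)


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Load a generator configuration from a YAML file (``generator:`` section or flat)."""
    raw = yaml.safe_load(Path(path).read_text())
    if "generator" in raw:
        raw = raw["generator"]
    return _coerce_generator_config(raw)


def config_hash(config: GeneratorConfig | dict) -> str:
    if isinstance(config, GeneratorConfig):
        config = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in asdict(config).items()}
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: str | Path, seed: int, config, files: dict[str, Path]) -> Path:
    """Provenance manifest: config hash, root seed, content hashes of outputs."""
    out_dir = Path(out_dir)
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "files": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
            for name, p in files.items()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
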