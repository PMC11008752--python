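"""Validated file I/O: long-format cohort CSV, YAML config, run manifests.

The single interchange format is a long CSV with header
``subject_id,time_years,md_db[,fp_rate]`` — times in decimal years from
each eye's first test, MD in dB, optional false-positive rate in percent.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, DataError

REQUIRED_COLUMNS = ("subject_id", "time_years", "md_db")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise DataError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    for col in ("time_years", "md_db"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[vals.isna(), "subject_id"].unique()
        if len(bad):
            raise DataError(
                f"{path}: non-numeric {col} for subjects {bad[:5].tolist()}"
            )
        df[col] = vals
    # times must be non-decreasing within each subject (file order)
    shifted = df.groupby("subject_id")["time_years"].diff()
    bad = df.loc[shifted < 0, "subject_id"].unique()
    if len(bad):
        raise DataError(
            f"{path}: non-monotone time_years within subjects {bad[:5].tolist()}"
        )
    return df


def write_table(df: pd.DataFrame, path, force: bool = False, header_comment: str | None = None):
    """Write a DataFrame as CSV; refuses to overwrite unless ``force``."""
    path = Path(path)
    if path.exists() and not force:
        raise ConfigError(f"{path} exists; pass force to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def load_yaml_config(path) -> dict:
    path = Path(path)
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"no such config file: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse YAML {path}: {exc}") from exc
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(payload: dict, path, force: bool = False):
    path = Path(path)
    if path.exists() and not force:
        raise ConfigError(f"{path} exists; pass force to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_manifest(path, command: str, config: dict, seed, outputs, extra: dict | None = None,
                   force: bool = True):
    """Record everything needed to reproduce a run: command, config (and its
    hash), seed, package/library versions, output paths, diagnostics."""
    import scipy

    import vfprog

    cfg = _jsonable(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    payload = {
        "command": command,
        "config": cfg,
        "config_sha256": digest,
        "seed": seed,
        "outputs": [str(p) for p in outputs],
        "versions": {
            "vfprog": vfprog.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        payload.update(_jsonable(extra))
    write_json(payload, path, force=force)
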