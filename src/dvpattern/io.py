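"""Delimited-text readers/writers and run configuration.

All tables are comma-separated text with a header; file-level metadata
(seed, config hash, package version) travels in leading ``#`` comment
lines so every output records how it was produced.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .profiles import AngularProfile, GridHeatmap

log = logging.getLogger("dvpattern")

NUCLEI_REQUIRED = ("embryo_id", "nucleus_id", "x_um", "y_um", "z_um", "psmad5_au")


def _write_with_metadata(df: pd.DataFrame, path, metadata: Mapping | None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def write_nuclei(df: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    missing = [c for c in NUCLEI_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"nuclei table missing required column(s): {', '.join(missing)}")
    _write_with_metadata(df, path, metadata)


def read_nuclei(path) -> pd.DataFrame:
    """Read a nuclei table, validating required columns.

    Unknown extra columns are kept but logged, so sidecar ground-truth
    columns survive a round trip without being silently relied upon.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in NUCLEI_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    known = set(NUCLEI_REQUIRED)
    extra = [
        c
        for c in df.columns
        if c not in known and not c.startswith("fish_") and not c.startswith("true_")
    ]
    if extra:
        log.warning("%s: ignoring unknown column(s): %s", path, ", ".join(extra))
    return df


def write_profile(profile: AngularProfile, path, metadata: Mapping | None = None) -> None:
    meta = {
        "axis": profile.axis,
        "channel": profile.channel,
        "band_center": profile.band_center,
        "band_width_um": profile.band_width_um,
        **(metadata or {}),
    }
    _write_with_metadata(profile.to_frame(), path, meta)


def write_boundary_calls(calls: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    _write_with_metadata(calls, path, metadata)


def write_heatmap(hm: GridHeatmap, path, metadata: Mapping | None = None) -> None:
    meta = {"channel": hm.channel, **(metadata or {})}
    df = pd.DataFrame(hm.values, columns=[f"dv_bin_{j + 1}" for j in range(8)])
    df.insert(0, "av_row", np.arange(1, 9))
    _write_with_metadata(df, path, meta)


def load_config(path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a key/value mapping")
    return cfg


def dump_config(cfg: Mapping, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    canonical = yaml.safe_dump(dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
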