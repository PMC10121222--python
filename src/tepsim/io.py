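"""Readers/writers and run manifests shared by all subcommands.

Primary exchange format is tab-delimited text (human-diffable); large
arrays can additionally be stored as compressed ``.npz`` containers with a
JSON sidecar carrying the time axis metadata, labels and seeds.  Every run
writes a JSON manifest (config snapshot, seeds, package version, input
checksums) sufficient to reproduce it.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .simulator import Leadfield, TEPData


def read_leadfield(path, noise_sd: float = 0.0) -> Leadfield:
    """Read a channels x regions gain matrix (tab-delimited, optional
    header row of channel labels in the first column)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     float_precision="round_trip")
    if not np.issubdtype(df.dtypes.iloc[0], np.number):
        labels = df.iloc[:, 0].astype(str).tolist()
        gain = df.iloc[:, 1:].to_numpy(dtype=float)
    else:
        labels = None
        gain = df.to_numpy(dtype=float)
    return Leadfield(gain=gain, channel_labels=labels, noise_sd=noise_sd)


def write_leadfield(lf: Leadfield, path) -> None:
    df = pd.DataFrame(lf.gain, index=lf.channel_labels)
    df.to_csv(path, sep="\t", header=False, float_format="%.17g")


def write_timeseries(path, time: np.ndarray, data: np.ndarray,
                     labels: list[str]) -> None:
    """Tab-delimited series: a time column plus one column per series."""
    df = pd.DataFrame(data.T, columns=labels)
    df.insert(0, "time_ms", time)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_tep(path) -> TEPData:
    """Read channel epochs written by :func:`write_timeseries`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "time_ms" not in df.columns:
        raise ConfigError(f"{path}: expected a 'time_ms' column")
    time = df["time_ms"].to_numpy(dtype=float)
    chans = [c for c in df.columns if c != "time_ms"]
    data = df[chans].to_numpy(dtype=float).T
    if len(time) > 1:
        sfreq = 1000.0 / float(np.median(np.diff(time)))
    else:
        sfreq = float("nan")
    return TEPData(data=data, time=time, sfreq=sfreq, channel_labels=chans)


def write_tep(tep: TEPData, path) -> None:
    write_timeseries(path, tep.time, tep.data, tep.channel_labels)


def save_array_container(path, sidecar_path=None, **arrays) -> None:
    """Compressed binary container (.npz) with a JSON sidecar of metadata.

    Keyword values that are numpy arrays go into the container; everything
    else (scalars, strings, lists) goes into the sidecar.
    """
    np_arrays = {k: v for k, v in arrays.items() if isinstance(v, np.ndarray)}
    meta = {k: v for k, v in arrays.items() if not isinstance(v, np.ndarray)}
    np.savez_compressed(path, **np_arrays)
    if sidecar_path is None:
        sidecar_path = str(path) + ".json"
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seeds: dict,
                   input_paths: dict | None = None) -> dict:
    """Write the reproducibility manifest for a completed run."""
    from . import __version__
    manifest = {
        "config": config,
        "seeds": seeds,
        "version": __version__,
        "input_checksums": {
            name: file_checksum(p)
            for name, p in (input_paths or {}).items() if Path(p).exists()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

KNOWN_KEYS = {
    "connectome_weights", "connectome_lengths", "labels", "velocity",
    "leadfield", "tep", "stimulus_field", "threshold_fraction",
    "stim_onset", "stim_duration", "stim_amplitude",
    "epoch_start", "epoch_end", "dt", "burn_in", "seed", "out",
    "log_level", "noise_sd", "params", "n_regions", "n_channels",
    "batch_length", "learning_rate", "max_epochs", "lesion_times",
    "n_perm", "alpha", "sfreq",
}


def parse_config(path=None, overrides: dict | None = None) -> dict:
    """Load a JSON/YAML config file; flag overrides win over file values.

    Unknown keys raise :class:`ConfigError` with a closest-match
    suggestion.
    """
    config: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {path}")
        text = p.read_text()
        config = (json.loads(text) if p.suffix == ".json"
                  else yaml.safe_load(text)) or {}
        if not isinstance(config, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    for k, v in (overrides or {}).items():
        if v is not None:
            config[k] = v
    for key in config:
        if key not in KNOWN_KEYS:
            close = difflib.get_close_matches(key, KNOWN_KEYS, n=1)
            hint = f"; did you mean {close[0]!r}?" if close else ""
            raise ConfigError(f"unknown config key {key!r}{hint} "
                              f"(valid keys: {sorted(KNOWN_KEYS)})")
    for key in ("connectome_weights", "connectome_lengths", "leadfield",
                "tep", "labels", "params"):
        if key in config and not Path(config[key]).exists():
            raise ConfigError(f"{key} path does not exist: {config[key]}")
    return config
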