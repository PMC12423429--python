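"""CSV/YAML readers, writers, schema validation and the run manifest.

All interchange is plain UTF-8 CSV with a header row and "." decimals.

Schemas
-------
CSA slices (``slices.csv``)::

    participant_id,foot,group,modality,trial,slice_index,position_cm,csa_cm2

Fascia thickness (``thickness.csv``)::

    participant_id,foot,group,modality,trial,image_1_mm,image_2_mm

Within one (participant, foot, modality, trial), slice indices must be
contiguous from 0 and positions strictly increasing on the nominal grid.
Validation failures raise :class:`SchemaError` naming the file, rows and
field concerned.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .morphometry import CSASeries
from .simulate import NoiseSpec, StudyConfig, StudyDataset

__all__ = [
    "SchemaError",
    "SLICE_COLUMNS",
    "THICKNESS_COLUMNS",
    "read_csa_csv",
    "read_thickness_csv",
    "series_from_slices",
    "write_dataset",
    "write_tables",
    "load_config",
]

logger = logging.getLogger(__name__)

SLICE_COLUMNS = [
    "participant_id",
    "foot",
    "group",
    "modality",
    "trial",
    "slice_index",
    "position_cm",
    "csa_cm2",
]
THICKNESS_COLUMNS = [
    "participant_id",
    "foot",
    "group",
    "modality",
    "trial",
    "image_1_mm",
    "image_2_mm",
]

SERIES_KEY = ["participant_id", "foot", "group", "modality", "trial"]


class SchemaError(ValueError):
    """A tabular input violates the interchange schema."""


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_csa_csv(path, spacing: float = 0.5, strict_grid: bool = True) -> pd.DataFrame:
    """Read and validate a CSA slice file into a long-format frame.

    Rows are sorted by series key and slice index, so shuffled input yields
    the same series.  Grid violations name the offending foot/trial.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SLICE_COLUMNS, path)
    df = df[SLICE_COLUMNS].sort_values(SERIES_KEY + ["slice_index"]).reset_index(drop=True)
    if df["csa_cm2"].lt(0).any():
        rows = df.index[df["csa_cm2"] < 0].tolist()
        raise SchemaError(f"{path}: negative csa_cm2 at row(s) {rows}")
    for key, sub in df.groupby(SERIES_KEY, sort=False):
        label = dict(zip(SERIES_KEY, key))
        idx = sub["slice_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(sub))):
            raise SchemaError(
                f"{path}: slice_index not contiguous from 0 for {label} (field slice_index)"
            )
        pos = sub["position_cm"].to_numpy(dtype=float)
        gaps = np.diff(pos)
        if np.any(gaps <= 0):
            raise SchemaError(
                f"{path}: positions not strictly increasing for {label} (field position_cm)"
            )
        if strict_grid and np.any(np.abs(gaps - spacing) > 1e-6):
            raise SchemaError(
                f"{path}: slice gap deviates from the {spacing} cm grid for {label} "
                "(field position_cm)"
            )
    return df


def read_thickness_csv(path) -> pd.DataFrame:
    """Read and validate a paired fascia-thickness file."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, THICKNESS_COLUMNS, path)
    df = df[THICKNESS_COLUMNS].sort_values(SERIES_KEY).reset_index(drop=True)
    for col in ("image_1_mm", "image_2_mm"):
        if df[col].lt(0).any():
            rows = df.index[df[col] < 0].tolist()
            raise SchemaError(f"{path}: negative {col} at row(s) {rows}")
    dup = df.duplicated(SERIES_KEY)
    if dup.any():
        raise SchemaError(f"{path}: duplicate (participant,foot,modality,trial) rows {df.index[dup].tolist()}")
    return df


def series_from_slices(df: pd.DataFrame, spacing: float = 0.5, strict_grid: bool = True) -> dict:
    """Group validated slice rows into :class:`CSASeries` keyed by series id."""
    out = {}
    for key, sub in df.groupby(SERIES_KEY, sort=False):
        out[key] = CSASeries(
            positions=sub["position_cm"].to_numpy(dtype=float),
            areas=sub["csa_cm2"].to_numpy(dtype=float),
            spacing=spacing,
            unit=f"{key[0]}:{key[1]}",
            modality=key[3],
            trial=int(key[4]),
            strict_grid=strict_grid,
        )
    return out


def write_dataset(dataset: StudyDataset, outdir) -> dict:
    """Write a study dataset's input tables (slices.csv, thickness.csv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("slices", dataset.slices), ("thickness", dataset.thickness)):
        p = outdir / f"{name}.csv"
        # default float repr round-trips, keeping the read-back lossless
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def _config_to_dict(config: StudyConfig) -> dict:
    d = asdict(config)
    return d


def write_tables(bundle: dict, outdir, config: StudyConfig | None = None, seed: int | None = None) -> dict:
    """Write report tables plus a JSON run manifest with deterministic bytes.

    ``bundle`` maps table names to DataFrames (reliability, comparison,
    summary, bland_altman_points, ...).  The manifest records the seed, a
    config hash, the full config, and per-table row counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in bundle.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p
    manifest = {
        "seed": seed if seed is not None else (config.seed if config else None),
        "tables": {name: int(len(df)) for name, df in bundle.items()},
    }
    if config is not None:
        cfg = _config_to_dict(config)
        manifest["config"] = cfg
        manifest["config_sha256"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mp
    logger.info("wrote %d tables to %s", len(bundle), outdir)
    return paths


# flat config keys -> StudyConfig structure
_GROUP_KEYS = {
    "fascia_mean_nonpf_mm": ("fascia_mean_mm", "non-PF"),
    "fascia_mean_pf_mm": ("fascia_mean_mm", "PF"),
    "fascia_sd_nonpf_mm": ("fascia_sd_mm", "non-PF"),
    "fascia_sd_pf_mm": ("fascia_sd_mm", "PF"),
    "volume_mean_nonpf_cm3": ("volume_mean_cm3", "non-PF"),
    "volume_mean_pf_cm3": ("volume_mean_cm3", "PF"),
    "volume_sd_nonpf_cm3": ("volume_sd_cm3", "non-PF"),
    "volume_sd_pf_cm3": ("volume_sd_cm3", "PF"),
}
_SCALAR_KEYS = (
    "n_feet_pf",
    "n_feet_nonpf",
    "slice_spacing",
    "slices_min",
    "slices_max",
    "intra_participant_corr",
    "seed",
)
_NOISE_KEYS = ("sigma_between", "sigma_within", "modality_bias", "sigma_method")


def load_config(path=None) -> StudyConfig:
    """Build a :class:`StudyConfig` from a flat key-value YAML file.

    Absent keys fall back to the study defaults; unknown keys and
    out-of-range values raise :class:`SchemaError` naming the key.  An
    empty or missing file yields the full default configuration.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a flat key-value mapping")

    base = StudyConfig()
    kwargs = {
        "fascia_mean_mm": dict(base.fascia_mean_mm),
        "fascia_sd_mm": dict(base.fascia_sd_mm),
        "volume_mean_cm3": dict(base.volume_mean_cm3),
        "volume_sd_cm3": dict(base.volume_sd_cm3),
    }
    fascia_noise = asdict(base.fascia_noise)
    volume_noise = asdict(base.volume_noise)
    for key, value in raw.items():
        if key in _SCALAR_KEYS:
            kwargs[key] = value
        elif key in _GROUP_KEYS:
            target, group = _GROUP_KEYS[key]
            kwargs[target][group] = float(value)
        elif key.startswith("fascia_") and key[len("fascia_"):] in _NOISE_KEYS:
            fascia_noise[key[len("fascia_"):]] = float(value)
        elif key.startswith("volume_") and key[len("volume_"):] in _NOISE_KEYS:
            volume_noise[key[len("volume_"):]] = float(value)
        else:
            raise SchemaError(f"{path}: unknown config key {key!r}")
    kwargs["fascia_noise"] = NoiseSpec(**fascia_noise)
    kwargs["volume_noise"] = NoiseSpec(**volume_noise)
    try:
        return StudyConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: invalid configuration value ({exc})") from exc
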