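"""Readers/writers for every artifact the pipeline touches.

Formats: movies and label masks as multipage 16-bit TIFF with calibration
metadata embedded as JSON in the ImageDescription tag; track tables and
derived statistics as UTF-8 CSV with a header row; run configuration as
YAML. All round-trips are lossless for pixel data, table contents and
metadata.

Coordinate convention: CSV coordinates are µm in a right-handed frame with
0 degrees = anterior and 90 = "Up"; the image-row axis (which grows
downward) is flipped once, at the pixel<->physical boundary in
:mod:`myoflow.geometry`, and nowhere else. Frame indices are 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import CalibrationError, ConfigurationError, DimensionError, SchemaError

ROTATION_DIRECTIONS = ("Up", "Down", "unknown")

TRACK_SCHEMA = ["track_id", "frame", "x_um", "y_um", "diameter_um",
                "intensity", "cell_id", "chamber_id"]


@dataclass
class MovieMetadata:
    """Calibration and axis conventions carried by every movie file."""

    pixel_size: float                      # µm / pixel
    frame_interval: float                  # s
    ap_angle: float = 0.0                  # anterior direction, degrees
    rotation_direction: str = "unknown"    # Up | Down | unknown
    channels: dict = field(default_factory=lambda: {"0": "myosin"})

    def __post_init__(self):
        if self.pixel_size is None or self.pixel_size <= 0:
            raise CalibrationError(
                f"pixel_size must be > 0 µm/pixel, got {self.pixel_size}")
        if self.frame_interval is None or self.frame_interval <= 0:
            raise CalibrationError(
                f"frame_interval must be > 0 s, got {self.frame_interval}")
        if self.rotation_direction not in ROTATION_DIRECTIONS:
            raise CalibrationError(
                f"rotation_direction must be one of {ROTATION_DIRECTIONS}, "
                f"got {self.rotation_direction!r}")


@dataclass
class Movie:
    """A calibrated image stack with optional per-frame cell label mask."""

    data: np.ndarray            # (n_frames, rows, cols)
    metadata: MovieMetadata
    labels: np.ndarray | None = None

    def __post_init__(self):
        if self.data.ndim != 3:
            raise DimensionError(
                f"movie data must be (frames, rows, cols), got shape "
                f"{self.data.shape}")
        if self.data.shape[0] < 2:
            raise DimensionError(
                f">=2 frames required, got {self.data.shape[0]}")
        if self.labels is not None and self.labels.shape != self.data.shape:
            raise DimensionError(
                f"label mask shape {self.labels.shape} does not match movie "
                f"shape {self.data.shape}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.metadata.frame_interval


# ---------------------------------------------------------------------------
# Movies
# ---------------------------------------------------------------------------

def write_movie(movie: Movie, path) -> None:
    """Write a multipage 16-bit TIFF with metadata in ImageDescription."""
    data = movie.data
    if data.dtype not in (np.uint8, np.uint16):
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, metadata=None,
                     description=json.dumps(asdict(movie.metadata)))


def read_movie(path, labels_path=None) -> Movie:
    """Read a calibrated movie (>=2 frames; 8/16-bit multipage TIFF).

    Raises :class:`CalibrationError` if no metadata tag is present — units
    are never silently assumed.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        raise DimensionError(f"{path.name}: >=2 frames required, got 1")
    meta = _parse_metadata(desc, path)
    labels = None
    if labels_path is not None:
        labels = read_labels(labels_path, expected_shape=data.shape)
    return Movie(data=data, metadata=meta, labels=labels)


def _parse_metadata(description: str, path: Path) -> MovieMetadata:
    if not description:
        raise CalibrationError(
            f"{path.name}: no embedded calibration metadata "
            "(pixel_size / frame_interval); refusing to assume units")
    try:
        raw = json.loads(description)
    except json.JSONDecodeError as exc:
        raise CalibrationError(
            f"{path.name}: ImageDescription is not valid JSON metadata: "
            f"{exc}") from exc
    known = {k: raw[k] for k in
             ("pixel_size", "frame_interval", "ap_angle",
              "rotation_direction", "channels") if k in raw}
    missing = [k for k in ("pixel_size", "frame_interval") if k not in known]
    if missing:
        raise CalibrationError(
            f"{path.name}: metadata missing required field(s) "
            f"{', '.join(missing)}")
    return MovieMetadata(**known)


# ---------------------------------------------------------------------------
# Label masks
# ---------------------------------------------------------------------------

def write_labels(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint16), metadata=None)


def read_labels(path, expected_shape=None) -> np.ndarray:
    """Per-frame label masks: non-negative integers, 0 = background."""
    labels = tifffile.imread(path)
    if labels.ndim == 2:
        labels = labels[None]
    if np.issubdtype(labels.dtype, np.signedinteger) and labels.min() < 0:
        raise SchemaError(f"{Path(path).name}: negative labels found")
    if expected_shape is not None and labels.shape != tuple(expected_shape):
        raise DimensionError(
            f"{Path(path).name}: label shape {labels.shape} does not match "
            f"movie shape {tuple(expected_shape)}")
    if labels.max() == 0:
        warnings.warn(f"{Path(path).name}: label mask contains no cells",
                      stacklevel=2)
    return labels


# ---------------------------------------------------------------------------
# Track tables
# ---------------------------------------------------------------------------

def write_tracks(tracks: pd.DataFrame, path) -> None:
    missing = [c for c in TRACK_SCHEMA if c not in tracks.columns]
    if missing:
        raise SchemaError(
            f"track table missing mandatory column(s): {', '.join(missing)}")
    tracks.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    """Read a track-table CSV; rows returned sorted by (track_id, frame).

    Unknown columns are preserved. A missing mandatory column raises a
    :class:`SchemaError` naming it. An empty table (header only) is valid.
    """
    table = pd.read_csv(path, comment="#")
    missing = [c for c in TRACK_SCHEMA if c not in table.columns]
    if missing:
        raise SchemaError(
            f"{Path(path).name}: missing mandatory column(s): "
            f"{', '.join(missing)}")
    return table.sort_values(["track_id", "frame"],
                             kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_POSITIVE = ("pixel_size", "frame_interval")


def validate_config(config: dict) -> list[str]:
    """Return every violated constraint (empty list = valid)."""
    problems = []
    for key in _CONFIG_POSITIVE:
        if key in config and not (isinstance(config[key], (int, float))
                                  and config[key] > 0):
            problems.append(f"{key} must be a positive number, "
                            f"got {config[key]!r}")
    if "rotation_direction" in config and \
            config["rotation_direction"] not in ROTATION_DIRECTIONS:
        problems.append(
            f"rotation_direction must be one of {ROTATION_DIRECTIONS}, "
            f"got {config['rotation_direction']!r}")
    if "n_frames" in config and (not isinstance(config["n_frames"], int)
                                 or config["n_frames"] < 2):
        problems.append(f"n_frames must be an integer >= 2, "
                        f"got {config['n_frames']!r}")
    if "seed" in config and not isinstance(config["seed"], int):
        problems.append(f"seed must be an integer, got {config['seed']!r}")
    return problems


def read_config(path) -> dict:
    """Read and validate a YAML run configuration.

    Raises :class:`ConfigurationError` listing *every* violated constraint.
    """
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ConfigurationError(
            f"{Path(path).name}: config must be a key-value mapping")
    problems = validate_config(config)
    if problems:
        raise ConfigurationError(
            f"{Path(path).name}: invalid configuration:\n  - "
            + "\n  - ".join(problems))
    return config


def write_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
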