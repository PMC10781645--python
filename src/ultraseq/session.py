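"""Session containers and file I/O.

A :class:`Session` bundles everything recorded in one experiment: the binary
event matrix (cells x time bins), optional pre-binarization fluorescence,
anatomical cell positions within the field of view, and the wheel behavior
trace. HDF5 is the canonical on-disk container; a directory of CSV files is
accepted for small fixtures. All time coordinates are 0-based bin indices;
seconds are always obtained by multiplying with ``bin_size``.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("ultraseq")


@dataclass
class EventMatrix:
    """Binary activity, one row per cell, one column per time bin."""

    values: np.ndarray
    bin_size: float

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("event matrix must be 2-D (cells x bins)")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("event matrix entries must be 0 or 1")
        self.values = self.values.astype(np.uint8)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_size


@dataclass
class CellPositions:
    """Anatomical (x, y) positions in micrometres within the FOV."""

    xy: np.ndarray
    fov_size: float

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("positions must be (n_cells, 2)")
        if np.any(self.xy < 0) or np.any(self.xy > self.fov_size):
            raise ValueError("positions must lie within [0, fov_size]")


@dataclass
class BehaviorTrace:
    """Wheel position at the native tracking rate plus derived state.

    ``position`` is in cm sampled at ``native_rate`` Hz. Derived fields
    (speed at the imaging rate, running/immobile state) are filled by
    :func:`ultraseq.behavior.derive_speed`.
    """

    position: np.ndarray
    native_rate: float
    speed: Optional[np.ndarray] = None
    acceleration: Optional[np.ndarray] = None
    state: Optional[np.ndarray] = None  # bool, True = running, per event bin

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim != 1:
            raise ValueError("position must be 1-D")
        if self.native_rate <= 0:
            raise ValueError("native_rate must be positive")


@dataclass
class Session:
    events: EventMatrix
    fluorescence: Optional[np.ndarray] = None
    positions: Optional[CellPositions] = None
    behavior: Optional[BehaviorTrace] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n_cells, n_bins = self.events.values.shape
        if self.fluorescence is not None:
            self.fluorescence = np.asarray(self.fluorescence, dtype=float)
            if self.fluorescence.shape[0] != n_cells:
                raise ValueError("fluorescence cell count disagrees with events")
        if self.positions is not None and self.positions.xy.shape[0] != n_cells:
            raise ValueError("positions cell count disagrees with events")
        if self.behavior is not None:
            beh_dur = self.behavior.position.size / self.behavior.native_rate
            if abs(beh_dur - self.events.duration) > max(2.0, 0.05 * self.events.duration):
                raise ValueError("behavior duration disagrees with events")

    @property
    def bin_size(self) -> float:
        return self.events.bin_size


def write_session(session: Session, path) -> None:
    """Write a session to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("events", data=session.events.values, compression="gzip")
        fh["events"].attrs["bin_size"] = session.events.bin_size
        if session.fluorescence is not None:
            fh.create_dataset("fluorescence", data=session.fluorescence,
                              compression="gzip")
        if session.positions is not None:
            g = fh.create_group("positions")
            g.create_dataset("xy", data=session.positions.xy)
            g.attrs["fov_size"] = session.positions.fov_size
        if session.behavior is not None:
            g = fh.create_group("behavior")
            g.create_dataset("position", data=session.behavior.position)
            g.attrs["native_rate"] = session.behavior.native_rate
        fh.attrs["meta"] = json.dumps(session.meta, sort_keys=True)


def read_session(path) -> Session:
    """Read a session from HDF5 or a directory of CSV files.

    The CSV layout mirrors the HDF5 one: ``events.csv`` (cells x bins,
    no header), ``meta.json`` with at least ``bin_size``, and optional
    ``fluorescence.csv``, ``positions.csv`` (columns x, y plus fov_size in
    meta) and ``behavior.csv`` (column position, native_rate in meta).
    """
    path = Path(path)
    if path.is_dir():
        return _read_session_csv(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as fh:
        if "events" not in fh:
            raise KeyError("missing required dataset 'events'")
        events = EventMatrix(fh["events"][()], float(fh["events"].attrs["bin_size"]))
        fluorescence = fh["fluorescence"][()] if "fluorescence" in fh else None
        positions = None
        if "positions" in fh:
            positions = CellPositions(fh["positions/xy"][()],
                                      float(fh["positions"].attrs["fov_size"]))
        behavior = None
        if "behavior" in fh:
            behavior = BehaviorTrace(fh["behavior/position"][()],
                                     float(fh["behavior"].attrs["native_rate"]))
        meta = json.loads(fh.attrs.get("meta", "{}"))
    return Session(events, fluorescence, positions, behavior, meta)


def _read_session_csv(path: Path) -> Session:
    events_file = path / "events.csv"
    meta_file = path / "meta.json"
    if not events_file.exists() or not meta_file.exists():
        raise FileNotFoundError("CSV session requires events.csv and meta.json")
    meta = json.loads(meta_file.read_text())
    values = pd.read_csv(events_file, header=None).to_numpy()
    events = EventMatrix(values, float(meta["bin_size"]))
    fluorescence = None
    if (path / "fluorescence.csv").exists():
        fluorescence = pd.read_csv(path / "fluorescence.csv", header=None).to_numpy()
    positions = None
    if (path / "positions.csv").exists():
        xy = pd.read_csv(path / "positions.csv")[["x", "y"]].to_numpy()
        positions = CellPositions(xy, float(meta["fov_size"]))
    behavior = None
    if (path / "behavior.csv").exists():
        pos = pd.read_csv(path / "behavior.csv")["position"].to_numpy()
        behavior = BehaviorTrace(pos, float(meta["native_rate"]))
    extra = {k: v for k, v in meta.items()
             if k not in ("bin_size", "fov_size", "native_rate")}
    return Session(events, fluorescence, positions, behavior, extra)


def _sanitize(obj):
    """Convert a nested result record into JSON-serializable form.

    NaN and infinities become null (a logged, documented convention);
    numpy scalars and arrays are converted to Python numbers and lists.
    """
    if isinstance(obj, dict):
        return {str(k): _sanitize(obj[k]) for k in obj}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        if math.isnan(v) or math.isinf(v):
            logger.warning("non-finite value serialized as null")
            return None
        return v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(results: dict, path) -> None:
    """Write a nested result record as JSON with deterministic key order."""
    path = Path(path)
    payload = _sanitize(results)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
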