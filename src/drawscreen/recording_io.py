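"""Recording and feature-sheet I/O plus active-drawing segmentation.

A :class:`RawRecording` holds one participant x shape x phase multichannel
time series sampled at a nominal 30 Hz: pen-tip position (relative screen
coordinates in [0, 1]), pen pressure in [0, 1], pen azimuth (orientation,
degrees [0, 360)), pen tilt (altitude, degrees [0, 90]) and webcam-derived
gaze rotation about the X and Y axes (degrees [-90, 90], missing allowed).
Demonstration-phase recordings additionally carry the advancing-line tip
position (``line_x``/``line_y``) that the child watches.

All pen features are computed inside *active drawing segments*: maximal
runs of samples with the pen in contact with the tablet (pressure above a
threshold). :func:`segment_active_drawing` finds those runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SHAPE_IDS = ("equilateral_triangle", "inverted_triangle", "square", "sun")
PHASES = ("demo", "drawing")

#: The 16 model variables, in canonical feature-sheet column order.
FEATURE_NAMES = (
    "Mpenpressure", "SDpenpressure", "Mpenpressurechange",
    "Mdrawingspeed", "SDdrawingspeed", "Mdrawingacceleration",
    "Mpentilt", "SDpentilt", "Mpentiltchange",
    "Mpenorientation", "SDpenorientation", "Mpenorientationchange",
    "Corrdemoeyehorizontal", "Corrdemoeyevertical",
    "Corrdrawingeyehorizontal", "Corrdrawingeyevertical",
)

RECORDING_COLUMNS = (
    "participant_id", "shape", "phase", "t", "x", "y", "pressure",
    "azimuth", "tilt", "gaze_x", "gaze_y", "line_x", "line_y",
)

#: (low, high, high_inclusive) bounds for each numeric channel.
_CHANNEL_RANGES = {
    "x": (0.0, 1.0, True),
    "y": (0.0, 1.0, True),
    "pressure": (0.0, 1.0, True),
    "azimuth": (0.0, 360.0, False),
    "tilt": (0.0, 90.0, True),
    "gaze_x": (-90.0, 90.0, True),
    "gaze_y": (-90.0, 90.0, True),
    "line_x": (0.0, 1.0, True),
    "line_y": (0.0, 1.0, True),
}


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


class DataError(ValueError):
    """Values in a file violate the recording invariants."""


@dataclass
class RawRecording:
    """Synchronized multichannel time series for one participant x shape x phase."""

    participant_id: str
    shape_id: str
    phase: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    azimuth: np.ndarray
    tilt: np.ndarray
    gaze_x: np.ndarray = field(default=None)  # NaN = missing
    gaze_y: np.ndarray = field(default=None)
    line_x: np.ndarray = field(default=None)  # demo phase only
    line_y: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("t", "x", "y", "pressure", "azimuth", "tilt"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != n:
                raise DataError(f"channel {name!r} length {len(arr)} != {n}")
        for name in ("gaze_x", "gaze_y", "line_x", "line_y"):
            arr = getattr(self, name)
            if arr is None:
                arr = np.full(n, np.nan)
            arr = np.asarray(arr, dtype=float)
            if len(arr) != n:
                raise DataError(f"channel {name!r} length {len(arr)} != {n}")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        """Raise :class:`DataError` citing row numbers on any violation."""
        if self.shape_id not in SHAPE_IDS:
            raise DataError(f"unknown shape_id {self.shape_id!r}")
        if self.phase not in PHASES:
            raise DataError(f"unknown phase {self.phase!r}")
        if len(self) >= 2 and not np.all(np.diff(self.t) > 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise DataError(f"time not strictly increasing at row {bad}")
        for name, (lo, hi, hi_incl) in _CHANNEL_RANGES.items():
            vals = getattr(self, name)
            with np.errstate(invalid="ignore"):
                bad = (vals < lo) | (vals > hi if hi_incl else vals >= hi)
            bad &= ~np.isnan(vals)
            if bad.any():
                rows = np.flatnonzero(bad)[:5].tolist()
                raise DataError(
                    f"channel {name!r} out of range [{lo}, {hi}"
                    f"{']' if hi_incl else ')'} at row(s) {rows}"
                )
        if self.phase == "demo" and (
            np.isnan(self.line_x).all() or np.isnan(self.line_y).all()
        ):
            raise DataError("demo-phase recording must carry line_x/line_y")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "shape": self.shape_id,
                "phase": self.phase,
                "t": self.t, "x": self.x, "y": self.y,
                "pressure": self.pressure, "azimuth": self.azimuth,
                "tilt": self.tilt, "gaze_x": self.gaze_x, "gaze_y": self.gaze_y,
                "line_x": self.line_x, "line_y": self.line_y,
            },
            columns=list(RECORDING_COLUMNS),
        )


@dataclass(frozen=True)
class DrawingSegment:
    """A maximal run of pen-down samples, inclusive indices into a recording."""

    recording: RawRecording
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if self.end_index < self.start_index:
            raise DataError("segment end before start")

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def sl(self) -> slice:
        return slice(self.start_index, self.end_index + 1)

    def channel(self, name: str) -> np.ndarray:
        return getattr(self.recording, name)[self.sl]


def segment_active_drawing(
    rec: RawRecording, pressure_threshold: float = 0.0, min_len: int = 3
) -> list[DrawingSegment]:
    """Maximal runs with ``pressure > pressure_threshold`` of length >= ``min_len``.

    Returns segments in temporal order; an empty list if no run qualifies.
    Samples in shorter runs (spurious contacts) are discarded, and no
    differencing is ever done across a segment boundary downstream.
    """
    active = np.asarray(rec.pressure) > pressure_threshold
    if not active.any():
        return []
    padded = np.concatenate(([False], active, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return [
        DrawingSegment(rec, int(s), int(e))
        for s, e in zip(starts, ends)
        if e - s + 1 >= min_len
    ]


# ---------------------------------------------------------------------------
# Recording CSV I/O


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write one recording to CSV (empty string encodes missing gaze/line)."""
    rec.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_recording(path: str | Path, dialect: dict[str, str] | None = None) -> RawRecording:
    """Read and validate a recording CSV.

    ``dialect`` maps file column names to canonical names for ingesting
    foreign exports; matching is case-insensitive.
    """
    df = pd.read_csv(path)
    rename = {c: c.strip().lower() for c in df.columns}
    if dialect:
        rename.update({k: v.lower() for k, v in dialect.items()})
    df = df.rename(columns=rename)
    mandatory = {"participant_id", "shape", "phase", "t", "x", "y", "pressure",
                 "azimuth", "tilt"}
    missing = mandatory - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    for opt in ("gaze_x", "gaze_y", "line_x", "line_y"):
        if opt not in df.columns:
            df[opt] = np.nan
    rec = RawRecording(
        participant_id=str(df["participant_id"].iloc[0]),
        shape_id=str(df["shape"].iloc[0]),
        phase=str(df["phase"].iloc[0]),
        t=df["t"].to_numpy(float),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        pressure=df["pressure"].to_numpy(float),
        azimuth=df["azimuth"].to_numpy(float),
        tilt=df["tilt"].to_numpy(float),
        gaze_x=df["gaze_x"].to_numpy(float),
        gaze_y=df["gaze_y"].to_numpy(float),
        line_x=df["line_x"].to_numpy(float),
        line_y=df["line_y"].to_numpy(float),
    )
    try:
        rec.validate()
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from None
    return rec


# ---------------------------------------------------------------------------
# Feature-sheet I/O

# Alias map for published data-sheet dialects. Keys are lowercased foreign
# headers; note the supplement's "vartical" spelling and the bare
# "Drawingspeed" name for the speed mean.
DEFAULT_FEATURE_ALIASES: dict[str, str] = {
    "drawingspeed": "Mdrawingspeed",
    "mdrawingspeed": "Mdrawingspeed",
    "corrdemoeyevartical": "Corrdemoeyevertical",
    "corrdrawingeyevartical": "Corrdrawingeyevertical",
    "label": "group",
    "class": "group",
}


def write_feature_sheet(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature sheet: participant_id, group, then the 16 variables."""
    cols = ["participant_id", "group", *FEATURE_NAMES]
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"feature table missing column(s) {sorted(missing)}")
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_feature_sheet(
    path: str | Path, aliases: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a per-shape feature sheet into a validated DataFrame.

    Columns are matched case-insensitively, then through the alias map
    (:data:`DEFAULT_FEATURE_ALIASES` unless overridden). The group column
    is binarized to {"high", "low"}; 0/1 labels map to low/high.
    """
    df = pd.read_csv(path)
    alias = {k.lower(): v for k, v in (aliases or DEFAULT_FEATURE_ALIASES).items()}
    canon_by_lower = {n.lower(): n for n in FEATURE_NAMES}
    canon_by_lower.update({"participant_id": "participant_id", "group": "group"})
    rename: dict[str, str] = {}
    for col in df.columns:
        key = col.strip().lower()
        key = alias.get(key, key)
        if isinstance(key, str) and key.lower() in canon_by_lower:
            rename[col] = canon_by_lower[key.lower()]
        elif key in FEATURE_NAMES or key in ("participant_id", "group"):
            rename[col] = key
    df = df.rename(columns=rename)
    missing = [n for n in FEATURE_NAMES if n not in df.columns]
    if "group" not in df.columns:
        missing.append("group")
    if missing:
        raise SchemaError(
            f"{path}: feature sheet missing column(s) {missing}; expected "
            f"participant_id, group and the 16 variables {list(FEATURE_NAMES)}"
        )
    if "participant_id" not in df.columns:
        df["participant_id"] = [f"P{i:03d}" for i in range(1, len(df) + 1)]
    group = df["group"]
    if group.dtype != object:
        df["group"] = np.where(group.astype(float) > 0, "high", "low")
    else:
        df["group"] = group.str.strip().str.lower()
    bad = ~df["group"].isin(["high", "low"])
    if bad.any():
        raise DataError(f"{path}: unknown group label(s) {sorted(df['group'][bad].unique())}")
    return df[["participant_id", "group", *FEATURE_NAMES]].copy()
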