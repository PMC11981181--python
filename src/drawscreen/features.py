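"""Extraction of the 16 drawing-process variables from a recording pair.

For one participant x shape, a demonstration-phase and a drawing-phase
recording yield a 16-dimensional feature vector:

* pen pressure: mean, SD, mean per-sample change;
* pen-tip movement: mean and SD of drawing speed (line length per unit
  time between consecutive pen-down samples), mean change in speed;
* pen barrel pose: mean/SD/mean-change of tilt (linear statistics) and of
  azimuth-orientation (circular statistics);
* gaze coupling: Pearson correlation between gaze rotation and the
  advancing-line position while watching the demonstration, and between
  gaze rotation and the pen-tip position while actively drawing, in the
  horizontal and vertical directions.

"Mean change" statistics are means of absolute first differences between
consecutive samples within an active segment — signed differences would
telescope to approximately zero and carry no dispersion information. No
difference is ever taken across a pen-up gap. Sample (n-1) standard
deviations throughout. Both conventions are switchable in
:class:`FeatureConfig` for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording_io import (
    FEATURE_NAMES,
    DrawingSegment,
    RawRecording,
    segment_active_drawing,
)


class InsufficientDataError(ValueError):
    """Not enough active samples to compute a feature."""


class NoActiveDrawingError(ValueError):
    """A drawing-phase recording contains no active drawing segment."""


@dataclass(frozen=True)
class FeatureConfig:
    """Options for feature extraction.

    pressure_threshold, min_segment_len:
        Segmentation rule: pen-down means pressure strictly above the
        threshold; runs shorter than ``min_segment_len`` samples (default
        3, i.e. 0.1 s at 30 Hz) are treated as spurious contacts.
    change_mode:
        ``"absolute"`` (default) or ``"signed"`` first differences for the
        mean-change features.
    orientation_stats:
        ``"circular"`` (default): mean direction, circular SD in degrees,
        wrapped angular differences. ``"linear"``: naive arithmetic on the
        raw [0, 360) values.
    min_corr_pairs:
        Minimum number of non-missing gaze/reference pairs for a coupling
        correlation to be valid.
    invalid_corr_value:
        Imputation for invalid correlations (default 0 = no coupling); the
        validity mask still records them as invalid.
    """

    pressure_threshold: float = 0.0
    min_segment_len: int = 3
    change_mode: str = "absolute"
    orientation_stats: str = "circular"
    min_corr_pairs: int = 10
    invalid_corr_value: float = 0.0


@dataclass
class FeatureVector:
    """The 16 named variables for one participant x shape, plus validity flags."""

    participant_id: str
    shape_id: str
    values: dict[str, float]
    valid: dict[str, bool]

    def to_series(self) -> pd.Series:
        return pd.Series({n: self.values[n] for n in FEATURE_NAMES}, name=self.participant_id)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _pooled(segments: list[np.ndarray]) -> np.ndarray:
    if not segments:
        raise InsufficientDataError("no active segments")
    return np.concatenate(segments)


def _mean_change(segments: list[np.ndarray], signed: bool) -> float:
    diffs = [np.diff(s) for s in segments if len(s) >= 2]
    if not diffs:
        return 0.0
    d = np.concatenate(diffs)
    if d.size == 0:
        return 0.0
    return float(np.mean(d) if signed else np.mean(np.abs(d)))


def pressure_features(
    pressure_segments: list[np.ndarray], cfg: FeatureConfig = FeatureConfig()
) -> tuple[float, float, float]:
    """(Mpenpressure, SDpenpressure, Mpenpressurechange) over pooled active samples."""
    p = _pooled(pressure_segments)
    if p.size < 2:
        raise InsufficientDataError(f"need >= 2 active samples, got {p.size}")
    return (
        float(np.mean(p)),
        float(np.std(p, ddof=1)),
        _mean_change(pressure_segments, cfg.change_mode == "signed"),
    )


def kinematics_features(
    xy_segments: list[tuple[np.ndarray, np.ndarray]],
    t_segments: list[np.ndarray],
    cfg: FeatureConfig = FeatureConfig(),
) -> tuple[float, float, float]:
    """(Mdrawingspeed, SDdrawingspeed, Mdrawingacceleration).

    Speed for a consecutive pen-down pair is the Euclidean distance between
    pen-tip positions divided by the sample interval (the "unit time"
    between drawing points). The change feature averages successive speed
    differences within a segment.
    """
    speeds: list[np.ndarray] = []
    for (x, y), t in zip(xy_segments, t_segments):
        if len(x) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise InsufficientDataError("non-positive sample interval in segment")
            speeds.append(np.hypot(np.diff(x), np.diff(y)) / dt)
    v = np.concatenate(speeds) if speeds else np.empty(0)
    if v.size < 2:
        raise InsufficientDataError("need >= 3 active samples in some segment")
    m = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    acc = _mean_change(speeds, cfg.change_mode == "signed")
    return m, sd, acc


def _circular_mean_deg(a: np.ndarray) -> float:
    rad = np.deg2rad(a)
    mean = math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    return mean % 360.0


def _circular_sd_deg(a: np.ndarray) -> float:
    rad = np.deg2rad(a)
    r = math.hypot(float(np.mean(np.sin(rad))), float(np.mean(np.cos(rad))))
    r = min(r, 1.0)
    return math.degrees(math.sqrt(max(-2.0 * math.log(r), 0.0))) if r > 0 else float("inf")


def _wrap_diff_deg(a: np.ndarray) -> np.ndarray:
    """First differences wrapped to (-180, 180]."""
    d = np.diff(a)
    return (d + 180.0) % 360.0 - 180.0


def pose_features(
    tilt_segments: list[np.ndarray],
    azimuth_segments: list[np.ndarray],
    cfg: FeatureConfig = FeatureConfig(),
) -> tuple[float, float, float, float, float, float]:
    """(Mpentilt, SDpentilt, Mpentiltchange, Mpenorientation, SDpenorientation,
    Mpenorientationchange).

    Tilt (altitude, [0, 90]) is treated linearly. Azimuth lives on the
    circle: with circular statistics the mean is the direction of the mean
    resultant vector, the SD is sqrt(-2 ln R) in degrees, and changes are
    wrapped to [0, 180] before averaging, so a 350° -> 10° step counts as
    20°, not 340°.
    """
    tilt = _pooled(tilt_segments)
    azi = _pooled(azimuth_segments)
    if tilt.size < 2 or azi.size < 2:
        raise InsufficientDataError("need >= 2 active samples for pose features")
    signed = cfg.change_mode == "signed"
    m_tilt = float(np.mean(tilt))
    sd_tilt = float(np.std(tilt, ddof=1))
    ch_tilt = _mean_change(tilt_segments, signed)
    if cfg.orientation_stats == "circular":
        m_azi = _circular_mean_deg(azi)
        sd_azi = _circular_sd_deg(azi)
        wdiffs = [_wrap_diff_deg(s) for s in azimuth_segments if len(s) >= 2]
        if wdiffs:
            d = np.concatenate(wdiffs)
            ch_azi = float(np.mean(d) if signed else np.mean(np.abs(d)))
        else:
            ch_azi = 0.0
    else:
        m_azi = float(np.mean(azi))
        sd_azi = float(np.std(azi, ddof=1))
        ch_azi = _mean_change(azimuth_segments, signed)
    return m_tilt, sd_tilt, ch_tilt, m_azi, sd_azi, ch_azi


def gaze_coupling(
    gaze: np.ndarray,
    reference: np.ndarray,
    cfg: FeatureConfig = FeatureConfig(),
) -> tuple[float, bool]:
    """Pearson correlation between a gaze channel and a reference signal.

    Pairs with missing (NaN) values in either signal are dropped pairwise.
    Returns ``(value, valid)``; with fewer than ``cfg.min_corr_pairs``
    valid pairs, or zero variance in either signal, the feature is invalid
    and imputed with ``cfg.invalid_corr_value``.
    """
    gaze = np.asarray(gaze, float)
    reference = np.asarray(reference, float)
    ok = ~(np.isnan(gaze) | np.isnan(reference))
    g, r = gaze[ok], reference[ok]
    if g.size < cfg.min_corr_pairs:
        return cfg.invalid_corr_value, False
    if np.ptp(g) == 0 or np.ptp(r) == 0:
        return cfg.invalid_corr_value, False
    val = float(np.corrcoef(g, r)[0, 1])
    if not np.isfinite(val):
        return cfg.invalid_corr_value, False
    return float(np.clip(val, -1.0, 1.0)), True


def extract_feature_vector(
    demo: RawRecording | None,
    drawing: RawRecording,
    cfg: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Assemble the 16-variable vector for one participant x shape.

    Pen features use pen-down samples of the drawing phase only.
    Demonstration-phase coupling correlates gaze with the advancing-line
    position over all demo frames; drawing-phase coupling correlates gaze
    with the pen-tip position over active samples only. ``demo=None``
    flags the two demo correlations invalid.
    """
    segments = segment_active_drawing(
        drawing, cfg.pressure_threshold, cfg.min_segment_len
    )
    if not segments:
        raise NoActiveDrawingError(
            f"no active drawing for participant {drawing.participant_id!r} "
            f"shape {drawing.shape_id!r}"
        )

    def seg_ch(name: str) -> list[np.ndarray]:
        return [s.channel(name) for s in segments]

    mp, sdp, chp = pressure_features(seg_ch("pressure"), cfg)
    ms, sds, acc = kinematics_features(
        [(s.channel("x"), s.channel("y")) for s in segments], seg_ch("t"), cfg
    )
    mt, sdt, cht, mo, sdo, cho = pose_features(seg_ch("tilt"), seg_ch("azimuth"), cfg)

    values = {
        "Mpenpressure": mp, "SDpenpressure": sdp, "Mpenpressurechange": chp,
        "Mdrawingspeed": ms, "SDdrawingspeed": sds, "Mdrawingacceleration": acc,
        "Mpentilt": mt, "SDpentilt": sdt, "Mpentiltchange": cht,
        "Mpenorientation": mo, "SDpenorientation": sdo, "Mpenorientationchange": cho,
    }
    valid = {n: True for n in values}

    active = np.concatenate([np.arange(s.start_index, s.end_index + 1) for s in segments])
    corr_specs = {
        "Corrdrawingeyehorizontal": (drawing.gaze_x[active], drawing.x[active]),
        "Corrdrawingeyevertical": (drawing.gaze_y[active], drawing.y[active]),
    }
    if demo is not None:
        corr_specs["Corrdemoeyehorizontal"] = (demo.gaze_x, demo.line_x)
        corr_specs["Corrdemoeyevertical"] = (demo.gaze_y, demo.line_y)
    for name in ("Corrdemoeyehorizontal", "Corrdemoeyevertical",
                 "Corrdrawingeyehorizontal", "Corrdrawingeyevertical"):
        if name in corr_specs:
            values[name], valid[name] = gaze_coupling(*corr_specs[name], cfg)
        else:
            values[name], valid[name] = cfg.invalid_corr_value, False

    return FeatureVector(
        participant_id=drawing.participant_id,
        shape_id=drawing.shape_id,
        values=values,
        valid=valid,
    )


def extract_feature_table(
    recordings: list[RawRecording], cfg: FeatureConfig = FeatureConfig()
) -> dict[str, pd.DataFrame]:
    """Extract one feature table per shape from a batch of recordings.

    Recordings are paired by (participant, shape): each pair should hold a
    demo and a drawing phase. Returns ``{shape_id: DataFrame}`` with
    columns ``participant_id`` plus the 16 variables, participants in
    first-appearance order.
    """
    by_key: dict[tuple[str, str], dict[str, RawRecording]] = {}
    order: list[tuple[str, str]] = []
    for rec in recordings:
        key = (rec.participant_id, rec.shape_id)
        if key not in by_key:
            by_key[key] = {}
            order.append(key)
        by_key[key][rec.phase] = rec
    rows: dict[str, list[pd.Series]] = {}
    for pid, shape in order:
        pair = by_key[(pid, shape)]
        if "drawing" not in pair:
            continue
        fv = extract_feature_vector(pair.get("demo"), pair["drawing"], cfg)
        rows.setdefault(shape, []).append(
            pd.Series({"participant_id": pid, **{n: fv.values[n] for n in FEATURE_NAMES}})
        )
    return {
        shape: pd.DataFrame(series_list).reset_index(drop=True)
        for shape, series_list in rows.items()
    }
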