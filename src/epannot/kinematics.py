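"""Kinematic variables computed per timestep from a motion recording.

The pipeline first low-pass filters every position coordinate (zero-phase
2nd-order Butterworth, 6 Hz by default); orientations are left unfiltered.
From the filtered streams six variable families are derived:

* relative speed of each fingernail sensor w.r.t. the stimulus-center
  sensor, defined as the absolute rate of change of the Euclidean distance
  between the two (range rate, m/s);
* per hand, the volume of the smallest convex hull enclosing the whole
  (rigid cuboid) stimulus and that hand's thumbnail sensor, plus its rate;
* stimulus elevation (z of the embedded sensor, mm) and its rate;
* per nail sensor, distance to the nearest of 45 grid points per cuboid
  face (6 x 45 = 270 surface points);
* per hand, whether the virtual midpoint between index and thumb nails
  lies inside the cuboid volume;
* per hand, the index-finger angle (geodesic angle between the nail and
  proximal-phalanx sensor orientations, deg) and its rate.

Rates of change are central differences on the filtered signals (one-sided
at the ends).  The trial's initial-lift sample is detected from elevation
and its rate; the per-hand hull volume at that sample is the Pressure
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.transform import Rotation

from .io_formats import (
    HANDS,
    NAIL_SENSORS,
    ConfigError,
    DataError,
    MotionRecording,
    StimulusGeometry,
    ThresholdConfig,
    hand_prefix,
)

__all__ = [
    "FeatureTable",
    "lowpass_filter",
    "central_rate",
    "relative_speed",
    "stimulus_corners",
    "hull_size",
    "surface_distance",
    "point_in_stimulus",
    "midpoint",
    "orientation_angle",
    "detect_lift",
    "extract_features",
]


# ---------------------------------------------------------------------------
# Quaternion helpers (scalar-first storage; scipy uses scalar-last)
# ---------------------------------------------------------------------------


def _rotation(quat_wxyz: np.ndarray, tol: float = 1e-6) -> Rotation:
    q = np.asarray(quat_wxyz, dtype=float)
    norms = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise DataError("quaternion not unit norm")
    return Rotation.from_quat(np.roll(q, -1, axis=-1))


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------


def lowpass_filter(
    series: np.ndarray, fs: float, cutoff: float, order: int = 2
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The two passes square the magnitude response, so the single-pass -3 dB
    point at the cutoff becomes an amplitude ratio of ~0.5.
    """
    series = np.asarray(series, dtype=float)
    if cutoff >= fs / 2.0:
        raise ConfigError("filter_cutoff_hz must be below the Nyquist frequency")
    if series.shape[-1] < 3 * order:
        raise ValueError("series too short for the requested filter order")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    padlen = min(3 * (max(len(a), len(b)) - 1), series.shape[-1] - 1)
    return filtfilt(b, a, series, axis=-1, padlen=padlen)


def central_rate(series: np.ndarray, fs: float) -> np.ndarray:
    """Rate of change: central differences, one-sided at the two ends."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(series, 1.0 / fs, axis=-1)


def relative_speed(
    nail_positions: np.ndarray,
    stimulus_positions: np.ndarray,
    fs: float,
    mode: str = "range_rate",
) -> np.ndarray:
    """Relative speed of a nail sensor w.r.t. the stimulus sensor, in m/s.

    ``range_rate`` (default) is |d/dt ||p_nail - p_stim|||: motion at a
    constant distance from the stimulus center (e.g. circling it) reads as
    zero.  ``velocity_norm`` is ||d/dt (p_nail - p_stim)||.
    """
    nail = np.asarray(nail_positions, dtype=float)
    stim = np.asarray(stimulus_positions, dtype=float)
    if nail.shape != stim.shape:
        raise ValueError("nail and stimulus position series must match in shape")
    if mode == "range_rate":
        dist = np.linalg.norm(nail - stim, axis=-1)
        return np.abs(central_rate(dist, fs)) / 1000.0
    if mode == "velocity_norm":
        rel = (nail - stim).T  # (3, n)
        vel = central_rate(rel, fs)
        return np.linalg.norm(vel, axis=0) / 1000.0
    raise ConfigError(f"unknown rel_speed_mode {mode!r}")


# ---------------------------------------------------------------------------
# Stimulus geometry features
# ---------------------------------------------------------------------------


def stimulus_corners(
    position: np.ndarray, quat_wxyz: np.ndarray, geom: StimulusGeometry
) -> np.ndarray:
    """World-frame cuboid corners for one pose (8, 3) or a series (n, 8, 3)."""
    rot = _rotation(quat_wxyz)
    local = geom.corners_local()  # (8, 3)
    pos = np.asarray(position, dtype=float)
    if pos.ndim == 1:
        return pos + rot.apply(local)
    mats = rot.as_matrix()  # (n, 3, 3)
    return pos[:, None, :] + np.einsum("nij,kj->nki", mats, local)


def hull_size(corners: np.ndarray, thumb_point: np.ndarray) -> float:
    """Volume (mm^3) of the convex hull of the 8 cuboid corners + thumb point.

    Equals the cuboid volume exactly when the thumb point lies inside or on
    the cuboid; strictly greater otherwise.
    """
    pts = np.vstack([np.asarray(corners, dtype=float), np.asarray(thumb_point, float)])
    try:
        return float(ConvexHull(pts).volume)
    except QhullError as exc:
        raise DataError(f"degenerate point set for hull volume: {exc}") from exc


def _to_local(
    points: np.ndarray, position: np.ndarray, quat_wxyz: np.ndarray
) -> np.ndarray:
    """Express world points in the stimulus local frame (broadcasting over time)."""
    rot = _rotation(quat_wxyz)
    diff = np.asarray(points, dtype=float) - np.asarray(position, dtype=float)
    return rot.inv().apply(diff)


def surface_distance(
    point: np.ndarray,
    position: np.ndarray,
    quat_wxyz: np.ndarray,
    geom: StimulusGeometry,
    layout: Tuple[int, int] = (5, 9),
) -> float:
    """Distance (mm) from a point to the nearest stimulus surface grid point.

    Each face is represented by an nu x nv lattice (45 points by default);
    the reported distance is >= the true point-to-surface distance, with
    excess bounded by half the largest grid-cell diagonal.
    """
    local = _to_local(np.atleast_2d(point), position, quat_wxyz)
    grid = geom.face_grid_local(layout)
    d = np.linalg.norm(local[:, None, :] - grid[None, :, :], axis=-1)
    return float(d.min())


def point_in_stimulus(
    point: np.ndarray,
    position: np.ndarray,
    quat_wxyz: np.ndarray,
    geom: StimulusGeometry,
) -> bool:
    """Closed-box containment test in the stimulus local frame."""
    local = _to_local(np.atleast_2d(point), position, quat_wxyz)[0]
    return bool(np.all(np.abs(local) <= geom.half_dims + 1e-9))


def midpoint(index_nail: np.ndarray, thumb_nail: np.ndarray) -> np.ndarray:
    """Virtual midpoint between the index and thumb nail sensors."""
    return (np.asarray(index_nail, float) + np.asarray(thumb_nail, float)) / 2.0


def orientation_angle(q1_wxyz: np.ndarray, q2_wxyz: np.ndarray) -> np.ndarray:
    """Geodesic rotation angle between two orientations, deg in [0, 180].

    Insensitive to quaternion sign and symmetric in its arguments.
    """
    r1 = _rotation(q1_wxyz)
    r2 = _rotation(q2_wxyz)
    ang = np.degrees((r1.inv() * r2).magnitude())
    return ang if np.ndim(ang) else float(ang)


def detect_lift(
    elevation: np.ndarray,
    elevation_rate: np.ndarray,
    cfg: ThresholdConfig,
    fs: float,
) -> Optional[int]:
    """Sample index of the initial lift of the stimulus off the table.

    Baseline = median elevation over the first ``lift_baseline_window_ms``;
    the lift index is the first sample where elevation exceeds the baseline
    by ``lift_height_delta_mm`` while rising.  None if never satisfied.
    """
    elevation = np.asarray(elevation, dtype=float)
    window = int(round(cfg.lift_baseline_window_ms / 1000.0 * fs))
    if len(elevation) < window:
        raise ValueError("trial shorter than the lift baseline window")
    baseline = float(np.median(elevation[:window]))
    hits = np.flatnonzero(
        (elevation > baseline + cfg.lift_height_delta_mm)
        & (np.asarray(elevation_rate) > 0)
    )
    return int(hits[0]) if hits.size else None


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Per-timestep kinematic variables for both hands."""

    fs: float
    t: np.ndarray
    rel_speed: Dict[str, np.ndarray]  # nail sensor -> m/s
    hull_size: Dict[str, np.ndarray]  # hand -> mm^3
    hull_rate: Dict[str, np.ndarray]  # hand -> mm^3/s
    elevation: np.ndarray  # mm
    elevation_rate: np.ndarray  # mm/s
    surf_dist: Dict[str, np.ndarray]  # nail sensor -> mm
    midpoint_inside: Dict[str, np.ndarray]  # hand -> bool
    finger_angle: Dict[str, np.ndarray]  # hand -> deg
    finger_angle_rate: Dict[str, np.ndarray]  # hand -> deg/s
    lift_index: Optional[int]
    hull_at_lift: Dict[str, Optional[float]]

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def to_dataframe(self) -> pd.DataFrame:
        cols: Dict[str, np.ndarray] = {"time_s": self.t}
        for s in NAIL_SENSORS:
            cols[f"rel_speed[{s}]"] = self.rel_speed[s]
        for hand in HANDS:
            cols[f"hull_size[{hand}]"] = self.hull_size[hand]
            cols[f"hull_rate[{hand}]"] = self.hull_rate[hand]
        cols["elevation"] = self.elevation
        cols["elevation_rate"] = self.elevation_rate
        for s in NAIL_SENSORS:
            cols[f"surf_dist[{s}]"] = self.surf_dist[s]
        for hand in HANDS:
            cols[f"midpoint_inside[{hand}]"] = self.midpoint_inside[hand]
            cols[f"finger_angle[{hand}]"] = self.finger_angle[hand]
            cols[f"finger_angle_rate[{hand}]"] = self.finger_angle_rate[hand]
        return pd.DataFrame(cols)


def _batch_surface_distances(
    points: np.ndarray,
    stim_pos: np.ndarray,
    rot: Rotation,
    grid_local: np.ndarray,
) -> np.ndarray:
    """Min distance to the posed surface grid per timestep.  (n,) mm."""
    local = rot.inv().apply(points - stim_pos)  # (n, 3)
    d = np.linalg.norm(local[:, None, :] - grid_local[None, :, :], axis=-1)
    return d.min(axis=1)


def extract_features(
    rec: MotionRecording, geom: StimulusGeometry, cfg: ThresholdConfig
) -> FeatureTable:
    """Compute the full per-timestep FeatureTable for one recording."""
    rec.validate()
    cfg.validate()
    geom.validate()

    fs = rec.fs
    n = rec.n_samples

    # zero-phase filtering of every position coordinate; orientations raw
    pos = {
        s: lowpass_filter(rec.pos[s].T, fs, cfg.filter_cutoff_hz, cfg.filter_order).T
        for s in rec.pos
    }

    stim_pos = pos["stimulus"]
    stim_rot = _rotation(rec.quat["stimulus"])

    rel_speed = {
        s: relative_speed(pos[s], stim_pos, fs, cfg.rel_speed_mode)
        for s in NAIL_SENSORS
    }

    corners = stimulus_corners(stim_pos, rec.quat["stimulus"], geom)  # (n, 8, 3)
    hull: Dict[str, np.ndarray] = {}
    for hand in HANDS:
        thumb = pos[f"{hand_prefix(hand)}_thumb_nail"]
        hull[hand] = np.array(
            [hull_size(corners[k], thumb[k]) for k in range(n)]
        )
    hull_rate = {hand: central_rate(hull[hand], fs) for hand in HANDS}

    elevation = stim_pos[:, 2].copy()
    elevation_rate = central_rate(elevation, fs)

    grid_local = geom.face_grid_local(cfg.grid_layout)
    surf = {
        s: _batch_surface_distances(pos[s], stim_pos, stim_rot, grid_local)
        for s in NAIL_SENSORS
    }

    half = geom.half_dims
    midpoint_inside: Dict[str, np.ndarray] = {}
    finger_angle: Dict[str, np.ndarray] = {}
    finger_angle_rate: Dict[str, np.ndarray] = {}
    for hand in HANDS:
        p = hand_prefix(hand)
        mid = midpoint(pos[f"{p}_index_nail"], pos[f"{p}_thumb_nail"])
        local = stim_rot.inv().apply(mid - stim_pos)
        midpoint_inside[hand] = np.all(np.abs(local) <= half + 1e-9, axis=1)
        ang = orientation_angle(rec.quat[f"{p}_index_nail"], rec.quat[f"{p}_index_phalanx"])
        finger_angle[hand] = np.asarray(ang, dtype=float)
        finger_angle_rate[hand] = central_rate(finger_angle[hand], fs)

    lift_index = detect_lift(elevation, elevation_rate, cfg, fs)
    hull_at_lift: Dict[str, Optional[float]] = {
        hand: (float(hull[hand][lift_index]) if lift_index is not None else None)
        for hand in HANDS
    }

    return FeatureTable(
        fs=fs,
        t=rec.t.copy(),
        rel_speed=rel_speed,
        hull_size=hull,
        hull_rate=hull_rate,
        elevation=elevation,
        elevation_rate=elevation_rate,
        surf_dist=surf,
        midpoint_inside=midpoint_inside,
        finger_angle=finger_angle,
        finger_angle_rate=finger_angle_rate,
        lift_index=lift_index,
        hull_at_lift=hull_at_lift,
    )
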