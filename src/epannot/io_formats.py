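"""Data containers, file formats and unit conventions.

Everything downstream relies on the conventions fixed here:

* positions in mm, time in s, speeds in m/s, angles in deg, angle rates in
  deg/s, volumes in mm^3;
* right-handed world frame, z vertical-up, table surface at z = 0;
* quaternions stored scalar-first (w, x, y, z), unit norm;
* time intervals are half-open [t_start, t_end); a per-sample label applies
  to that sample's timestamp, which makes durations additive and the
  mask <-> interval conversion exact.

Motion recordings and annotation tracks are exchanged as delimited text
(TSV by default, comma also accepted); the threshold/geometry configuration
is YAML whose keys mirror the dataclass field names exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("epannot")

# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

EPS: Tuple[str, ...] = ("LM", "PR", "UH", "EN")
HANDS: Tuple[str, ...] = ("left", "right")

#: The seven instrumented sites: index nail, index proximal phalanx and
#: thumb nail on each hand, plus the sensor embedded at the stimulus center.
SENSORS: Tuple[str, ...] = (
    "L_index_nail",
    "L_index_phalanx",
    "L_thumb_nail",
    "R_index_nail",
    "R_index_phalanx",
    "R_thumb_nail",
    "stimulus",
)

NAIL_SENSORS: Tuple[str, ...] = (
    "L_index_nail",
    "L_thumb_nail",
    "R_index_nail",
    "R_thumb_nail",
)

#: The seven annotatable behaviors: LM/PR/UH per hand, EN bimanual.
LABELS: Tuple[Tuple[str, str], ...] = (
    ("LM", "left"),
    ("LM", "right"),
    ("PR", "left"),
    ("PR", "right"),
    ("UH", "left"),
    ("UH", "right"),
    ("EN", "bimanual"),
)


def opposite_hand(hand: str) -> str:
    if hand == "left":
        return "right"
    if hand == "right":
        return "left"
    raise ValueError(f"no opposite of hand {hand!r}")


def hand_prefix(hand: str) -> str:
    return {"left": "L", "right": "R"}[hand]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class FormatError(ValueError):
    """Structurally invalid input file."""


class DataError(ValueError):
    """Well-formed file whose contents violate a data invariant."""


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


# ---------------------------------------------------------------------------
# ThresholdConfig
# ---------------------------------------------------------------------------


@dataclass
class ThresholdConfig:
    """All numeric criteria, durations and post-processing constants.

    The defaults are the printed values of the annotation method: distance
    gate 20 mm, high/low relative speed 0.10/0.05 m/s, finger-angle rate
    gate 80 deg/s, 2nd-order 6 Hz low-pass filtering, 50 ms gap filling,
    per-EP minimum durations within the printed 17-250 ms range, dominance
    ranking LM-UH-PR-EN and two post-processing passes.
    """

    d_close_mm: float = 20.0
    v_high_ms: float = 0.10
    v_low_ms: float = 0.05
    omega_max_deg_s: float = 80.0
    filter_cutoff_hz: float = 6.0
    filter_order: int = 2
    gap_fill_max_ms: float = 50.0
    min_duration_ms: Dict[str, float] = field(
        default_factory=lambda: {"LM": 100.0, "PR": 17.0, "UH": 250.0, "EN": 250.0}
    )
    dominance: List[str] = field(default_factory=lambda: ["LM", "UH", "PR", "EN"])
    lift_height_delta_mm: float = 10.0
    lift_baseline_window_ms: float = 500.0
    pr_decrease_window_ms: float = 100.0
    grid_points_per_face: int = 45
    grid_layout: Tuple[int, int] = (5, 9)
    postprocess_passes: int = 2
    #: "range_rate" = |d/dt of the Euclidean nail-stimulus distance| (the
    #: printed definition); "velocity_norm" = norm of the relative velocity
    #: (alternative without the tangential-motion blind spot).
    rel_speed_mode: str = "range_rate"
    #: conflict resolution: clear the losing label over the "overlap" only
    #: (default) or the whole losing "interval".
    conflict_mode: str = "overlap"
    #: timewise agreement options (see agreement module).
    agreement_hand_sensitive: bool = True
    agreement_count_coblank: bool = True

    def validate(self) -> "ThresholdConfig":
        positive = (
            "d_close_mm",
            "v_high_ms",
            "v_low_ms",
            "omega_max_deg_s",
            "filter_cutoff_hz",
            "gap_fill_max_ms",
            "lift_height_delta_mm",
            "lift_baseline_window_ms",
            "pr_decrease_window_ms",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.grid_points_per_face < 1:
            raise ConfigError("grid_points_per_face must be >= 1")
        nu, nv = self.grid_layout
        if nu * nv != self.grid_points_per_face:
            raise ConfigError(
                "grid_layout must multiply out to grid_points_per_face"
            )
        if self.postprocess_passes < 1:
            raise ConfigError("postprocess_passes must be >= 1")
        if sorted(self.dominance) != sorted(EPS):
            raise ConfigError("dominance must be a permutation of the 4 EPs")
        if set(self.min_duration_ms) != set(EPS):
            raise ConfigError("min_duration_ms must map every EP")
        for ep, ms in self.min_duration_ms.items():
            if not 17.0 <= ms <= 250.0:
                raise ConfigError(
                    f"min_duration_ms[{ep}] must lie in the 17-250 ms range"
                )
        if self.rel_speed_mode not in ("range_rate", "velocity_norm"):
            raise ConfigError("rel_speed_mode must be range_rate or velocity_norm")
        if self.conflict_mode not in ("overlap", "interval"):
            raise ConfigError("conflict_mode must be overlap or interval")
        return self

    def rank(self, ep: str) -> int:
        """Dominance rank, 0 = highest priority."""
        return self.dominance.index(ep)


# ---------------------------------------------------------------------------
# StimulusGeometry
# ---------------------------------------------------------------------------


@dataclass
class StimulusGeometry:
    """Rigid cuboid stimulus model.

    The embedded sensor sits at the cuboid center, so the sensor pose *is*
    the cuboid pose.  The local frame has its origin at the center with axes
    along the edges; the long edge (h) is the local z axis.  Outer default
    dimensions 52 x 62 x 120 mm: core 30 x 40 x 120 mm plus an equal
    covering thickness on the four long faces sized to the 382 cm^3 outer
    volume of the instrumented stimulus.
    """

    w_mm: float = 52.0
    d_mm: float = 62.0
    h_mm: float = 120.0

    def validate(self) -> "StimulusGeometry":
        for name in ("w_mm", "d_mm", "h_mm"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        return self

    @property
    def dims(self) -> np.ndarray:
        return np.array([self.w_mm, self.d_mm, self.h_mm], dtype=float)

    @property
    def half_dims(self) -> np.ndarray:
        return self.dims / 2.0

    @property
    def volume_mm3(self) -> float:
        return float(self.w_mm * self.d_mm * self.h_mm)

    @property
    def half_diagonal_mm(self) -> float:
        return float(np.linalg.norm(self.half_dims))

    def corners_local(self) -> np.ndarray:
        """The 8 cuboid corners in the local frame, shape (8, 3)."""
        hw, hd, hh = self.half_dims
        signs = np.array(
            [
                [sx, sy, sz]
                for sx in (-1.0, 1.0)
                for sy in (-1.0, 1.0)
                for sz in (-1.0, 1.0)
            ]
        )
        return signs * np.array([hw, hd, hh])

    def face_grid_local(self, layout: Tuple[int, int] = (5, 9)) -> np.ndarray:
        """Surface-point lattice in the local frame, shape (6*nu*nv, 3).

        Each of the six faces carries an nu x nv lattice (endpoints
        included, so odd x odd layouts contain the face center and edge
        midlines).  The larger count is assigned to the longer in-face
        dimension.
        """
        nu, nv = sorted(layout)
        pts: List[np.ndarray] = []
        half = self.half_dims
        for axis in range(3):  # face normal axis
            u_axis, v_axis = [a for a in range(3) if a != axis]
            # longer in-face dimension gets nv points
            if half[u_axis] > half[v_axis]:
                u_axis, v_axis = v_axis, u_axis
            us = np.linspace(-half[u_axis], half[u_axis], nu)
            vs = np.linspace(-half[v_axis], half[v_axis], nv)
            uu, vv = np.meshgrid(us, vs, indexing="ij")
            for sign in (-1.0, 1.0):
                grid = np.zeros((nu * nv, 3))
                grid[:, axis] = sign * half[axis]
                grid[:, u_axis] = uu.ravel()
                grid[:, v_axis] = vv.ravel()
                pts.append(grid)
        return np.concatenate(pts, axis=0)

    def max_grid_gap_mm(self, layout: Tuple[int, int] = (5, 9)) -> float:
        """Upper bound on surface-to-nearest-grid-point distance.

        Half the largest grid-cell diagonal over the six faces; the grid
        approximation of the point-to-surface distance can exceed the true
        value by at most this much.
        """
        nu, nv = sorted(layout)
        half = self.half_dims
        worst = 0.0
        for axis in range(3):
            u_axis, v_axis = [a for a in range(3) if a != axis]
            lo, hi = sorted((2 * half[u_axis], 2 * half[v_axis]))
            pitch_u = lo / (nu - 1)
            pitch_v = hi / (nv - 1)
            worst = max(worst, 0.5 * float(np.hypot(pitch_u, pitch_v)))
        return worst


# ---------------------------------------------------------------------------
# MotionRecording
# ---------------------------------------------------------------------------

MOTION_COLUMNS = ("time_s", "sensor_id", "x_mm", "y_mm", "z_mm", "qw", "qx", "qy", "qz")


@dataclass
class MotionRecording:
    """Time-stamped 6-DoF samples for the 7 named sensors of one trial."""

    trial_id: str
    fs: float
    t: np.ndarray  # (n,) seconds
    pos: Dict[str, np.ndarray]  # sensor -> (n, 3) mm
    quat: Dict[str, np.ndarray]  # sensor -> (n, 4) scalar-first, unit norm

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Trial duration under half-open sample semantics: n/fs."""
        return self.n_samples / self.fs

    def validate(self, quat_tol: float = 1e-6) -> "MotionRecording":
        for sensor in SENSORS:
            if sensor not in self.pos or sensor not in self.quat:
                raise FormatError(f"missing sensor stream: {sensor}")
        n = self.n_samples
        for sensor in SENSORS:
            if len(self.pos[sensor]) != n or len(self.quat[sensor]) != n:
                raise FormatError(f"sensor {sensor} stream length mismatch")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise FormatError("timestamps must be strictly increasing")
            nominal = 1.0 / self.fs
            if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                raise FormatError(
                    "timestamps not uniform within 1% of the nominal interval"
                )
        for sensor in SENSORS:
            norms = np.linalg.norm(self.quat[sensor], axis=1)
            if np.any(np.abs(norms - 1.0) > quat_tol):
                raise DataError(f"non-unit quaternion in sensor {sensor}")
        return self


def read_motion(path, fs_expected: Optional[float] = None) -> MotionRecording:
    """Read a long-format motion file (one row per sensor per sample).

    The sampling frequency is inferred from the median inter-sample
    interval; if ``fs_expected`` is given the inferred value must agree
    within 1%.  Quaternions off unit norm by more than 1e-3 raise
    :class:`DataError`; smaller deviations are silently renormalized.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"cannot parse motion file {path}: {exc}") from exc
    missing_cols = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"motion file missing columns: {missing_cols}")

    trial_id = str(df["trial_id"].iloc[0]) if "trial_id" in df.columns else path.stem

    pos: Dict[str, np.ndarray] = {}
    quat: Dict[str, np.ndarray] = {}
    t_ref: Optional[np.ndarray] = None
    for sensor in SENSORS:
        sub = df[df["sensor_id"] == sensor].sort_values("time_s")
        if sub.empty:
            raise FormatError(f"missing sensor stream: {sensor}")
        t = sub["time_s"].to_numpy(dtype=float)
        if t_ref is None:
            t_ref = t
        elif len(t) != len(t_ref) or np.any(np.abs(t - t_ref) > 1e-9):
            raise FormatError(f"sensor {sensor} timestamps differ from other streams")
        pos[sensor] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        q = sub[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
        norms = np.linalg.norm(q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise DataError(f"quaternion norm off unit by > 1e-3 in sensor {sensor}")
        quat[sensor] = q / norms[:, None]

    assert t_ref is not None
    if len(t_ref) >= 2:
        dts = np.diff(t_ref)
        fs = 1.0 / float(np.median(dts))
    elif fs_expected is not None:
        fs = float(fs_expected)
    else:
        raise FormatError("cannot infer sampling frequency from a single sample")
    if fs_expected is not None and abs(fs - fs_expected) > 0.01 * fs_expected:
        raise FormatError(
            f"inferred fs {fs:.3f} Hz differs from expected {fs_expected} Hz"
        )
    rec = MotionRecording(trial_id=trial_id, fs=fs, t=t_ref, pos=pos, quat=quat)
    return rec.validate()


def write_motion(rec: MotionRecording, path) -> Path:
    """Write a recording in the long text format read by :func:`read_motion`."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = []
    for sensor in SENSORS:
        p = rec.pos[sensor]
        q = rec.quat[sensor]
        rows.append(
            pd.DataFrame(
                {
                    "trial_id": rec.trial_id,
                    "time_s": rec.t,
                    "sensor_id": sensor,
                    "x_mm": p[:, 0],
                    "y_mm": p[:, 1],
                    "z_mm": p[:, 2],
                    "qw": q[:, 0],
                    "qx": q[:, 1],
                    "qy": q[:, 2],
                    "qz": q[:, 3],
                }
            )
        )
    out = pd.concat(rows, ignore_index=True).sort_values(
        ["time_s", "sensor_id"], kind="stable"
    )
    out.to_csv(path, sep=sep, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# AnnotationTrack
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    ep: str
    hand: str
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def label(self) -> Tuple[str, str]:
        return (self.ep, self.hand)


@dataclass
class AnnotationTrack:
    """Intervals of (EP, hand) for one trial and one rater."""

    trial_id: str
    rater_id: str
    trial_duration: float
    intervals: List[Interval] = field(default_factory=list)

    def validate(self) -> "AnnotationTrack":
        if not self.trial_duration > 0:
            raise DataError("trial_duration must be positive")
        for iv in self.intervals:
            if iv.ep not in EPS:
                raise DataError(f"unknown EP {iv.ep!r}")
            if iv.ep == "EN":
                if iv.hand != "bimanual":
                    raise DataError("EN intervals must have hand=bimanual")
            elif iv.hand not in HANDS:
                raise DataError(f"{iv.ep} intervals must have hand left or right")
            if not (0.0 <= iv.t_start < iv.t_end):
                raise DataError("intervals need 0 <= t_start < t_end")
            if iv.t_end > self.trial_duration + 1e-9:
                raise DataError("interval t_end exceeds trial_duration")
        for a, b in zip(self._sorted(), self._sorted()[1:]):
            if a.label == b.label and b.t_start < a.t_end - 1e-12:
                raise DataError(
                    f"overlapping {a.label} intervals; call normalized() first"
                )
        return self

    def _sorted(self) -> List[Interval]:
        return sorted(
            self.intervals, key=lambda iv: (iv.t_start, iv.ep, iv.hand, iv.t_end)
        )

    def normalized(self) -> "AnnotationTrack":
        """Merge overlapping or abutting intervals with identical (ep, hand)."""
        by_label: Dict[Tuple[str, str], List[Interval]] = {}
        for iv in self._sorted():
            by_label.setdefault(iv.label, []).append(iv)
        merged: List[Interval] = []
        for label, ivs in by_label.items():
            cur = ivs[0]
            for nxt in ivs[1:]:
                if nxt.t_start <= cur.t_end + 1e-12:
                    cur = Interval(cur.ep, cur.hand, cur.t_start, max(cur.t_end, nxt.t_end))
                else:
                    merged.append(cur)
                    cur = nxt
            merged.append(cur)
        merged.sort(key=lambda iv: (iv.t_start, iv.ep, iv.hand))
        return AnnotationTrack(self.trial_id, self.rater_id, self.trial_duration, merged)

    def labels_at(self, t: float) -> frozenset:
        """Set of active (ep, hand) labels at time t (half-open intervals)."""
        return frozenset(
            iv.label for iv in self.intervals if iv.t_start <= t < iv.t_end
        )

    def total_durations(self) -> Dict[Tuple[str, str], float]:
        out: Dict[Tuple[str, str], float] = {}
        for iv in self.intervals:
            out[iv.label] = out.get(iv.label, 0.0) + iv.duration
        return out


def write_annotation(track: AnnotationTrack, path) -> Path:
    """Write one annotation track as delimited text.

    Trial metadata is carried in leading ``# key=value`` comment lines so
    that the round trip is exact even for an empty track; intervals are
    written sorted by (t_start, ep, hand) with times in seconds at 6
    decimals.
    """
    track.validate()
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    header = (
        f"# trial_id={track.trial_id}\n"
        f"# rater_id={track.rater_id}\n"
        f"# trial_duration_s={track.trial_duration:.6f}\n"
    )
    cols = ["trial_id", "rater_id", "ep", "hand", "t_start_s", "t_end_s"]
    lines = [header + sep.join(cols)]
    for iv in track._sorted():
        lines.append(
            sep.join(
                [
                    track.trial_id,
                    track.rater_id,
                    iv.ep,
                    iv.hand,
                    f"{iv.t_start:.6f}",
                    f"{iv.t_end:.6f}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_annotation_header(path: Path) -> Dict[str, str]:
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def read_annotations(path) -> List[AnnotationTrack]:
    """Read all (trial, rater) tracks from one annotation file.

    Overlapping or abutting intervals with the same (ep, hand) are merged
    with a logged warning; an interval ending after the trial duration is a
    :class:`DataError`.
    """
    path = Path(path)
    meta = _parse_annotation_header(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = ["trial_id", "rater_id", "ep", "hand", "t_start_s", "t_end_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file missing columns: {missing}")

    duration = float(meta["trial_duration_s"]) if "trial_duration_s" in meta else None
    tracks: List[AnnotationTrack] = []
    if df.empty:
        if "trial_id" not in meta or duration is None:
            raise FormatError(
                "empty annotation file without # trial_id/# trial_duration_s metadata"
            )
        tracks.append(
            AnnotationTrack(
                meta["trial_id"], meta.get("rater_id", "unknown"), duration, []
            )
        )
        return tracks

    for (trial_id, rater_id), sub in df.groupby(["trial_id", "rater_id"], sort=True):
        ivs = [
            Interval(str(r.ep), str(r.hand), float(r.t_start_s), float(r.t_end_s))
            for r in sub.itertuples()
        ]
        dur = duration if duration is not None else max(iv.t_end for iv in ivs)
        track = AnnotationTrack(str(trial_id), str(rater_id), dur, ivs)
        merged = track.normalized()
        if len(merged.intervals) != len(ivs):
            logger.warning(
                "merged %d overlapping/abutting same-label intervals in %s (%s)",
                len(ivs) - len(merged.intervals),
                trial_id,
                rater_id,
            )
        tracks.append(merged.validate())
    return tracks


def read_annotation(path) -> AnnotationTrack:
    """Read a single-track annotation file (error if several tracks)."""
    tracks = read_annotations(path)
    if len(tracks) != 1:
        raise FormatError(
            f"expected one (trial, rater) track in {path}, found {len(tracks)}"
        )
    return tracks[0]


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------


def _coerce_dataclass(cls, data: dict, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown {section} field: {key}")
        if key == "grid_layout":
            value = tuple(int(v) for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def read_config(path) -> Tuple[ThresholdConfig, StimulusGeometry]:
    """Read a YAML config with ``thresholds:`` and ``stimulus:`` sections.

    Both sections are optional; omitted fields keep their defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError("config root must be a mapping")
    cfg = _coerce_dataclass(ThresholdConfig, data.get("thresholds") or {}, "thresholds")
    geom = _coerce_dataclass(StimulusGeometry, data.get("stimulus") or {}, "stimulus")
    return cfg.validate(), geom.validate()


def write_config(cfg: ThresholdConfig, geom: StimulusGeometry, path) -> Path:
    path = Path(path)
    data = {
        "thresholds": {
            **{
                f.name: getattr(cfg, f.name)
                for f in dataclasses.fields(cfg)
                if f.name != "grid_layout"
            },
            "grid_layout": list(cfg.grid_layout),
        },
        "stimulus": {f.name: getattr(geom, f.name) for f in dataclasses.fields(geom)},
    }
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
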