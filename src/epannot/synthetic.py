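"""Synthetic scenario renderer and ground-truth scorer.

Renders scripted Exploratory-Procedure episodes into 7-sensor motion
recordings so the whole annotation pipeline can be exercised without real
recordings.  A trial follows the study protocol: hands resting ~20 cm to
either side of the stimulus, bimanual pickup, lift to carrying height, one
scripted exploration episode, replacement, release.

Behavior templates (hand poses relative to the stimulus center; the
holding hand grips across the two x faces, the exploring hand across the
two y faces):

* LM  -- the exploring index nail rubs sinusoidally along the long axis,
  6 mm off a face and offset from the face center so the rub modulates
  the distance to the stimulus-center sensor (relative speed is a range
  rate); the exploring thumb rests 10 mm off the same face, the other
  hand holds statically.
* PR  -- the exploring thumb presses through its face into the nominal
  cuboid with a smooth ramp, so that hand's thumb hull drops below its
  at-lift value after a decreasing approach.
* UH  -- the holding hand grips statically while the other hand returns
  to its start position (midpoint outside the volume, thumb far).
* EN  -- both hands statically straddle the cuboid: midpoints inside, all
  four nails at rest, finger angles frozen.

Two overlays keep unscripted stretches free of incidental criteria hits.
A radial outward grip-adjustment "jitter" on the holding thumb runs during
transports where only that hand is on the stimulus: its peak radial speed
sits strictly between the low and high speed gates (~0.09 m/s), so it
breaks the Unsupported-Holding "all slow" criterion without ever meeting
the Lateral-Motion "fast" one, and the sub-gate windows around its speed
reversals are too short to survive minimum-duration pruning.  An
index-finger orientation "wiggle" on the lifting hand runs while both
hands grip outside scripted EN episodes, driving the finger-angle rate
repeatedly past the Enclosure gate.  Both overlays are phase-locked to
zero rate at the scripted-episode boundaries, which bounds the onset and
offset bias of the recovered episode to a few tens of ms.

Additive Gaussian position/orientation noise is optional and seeded; the
pipeline's 6 Hz zero-phase filtering is the intended noise defense, no
tracker-specific noise spectrum is emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    EPS,
    LABELS,
    SENSORS,
    AnnotationTrack,
    Interval,
    MotionRecording,
    StimulusGeometry,
    ThresholdConfig,
    hand_prefix,
    opposite_hand,
)

__all__ = [
    "ScriptError",
    "Segment",
    "ScenarioScript",
    "ep_scenario",
    "idle_scenario",
    "render_scenario",
    "evaluate_against_truth",
    "EvalMetrics",
]

BEHAVIORS = ("idle", "transport") + EPS


class ScriptError(ValueError):
    """Infeasible or malformed scenario script."""


@dataclass(frozen=True)
class Segment:
    behavior: str
    hand: Optional[str]
    t_start: float
    t_end: float
    params: Dict[str, float] = field(default_factory=dict)


@dataclass
class ScenarioScript:
    """Scripted lift--explore--replace trial with at most one EP episode."""

    trial_id: str = "synthetic"
    duration: float = 8.0
    t_lift: float = 2.0
    lift_height_mm: float = 80.0
    lift_ramp_s: float = 0.6
    t_replace: float = 5.8
    segments: List[Segment] = field(default_factory=list)
    pos_noise_sd_mm: float = 0.0
    ori_noise_sd_deg: float = 0.0
    seed: int = 0

    # behavior template parameters (mm, Hz); overridable per segment
    rub_amplitude_mm: float = 15.0
    rub_frequency_hz: float = 5.0
    press_depth_mm: float = 3.0
    sway_jitter_mm: float = 9.6
    sway_frequency_hz: float = 3.0

    def ep_segment(self) -> Optional[Segment]:
        eps = [s for s in self.segments if s.behavior in EPS]
        if len(eps) > 1:
            raise ScriptError("at most one EP episode per scripted trial")
        return eps[0] if eps else None

    def validate(self, cfg: Optional[ThresholdConfig] = None) -> "ScenarioScript":
        cfg = cfg or ThresholdConfig()
        if not self.duration > 0:
            raise ScriptError("duration must be positive")
        last = 0.0
        for seg in self.segments:
            if seg.behavior not in BEHAVIORS:
                raise ScriptError(f"unknown behavior {seg.behavior!r}")
            if not (0.0 <= seg.t_start < seg.t_end <= self.duration + 1e-9):
                raise ScriptError("segment outside [0, duration]")
            if seg.t_start < last - 1e-9:
                raise ScriptError("segments must be ordered and non-overlapping")
            last = seg.t_end
        ep = self.ep_segment()
        if ep is not None:
            if ep.t_start < self.t_lift:
                raise ScriptError(
                    f"{ep.behavior} episode needs a held stimulus: must start after t_lift"
                )
            if ep.behavior in ("LM", "PR", "UH") and ep.hand not in ("left", "right"):
                raise ScriptError(f"{ep.behavior} episode needs hand left or right")
            if ep.behavior == "EN" and ep.hand not in (None, "bimanual"):
                raise ScriptError("EN episode is bimanual")
            if ep.behavior == "LM":
                amp = ep.params.get("rub_amplitude_mm", self.rub_amplitude_mm)
                freq = ep.params.get("rub_frequency_hz", self.rub_frequency_hz)
                peak = 2.0 * math.pi * freq * amp / 1000.0  # m/s
                if peak <= cfg.v_high_ms:
                    raise ScriptError(
                        "LM rub amplitude*frequency implies peak speed "
                        f"{peak:.3f} m/s, not above v_high {cfg.v_high_ms} m/s"
                    )
            if ep.behavior == "PR":
                depth = ep.params.get("press_depth_mm", self.press_depth_mm)
                if not depth > 0:
                    raise ScriptError("PR press depth must be positive")
            if self.t_lift + self.lift_ramp_s >= self.t_replace:
                raise ScriptError("lift must complete before the replace phase")
        return self

    def to_yaml(self, path) -> None:
        data = {
            "trial_id": self.trial_id,
            "duration": self.duration,
            "t_lift": self.t_lift,
            "lift_height_mm": self.lift_height_mm,
            "lift_ramp_s": self.lift_ramp_s,
            "t_replace": self.t_replace,
            "pos_noise_sd_mm": self.pos_noise_sd_mm,
            "ori_noise_sd_deg": self.ori_noise_sd_deg,
            "seed": self.seed,
            "rub_amplitude_mm": self.rub_amplitude_mm,
            "rub_frequency_hz": self.rub_frequency_hz,
            "press_depth_mm": self.press_depth_mm,
            "sway_jitter_mm": self.sway_jitter_mm,
            "sway_frequency_hz": self.sway_frequency_hz,
            "segments": [
                {
                    "behavior": s.behavior,
                    "hand": s.hand,
                    "t_start": s.t_start,
                    "t_end": s.t_end,
                    "params": dict(s.params),
                }
                for s in self.segments
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioScript":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "ep" in data:  # builder shorthand
            return ep_scenario(
                data["ep"],
                hand=data.get("hand"),
                trial_id=data.get("trial_id"),
                seed=int(data.get("seed", 0)),
                pos_noise_sd_mm=float(data.get("pos_noise_sd_mm", 0.0)),
                ori_noise_sd_deg=float(data.get("ori_noise_sd_deg", 0.0)),
            )
        segs = [
            Segment(
                s["behavior"],
                s.get("hand"),
                float(s["t_start"]),
                float(s["t_end"]),
                dict(s.get("params") or {}),
            )
            for s in data.pop("segments", [])
        ]
        return cls(segments=segs, **data)


def idle_scenario(
    trial_id: str = "idle",
    duration: float = 8.0,
    seed: int = 0,
    pos_noise_sd_mm: float = 0.0,
) -> ScenarioScript:
    """Hands resting at the start positions for the whole trial."""
    return ScenarioScript(
        trial_id=trial_id,
        duration=duration,
        seed=seed,
        pos_noise_sd_mm=pos_noise_sd_mm,
        segments=[Segment("idle", None, 0.0, duration)],
    ).validate()


def ep_scenario(
    ep: str,
    hand: Optional[str] = None,
    trial_id: Optional[str] = None,
    seed: int = 0,
    pos_noise_sd_mm: float = 0.0,
    ori_noise_sd_deg: float = 0.0,
) -> ScenarioScript:
    """Canonical single-episode trial: lift at 2.0 s, episode 3.2-5.2 s,
    replace at 5.8 s, hands home by 7.0 s, trial over at 8.0 s."""
    if ep not in EPS:
        raise ScriptError(f"unknown EP {ep!r}")
    if ep == "EN":
        hand = "bimanual"
    elif hand is None:
        hand = "left" if ep == "UH" else "right"
    script = ScenarioScript(
        trial_id=trial_id or f"{ep}_{hand}_s{seed}",
        seed=seed,
        pos_noise_sd_mm=pos_noise_sd_mm,
        ori_noise_sd_deg=ori_noise_sd_deg,
        segments=[
            Segment("idle", None, 0.0, 1.2),
            Segment("transport", None, 1.2, 3.2),
            Segment(ep, hand, 3.2, 5.2),
            Segment("transport", None, 5.2, 7.0),
            Segment("idle", None, 7.0, 8.0),
        ],
    )
    return script.validate()


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass(frozen=True)
class _Anchor:
    """Dwell at pose p over [t0, t1]; t0 == t1 makes a fly-through waypoint."""

    t0: float
    t1: float
    kind: str  # "abs" or "rel" (to the stimulus center)
    p: Tuple[float, float, float]


def _resolve(anchor: _Anchor, n: int, stim_center: np.ndarray) -> np.ndarray:
    p = np.asarray(anchor.p, float)
    if anchor.kind == "rel":
        return stim_center + p
    return np.broadcast_to(p, (n, 3)).copy()


def _keyframe_path(
    anchors: Sequence[_Anchor], t: np.ndarray, stim_center: np.ndarray
) -> np.ndarray:
    """Dwell at each anchor, smoothstep transit in between.

    Anchors are resolved framewise, so relative anchors follow the moving
    stimulus and a transit blends smoothly onto a moving target.
    """
    n = len(t)
    pos = _resolve(anchors[0], n, stim_center)
    for a, b in zip(anchors, anchors[1:]):
        if b.t0 < a.t1 - 1e-9:
            raise ScriptError("keyframe anchors out of order")
        sel = t >= a.t1
        if not sel.any():
            continue
        wb = _resolve(b, n, stim_center)
        if b.t0 > a.t1:
            transit = sel & (t < b.t0)
            if transit.any():
                s = _smoothstep((t[transit] - a.t1) / (b.t0 - a.t1))[:, None]
                pos[transit] = (1 - s) * pos[transit] + s * wb[transit]
        after = t >= b.t0
        pos[after] = wb[after]
    return pos


def _sensor_name(hand: str, part: str) -> str:
    return {
        "thumb": f"{hand_prefix(hand)}_thumb_nail",
        "index": f"{hand_prefix(hand)}_index_nail",
        "phalanx": f"{hand_prefix(hand)}_index_phalanx",
    }[part]


def _rot_x_quat(theta_deg: np.ndarray) -> np.ndarray:
    half = np.radians(np.asarray(theta_deg, float)) / 2.0
    q = np.zeros((len(half), 4))
    q[:, 0] = np.cos(half)
    q[:, 1] = np.sin(half)
    return q


def _perturb_quats(q_wxyz: np.ndarray, sd_deg: float, rng) -> np.ndarray:
    n = len(q_wxyz)
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    half = np.radians(rng.normal(0.0, sd_deg, n)) / 2.0
    dq = np.column_stack([np.cos(half), axes * np.sin(half)[:, None]])
    w1, x1, y1, z1 = dq.T
    w2, x2, y2, z2 = q_wxyz.T
    out = np.column_stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


# grip standoffs from the faces (mm): tighter at pickup than while exploring,
# so the relaxed-grip hull stays strictly above the at-lift reference
_R_LIFT, _R_HOLD = 4.0, 6.0
# rub stroke center along the long axis, off the face center so the range
# rate stays high through the stroke
_RUB_Z_OFF = 45.0


def render_scenario(
    script: ScenarioScript,
    geom: Optional[StimulusGeometry] = None,
    fs: float = 300.0,
    cfg: Optional[ThresholdConfig] = None,
) -> Tuple[MotionRecording, AnnotationTrack]:
    """Render a script into a 7-sensor recording plus its ground-truth track."""
    geom = (geom or StimulusGeometry()).validate()
    cfg = (cfg or ThresholdConfig()).validate()
    script.validate(cfg)

    n = int(round(script.duration * fs))
    t = np.arange(n) / fs
    hw, hd, hh = geom.half_dims

    ep_seg = script.ep_segment()
    lifted = ep_seg is not None

    # ---- stimulus: standing on the table, long edge vertical ----
    rest_z = hh
    dz = np.zeros(n)
    if lifted:
        up = _smoothstep((t - script.t_lift) / script.lift_ramp_s)
        down = _smoothstep((t - script.t_replace) / script.lift_ramp_s)
        dz = script.lift_height_mm * (up - down)
    stim_center = np.column_stack([np.zeros(n), np.zeros(n), rest_z + dz])

    # ---- role assignment; templates assume the holder starts on -x ----
    if ep_seg is None:
        holder, explorer = "left", "right"
    elif ep_seg.behavior == "UH":
        holder = ep_seg.hand
        explorer = opposite_hand(holder)
    elif ep_seg.behavior == "EN":
        holder, explorer = "left", "right"
    else:
        explorer = ep_seg.hand
        holder = opposite_hand(explorer)
    sx = 1.0 if holder == "left" else -1.0

    def X(p: Tuple[float, float, float]) -> Tuple[float, float, float]:
        return (sx * p[0], p[1], p[2])

    start = {
        holder: {
            "thumb": X((-200.0, -25.0, 10.0)),
            "index": X((-200.0, 0.0, 15.0)),
            "phalanx": X((-230.0, 0.0, 40.0)),
        },
        explorer: {
            "thumb": X((200.0, -25.0, 10.0)),
            "index": X((200.0, 0.0, 15.0)),
            "phalanx": X((230.0, 0.0, 40.0)),
        },
    }
    grip = {
        holder: {
            "thumb": lambda r: X((-(hw + r), 0.0, 20.0)),
            "index": lambda r: X((hw + r, 0.0, 20.0)),
            "phalanx": lambda r: X((hw + r + 30.0, 0.0, 45.0)),
        },
        explorer: {
            "thumb": lambda r: X((0.0, -(hd + r), -20.0)),
            "index": lambda r: X((0.0, hd + r, -20.0)),
            "phalanx": lambda r: X((0.0, hd + r + 30.0, 5.0)),
        },
    }
    # collision-free pickup/release waypoints, descending from above
    way = {
        holder: {
            "thumb": X((-120.0, 0.0, 190.0)),
            "index": X((120.0, 0.0, 190.0)),
            "phalanx": X((150.0, 0.0, 200.0)),
        },
        explorer: {
            "thumb": X((60.0, -70.0, 190.0)),
            "index": X((60.0, 70.0, 190.0)),
            "phalanx": X((60.0, 100.0, 200.0)),
        },
    }
    # rub pose on the explorer's +y face
    rub_pose = {
        "index": (0.0, hd + 6.0, _RUB_Z_OFF),
        "thumb": (0.0, hd + 10.0, 0.0),
        "phalanx": (0.0, hd + 36.0, _RUB_Z_OFF + 20.0),
    }

    t_reach0, t_reach1 = 1.2, 1.8
    paths: Dict[str, np.ndarray] = {}
    for hand in (holder, explorer):
        for part in ("thumb", "index", "phalanx"):
            paths[_sensor_name(hand, part)] = np.broadcast_to(
                np.asarray(start[hand][part]), (n, 3)
            ).copy()

    if lifted:
        t_exp0, t_exp1 = ep_seg.t_start, ep_seg.t_end
        t_carry0 = max(script.t_lift + script.lift_ramp_s, t_exp0 - 0.6)
        t_ret1 = min(script.t_replace, t_exp1 + 0.6)
        t_rel0 = script.t_replace + script.lift_ramp_s
        t_rel1 = min(script.duration, t_rel0 + 0.6)
        t_mid_out = (t_carry0 + t_exp0) / 2.0
        t_mid_back = (t_exp1 + t_ret1) / 2.0

        for hand in (holder, explorer):
            for part in ("thumb", "index", "phalanx"):
                s0 = start[hand][part]
                wp = way[hand][part]
                g4 = grip[hand][part](_R_LIFT)
                g6 = grip[hand][part](_R_HOLD)
                # the grip relaxes from the pickup standoff to the holding
                # standoff during the lift ramp itself, so each thumb hull
                # is strictly increasing from the at-lift reference onward
                anchors: List[_Anchor] = [
                    _Anchor(0.0, t_reach0, "abs", s0),
                    _Anchor((t_reach0 + t_reach1) / 2, (t_reach0 + t_reach1) / 2, "abs", wp),
                    _Anchor(t_reach1, script.t_lift, "rel", g4),
                    _Anchor(script.t_lift + script.lift_ramp_s, t_carry0, "rel", g6),
                ]
                if hand == explorer and ep_seg.behavior == "LM":
                    pose = rub_pose[part]
                    if part == "thumb":
                        # over the top of the cuboid, never through it
                        w_out = (0.0, -50.0, hh + 35.0)
                        w_in = (0.0, 55.0, hh + 35.0)
                        anchors += [
                            _Anchor(t_mid_out - 0.1, t_mid_out - 0.1, "rel", w_out),
                            _Anchor(t_mid_out + 0.1, t_mid_out + 0.1, "rel", w_in),
                            _Anchor(t_exp0, t_exp1, "rel", pose),
                            _Anchor(t_mid_back - 0.1, t_mid_back - 0.1, "rel", w_in),
                            _Anchor(t_mid_back + 0.1, t_mid_back + 0.1, "rel", w_out),
                        ]
                    else:
                        anchors += [_Anchor(t_exp0, t_exp1, "rel", pose)]
                elif hand == explorer and ep_seg.behavior == "UH":
                    anchors += [
                        _Anchor(t_mid_out, t_mid_out, "abs", wp),
                        _Anchor(t_exp0, t_exp1, "abs", s0),
                        _Anchor(t_mid_back, t_mid_back, "abs", wp),
                    ]
                else:
                    anchors += [_Anchor(t_exp0, t_exp1, "rel", g6)]
                anchors += [
                    _Anchor(t_ret1, t_rel0, "rel", g6),
                    _Anchor((t_rel0 + t_rel1) / 2, (t_rel0 + t_rel1) / 2, "abs", wp),
                    _Anchor(t_rel1, script.duration + 1.0, "abs", s0),
                ]
                paths[_sensor_name(hand, part)] = _keyframe_path(anchors, t, stim_center)

        # ---- grip-adjustment jitter on the holding thumb ----
        if ep_seg.behavior in ("LM", "UH"):
            # only in these trials does the explorer leave the stimulus,
            # exposing the holder to incidental UH hits during transports
            a = script.sway_jitter_mm
            omega = 2.0 * math.pi * script.sway_frequency_hz
            normal = np.array([-sx, 0.0, 0.0])  # holder thumb face outward normal
            delta = np.zeros(n)
            for w0, w1, lock in ((t_carry0, t_exp0, t_exp0), (t_exp1, t_ret1, t_exp1)):
                sel = (t >= w0) & (t < w1)
                delta[sel] = 0.5 * a * (1.0 - np.cos(omega * (t[sel] - lock)))
            sensor = _sensor_name(holder, "thumb")
            paths[sensor] = paths[sensor] + delta[:, None] * normal

        # ---- LM rub overlay along the long axis ----
        if ep_seg.behavior == "LM":
            amp = ep_seg.params.get("rub_amplitude_mm", script.rub_amplitude_mm)
            freq = ep_seg.params.get("rub_frequency_hz", script.rub_frequency_hz)
            omega = 2.0 * math.pi * freq
            sel = (t >= t_exp0) & (t < t_exp1)
            dz_rub = np.zeros(n)
            dz_rub[sel] = amp * np.sin(omega * (t[sel] - t_exp0))
            for part in ("index", "phalanx"):
                sensor = _sensor_name(explorer, part)
                paths[sensor][:, 2] += dz_rub

        # ---- PR press overlay through the -y face ----
        if ep_seg.behavior == "PR":
            depth = ep_seg.params.get("press_depth_mm", script.press_depth_mm)
            ramp = 0.12
            travel = _R_HOLD + depth
            s_in = _smoothstep((t - t_exp0) / ramp)
            s_out = _smoothstep((t - (t_exp1 - ramp)) / ramp)
            delta = travel * (s_in - s_out)
            delta[(t < t_exp0) | (t >= t_exp1)] = 0.0
            sensor = _sensor_name(explorer, "thumb")
            paths[sensor][:, 1] += delta  # inward = +y

    # ---- orientations ----
    quat = {s: np.tile([1.0, 0.0, 0.0, 0.0], (n, 1)) for s in SENSORS}
    base_angle = 30.0  # deg between index nail and proximal phalanx at rest
    for hand in ("left", "right"):
        quat[_sensor_name(hand, "index")] = _rot_x_quat(np.full(n, base_angle))
    if lifted:
        # finger wiggle on the lifting hand blocks Enclosure while both
        # hands statically grip outside the scripted episode
        theta = np.full(n, base_angle)
        omega_w = 2.0 * math.pi * 1.5
        for w0, w1, lock in ((t_reach1, t_exp0, t_exp0), (t_exp1, t_rel0, t_exp1)):
            sel = (t >= w0) & (t < w1)
            theta[sel] = base_angle + 25.0 * (1.0 - np.cos(omega_w * (t[sel] - lock)))
        quat[_sensor_name(holder, "index")] = _rot_x_quat(theta)

    pos = {"stimulus": stim_center, **paths}

    rng = np.random.default_rng(script.seed)
    if script.pos_noise_sd_mm > 0:
        for s in SENSORS:
            pos[s] = pos[s] + rng.normal(0.0, script.pos_noise_sd_mm, (n, 3))
    if script.ori_noise_sd_deg > 0:
        for s in SENSORS:
            quat[s] = _perturb_quats(quat[s], script.ori_noise_sd_deg, rng)

    rec = MotionRecording(
        trial_id=script.trial_id, fs=fs, t=t, pos=pos, quat=quat
    ).validate()

    truth_intervals: List[Interval] = []
    if ep_seg is not None:
        hand = "bimanual" if ep_seg.behavior == "EN" else ep_seg.hand
        truth_intervals.append(
            Interval(ep_seg.behavior, hand, ep_seg.t_start, ep_seg.t_end)
        )
    truth = AnnotationTrack(script.trial_id, "truth", n / fs, truth_intervals).validate()
    return rec, truth


# ---------------------------------------------------------------------------
# Scoring against ground truth
# ---------------------------------------------------------------------------


@dataclass
class EvalMetrics:
    per_label: pd.DataFrame  # ep, hand, tp, fp, fn, precision, recall, f1, degenerate
    pooled: Dict[str, float]
    interval_errors: pd.DataFrame  # ep, hand, onset_err_s, offset_err_s


def _label_frames(track: AnnotationTrack, label, n: int, step: float) -> np.ndarray:
    m = np.zeros(n, bool)
    for iv in track.intervals:
        if iv.label != label:
            continue
        k0 = max(0, math.ceil(iv.t_start / step - 1e-9))
        k1 = min(n, math.ceil(iv.t_end / step - 1e-9))
        m[k0:k1] = True
    return m


def evaluate_against_truth(
    pred: AnnotationTrack,
    truth: AnnotationTrack,
    step: float = 1.0 / 300.0,
) -> EvalMetrics:
    """Frame-level precision/recall/F1 per label and pooled (micro), plus
    per-interval onset/offset absolute errors via greedy overlap matching.

    An undefined precision or recall (empty denominator) is reported as 0
    with the ``degenerate`` flag set.
    """
    if abs(pred.trial_duration - truth.trial_duration) > 1e-6:
        raise ValueError("pred and truth must share the trial duration")
    n = int(round(pred.trial_duration / step))

    rows = []
    tp_all = fp_all = fn_all = 0
    for label in LABELS:
        mp = _label_frames(pred, label, n, step)
        mt = _label_frames(truth, label, n, step)
        tp = int(np.sum(mp & mt))
        fp = int(np.sum(mp & ~mt))
        fn = int(np.sum(~mp & mt))
        tp_all += tp
        fp_all += fp
        fn_all += fn
        degenerate = (tp + fp == 0) or (tp + fn == 0)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append(
            {
                "ep": label[0],
                "hand": label[1],
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "degenerate": degenerate,
            }
        )

    pooled_p = tp_all / (tp_all + fp_all) if tp_all + fp_all else 0.0
    pooled_r = tp_all / (tp_all + fn_all) if tp_all + fn_all else 0.0
    pooled = {
        "precision": pooled_p,
        "recall": pooled_r,
        "f1": 2 * pooled_p * pooled_r / (pooled_p + pooled_r)
        if pooled_p + pooled_r
        else 0.0,
    }

    err_rows = []
    for label in LABELS:
        t_ivs = [iv for iv in truth.intervals if iv.label == label]
        p_ivs = [iv for iv in pred.intervals if iv.label == label]
        used = set()
        for tiv in t_ivs:
            best, best_ov = None, 0.0
            for j, piv in enumerate(p_ivs):
                if j in used:
                    continue
                ov = min(tiv.t_end, piv.t_end) - max(tiv.t_start, piv.t_start)
                if ov > best_ov:
                    best, best_ov = j, ov
            if best is not None:
                piv = p_ivs[best]
                used.add(best)
                err_rows.append(
                    {
                        "ep": label[0],
                        "hand": label[1],
                        "onset_err_s": abs(piv.t_start - tiv.t_start),
                        "offset_err_s": abs(piv.t_end - tiv.t_end),
                    }
                )
    return EvalMetrics(pd.DataFrame(rows), pooled, pd.DataFrame(err_rows))
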