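"""Rule-based per-timestep EP classification.

Each of the four Exploratory Procedures has a fixed set of criteria over
the kinematic variables; at every timestep each of the seven label channels
(LM/PR/UH per hand, EN bimanual) is set independently, so a frame may carry
several simultaneous labels at this stage -- conflicts are resolved later.
All printed comparisons are strict (<, >), exactly as typeset:

* Lateral Motion (hand = the rubbing hand): at least one of that hand's
  nails (index or thumb) is close to the surface (< 20 mm) with high
  relative speed (> 0.10 m/s), while the opposite thumb is slow
  (< 0.05 m/s).
* Pressure (hand = the pressing hand): that hand's stimulus+thumb hull is
  smaller than it was at the initial lift, and the hull was shrinking over
  the window preceding the moment it first dropped below that reference
  (guards against an outward-pointing thumb at pickup).
* Unsupported Holding (hand = the holding hand): thumb close (< 20 mm),
  thumb and index both slow (< 0.05 m/s), while the opposite hand is off
  the object (midpoint outside the volume, thumb farther than 20 mm).
* Enclosure (bimanual): all four nails slow (< 0.05 m/s), both virtual
  midpoints inside the stimulus volume, both index-finger angle rates low
  (< 80 deg/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .io_formats import (
    HANDS,
    LABELS,
    ThresholdConfig,
    hand_prefix,
    opposite_hand,
)
from .kinematics import FeatureTable

__all__ = [
    "LabelMask",
    "criteria_lm",
    "criteria_pr",
    "criteria_uh",
    "criteria_en",
    "classify_raw",
]


@dataclass
class LabelMask:
    """Boolean series per (ep, hand) label channel, aligned with a FeatureTable."""

    fs: float
    t: np.ndarray
    masks: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)

    @classmethod
    def empty(cls, fs: float, t: np.ndarray) -> "LabelMask":
        return cls(fs, np.asarray(t, float), {lab: np.zeros(len(t), bool) for lab in LABELS})

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def copy(self) -> "LabelMask":
        return LabelMask(self.fs, self.t.copy(), {k: v.copy() for k, v in self.masks.items()})

    def validate(self) -> "LabelMask":
        if set(self.masks) != set(LABELS):
            raise ValueError("mask must carry exactly the 7 label channels")
        for lab, m in self.masks.items():
            if len(m) != self.n_samples:
                raise ValueError(f"channel {lab} length mismatch")
        return self


def criteria_lm(feat: FeatureTable, hand: str, cfg: ThresholdConfig) -> np.ndarray:
    """Lateral Motion criteria for the given (rubbing) hand; bool per timestep."""
    p = hand_prefix(hand)
    o = hand_prefix(opposite_hand(hand))
    fast_close = np.zeros(feat.n_samples, bool)
    for nail in (f"{p}_index_nail", f"{p}_thumb_nail"):
        fast_close |= (feat.surf_dist[nail] < cfg.d_close_mm) & (
            feat.rel_speed[nail] > cfg.v_high_ms
        )
    opp_thumb_slow = feat.rel_speed[f"{o}_thumb_nail"] < cfg.v_low_ms
    return fast_close & opp_thumb_slow


def criteria_pr(feat: FeatureTable, hand: str, cfg: ThresholdConfig) -> np.ndarray:
    """Pressure criteria for the given (pressing) hand; bool per timestep.

    False everywhere when no lift was detected, and before the lift sample.
    A contiguous run of samples with hull < hull_at_lift counts only if the
    mean hull rate over the ``pr_decrease_window_ms`` preceding the run's
    first sample is negative (the pinch was closing, not still opening).
    """
    ref = feat.hull_at_lift.get(hand)
    out = np.zeros(feat.n_samples, bool)
    if ref is None or feat.lift_index is None:
        return out
    below = feat.hull_size[hand] < ref
    below[: feat.lift_index] = False
    window = int(round(cfg.pr_decrease_window_ms / 1000.0 * feat.fs))
    rate = feat.hull_rate[hand]
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return out
    # run starts: first below sample, or below sample whose predecessor is not
    starts = idx[np.flatnonzero(np.diff(idx, prepend=idx[0] - 2) > 1)]
    ends = np.append(idx[np.flatnonzero(np.diff(idx) > 1)], idx[-1])
    for t_c, t_e in zip(starts, ends):
        lo = max(0, t_c - window)
        if lo == t_c:
            continue  # no pre-entry history: cannot establish a decrease
        if float(np.mean(rate[lo:t_c])) < 0.0:
            out[t_c : t_e + 1] = True
    return out


def criteria_uh(feat: FeatureTable, hand: str, cfg: ThresholdConfig) -> np.ndarray:
    """Unsupported Holding criteria for the given (holding) hand."""
    p = hand_prefix(hand)
    opp = opposite_hand(hand)
    o = hand_prefix(opp)
    return (
        (feat.surf_dist[f"{p}_thumb_nail"] < cfg.d_close_mm)
        & (feat.rel_speed[f"{p}_thumb_nail"] < cfg.v_low_ms)
        & (feat.rel_speed[f"{p}_index_nail"] < cfg.v_low_ms)
        & ~feat.midpoint_inside[opp]
        & (feat.surf_dist[f"{o}_thumb_nail"] > cfg.d_close_mm)
    )


def criteria_en(feat: FeatureTable, cfg: ThresholdConfig) -> np.ndarray:
    """Enclosure criteria (bimanual)."""
    ok = np.ones(feat.n_samples, bool)
    for nail in feat.rel_speed:
        ok &= feat.rel_speed[nail] < cfg.v_low_ms
    for hand in HANDS:
        ok &= feat.midpoint_inside[hand]
        ok &= np.abs(feat.finger_angle_rate[hand]) < cfg.omega_max_deg_s
    return ok


def classify_raw(feat: FeatureTable, cfg: ThresholdConfig) -> LabelMask:
    """Evaluate all criteria sets per timestep; channels set independently."""
    cfg.validate()
    mask = LabelMask.empty(feat.fs, feat.t)
    for hand in HANDS:
        mask.masks[("LM", hand)] = criteria_lm(feat, hand, cfg)
        mask.masks[("PR", hand)] = criteria_pr(feat, hand, cfg)
        mask.masks[("UH", hand)] = criteria_uh(feat, hand, cfg)
    mask.masks[("EN", "bimanual")] = criteria_en(feat, cfg)
    return mask.validate()
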