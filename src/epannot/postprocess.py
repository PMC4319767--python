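"""Clean-up of raw label masks into annotation intervals.

Three operations run in order -- gap filling, minimum-duration pruning,
dominance-based conflict resolution -- and the whole routine is executed
twice (configurable), because resolving simultaneity can leave fragments
shorter than the per-EP minimum which the second pass removes.

* gap filling: a false run strictly shorter than 50 ms flanked by true
  runs of the *same* channel becomes true (no cross-label filling);
* pruning: a true run strictly shorter than that EP's minimum duration
  (17-250 ms depending on EP) is deleted; runs exactly at the minimum stay;
* conflict resolution: two labels conflict at a timestep iff they share a
  hand (EN occupies both).  Only the label ranked highest in the dominance
  order (LM-UH-PR-EN by default) survives; by default the loser is cleared
  over the overlapping timesteps only, optionally over its whole interval.

Durations follow the half-open sample convention: a run of k samples lasts
k/fs; all boundary comparisons are strict as printed.
"""

from __future__ import annotations

from typing import Iterator, List, Tuple

import numpy as np

from .io_formats import AnnotationTrack, Interval, ThresholdConfig
from .classifier import LabelMask

__all__ = [
    "fill_gaps",
    "prune_short",
    "resolve_conflicts",
    "mask_to_track",
    "postprocess",
]

_EPSILON = 1e-9


def _runs(mask: np.ndarray) -> Iterator[Tuple[int, int]]:
    """Yield (start, stop) of maximal true runs; stop is exclusive."""
    m = np.asarray(mask, bool)
    if m.size == 0:
        return
    edges = np.flatnonzero(np.diff(m.astype(np.int8)))
    starts = edges[::1] + 1
    bounds = np.concatenate([[0], starts, [m.size]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if m[lo]:
            yield int(lo), int(hi)


def _hands_of(label: Tuple[str, str]) -> Tuple[str, ...]:
    ep, hand = label
    return ("left", "right") if hand == "bimanual" else (hand,)


def fill_gaps(mask: LabelMask, cfg: ThresholdConfig) -> LabelMask:
    """Fill false runs strictly shorter than ``gap_fill_max_ms`` per channel.

    A gap is only filled while no other label sharing the hand is active
    inside it: otherwise a later pass would re-fill exactly the timesteps
    the dominance resolution just carved out, and the resulting fragments
    could never be cleaned up.  Occupancy counts only runs that are at
    least their EP's minimum duration -- shorter runs are deleted by the
    pruning step before they could ever win a conflict, so they cannot
    block a fill either (this keeps the two-pass routine a fixed point).
    Channels are processed in dominance order against the live mask, so
    simultaneous fills cannot create a conflict.
    """
    out = mask.copy()
    limit = cfg.gap_fill_max_ms / 1000.0 * mask.fs  # samples
    n = mask.n_samples
    ordered = sorted(out.masks, key=lambda lab: cfg.rank(lab[0]))
    for lab in ordered:
        m = out.masks[lab]
        occupied = np.zeros(n, bool)
        for other, om in out.masks.items():
            if other != lab and set(_hands_of(other)) & set(_hands_of(lab)):
                min_other = cfg.min_duration_ms[other[0]] / 1000.0 * mask.fs
                for lo, hi in _runs(om):
                    if (hi - lo) >= min_other - _EPSILON:
                        occupied[lo:hi] = True
        runs = list(_runs(m))
        for (_, stop_a), (start_b, _) in zip(runs, runs[1:]):
            if (start_b - stop_a) < limit - _EPSILON and not occupied[
                stop_a:start_b
            ].any():
                m[stop_a:start_b] = True
    return out


def prune_short(mask: LabelMask, cfg: ThresholdConfig) -> LabelMask:
    """Delete true runs strictly shorter than the EP's minimum duration."""
    out = mask.copy()
    for (ep, hand), m in out.masks.items():
        min_samples = cfg.min_duration_ms[ep] / 1000.0 * mask.fs
        for lo, hi in _runs(m):
            if (hi - lo) < min_samples - _EPSILON:
                m[lo:hi] = False
    return out


def resolve_conflicts(mask: LabelMask, cfg: ThresholdConfig) -> LabelMask:
    """Keep only the highest-ranked label wherever two labels share a hand.

    With ``conflict_mode == "overlap"`` (default) the losing label is
    cleared over the conflicting timesteps only; with ``"interval"`` every
    losing run that touches a conflict is removed entirely.
    """
    out = mask.copy()
    n = mask.n_samples
    occupied = {"left": np.zeros(n, bool), "right": np.zeros(n, bool)}
    for ep in cfg.dominance:
        # channels of one EP occupy different hands and never conflict
        for lab in [l for l in out.masks if l[0] == ep]:
            m = out.masks[lab]
            blocked = np.zeros(n, bool)
            for hand in _hands_of(lab):
                blocked |= occupied[hand]
            conflict = m & blocked
            if cfg.conflict_mode == "interval":
                for lo, hi in _runs(m):
                    if conflict[lo:hi].any():
                        m[lo:hi] = False
            else:
                m &= ~blocked
            for hand in _hands_of(lab):
                occupied[hand] |= m
    return out


def mask_to_track(
    mask: LabelMask, trial_id: str, rater_id: str = "auto"
) -> AnnotationTrack:
    """Convert maximal true runs to half-open intervals on the sample grid.

    Endpoints are computed as sample_index / fs (relative to the first
    timestamp), so abutting runs produce exactly matching boundaries.
    """
    n = mask.n_samples
    fs = mask.fs
    t0 = float(mask.t[0]) if n else 0.0
    duration = n / fs if n else 1.0 / fs
    intervals: List[Interval] = []
    for (ep, hand), m in mask.masks.items():
        for lo, hi in _runs(m):
            lo_idx = round((float(mask.t[lo]) - t0) * fs)
            intervals.append(
                Interval(ep, hand, lo_idx / fs, (lo_idx + hi - lo) / fs)
            )
    intervals.sort(key=lambda iv: (iv.t_start, iv.ep, iv.hand))
    return AnnotationTrack(trial_id, rater_id, duration, intervals).validate()


def postprocess(
    raw: LabelMask,
    cfg: ThresholdConfig,
    trial_id: str,
    rater_id: str = "auto",
) -> AnnotationTrack:
    """fill_gaps -> prune_short -> resolve_conflicts, run ``postprocess_passes`` times."""
    cfg.validate()
    mask = raw.validate().copy()
    for _ in range(cfg.postprocess_passes):
        mask = resolve_conflicts(prune_short(fill_gaps(mask, cfg), cfg), cfg)
    return mask_to_track(mask, trial_id, rater_id)


def postprocess_mask(raw: LabelMask, cfg: ThresholdConfig) -> LabelMask:
    """Like :func:`postprocess` but returning the final mask (for analysis)."""
    mask = raw.validate().copy()
    for _ in range(cfg.postprocess_passes):
        mask = resolve_conflicts(prune_short(fill_gaps(mask, cfg), cfg), cfg)
    return mask


def annotate_recording(rec, geom=None, cfg=None, rater_id: str = "auto") -> AnnotationTrack:
    """Full pipeline: filtering + variables -> criteria -> post-processing."""
    from .io_formats import StimulusGeometry
    from .kinematics import extract_features
    from .classifier import classify_raw

    geom = geom or StimulusGeometry()
    cfg = cfg or ThresholdConfig()
    feat = extract_features(rec, geom, cfg)
    raw = classify_raw(feat, cfg)
    return postprocess(raw, cfg, rec.trial_id, rater_id)
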