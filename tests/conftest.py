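"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from epannot import (
    HANDS,
    LABELS,
    NAIL_SENSORS,
    AnnotationTrack,
    FeatureTable,
    Interval,
    LabelMask,
    StimulusGeometry,
    ThresholdConfig,
)


@pytest.fixture()
def cfg() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture()
def geom() -> StimulusGeometry:
    return StimulusGeometry()


# ---------------------------------------------------------------------------
# Constructed feature tables for criteria tests
# ---------------------------------------------------------------------------


def make_features(
    n: int = 10,
    fs: float = 300.0,
    rel_speed: dict | None = None,
    surf_dist: dict | None = None,
    hull_size: dict | None = None,
    hull_rate: dict | None = None,
    midpoint_inside: dict | None = None,
    finger_angle_rate: dict | None = None,
    lift_index: int | None = None,
    hull_at_lift: dict | None = None,
) -> FeatureTable:
    """Feature table with inactive defaults: hands far away and slow.

    Channel overrides may be scalars (broadcast) or arrays of length n.
    """

    def series(value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        return np.full(n, float(arr)) if arr.ndim == 0 else arr.astype(float)

    def per_key(defaults: dict, over: dict | None) -> dict:
        out = {k: series(v) for k, v in defaults.items()}
        for k, v in (over or {}).items():
            out[k] = series(v)
        return out

    rs = per_key({s: 0.02 for s in NAIL_SENSORS}, rel_speed)
    sd = per_key({s: 150.0 for s in NAIL_SENSORS}, surf_dist)
    hs = per_key({h: 5e5 for h in HANDS}, hull_size)
    hr = per_key({h: 0.0 for h in HANDS}, hull_rate)
    far = per_key({h: 0.0 for h in HANDS}, midpoint_inside)
    mi = {h: far[h].astype(bool) for h in HANDS}
    fr = per_key({h: 0.0 for h in HANDS}, finger_angle_rate)
    return FeatureTable(
        fs=fs,
        t=np.arange(n) / fs,
        rel_speed=rs,
        hull_size=hs,
        hull_rate=hr,
        elevation=np.full(n, 60.0),
        elevation_rate=np.zeros(n),
        surf_dist=sd,
        midpoint_inside=mi,
        finger_angle={h: np.full(n, 30.0) for h in HANDS},
        finger_angle_rate=fr,
        lift_index=lift_index,
        hull_at_lift=hull_at_lift or {h: None for h in HANDS},
    )


# ---------------------------------------------------------------------------
# Random masks / tracks for fuzzing
# ---------------------------------------------------------------------------


def random_mask(rng: np.random.Generator, n: int = 240, fs: float = 300.0,
                density: float = 0.3) -> LabelMask:
    """Blocky random label mask: a few random runs per channel."""
    mask = LabelMask.empty(fs, np.arange(n) / fs)
    for lab in LABELS:
        m = mask.masks[lab]
        for _ in range(rng.integers(0, 5)):
            lo = int(rng.integers(0, n))
            hi = min(n, lo + int(rng.integers(1, max(2, int(n * density)))))
            m[lo:hi] = True
    return mask


def random_fuzz_track(rng: np.random.Generator, trial_id: str, rater_id: str,
                      duration: float = 2.0) -> AnnotationTrack:
    intervals = []
    for lab in LABELS:
        if rng.random() < 0.5:
            continue
        k = int(rng.integers(1, 4))
        edges = np.sort(rng.uniform(0, duration, 2 * k))
        for a, b in zip(edges[::2], edges[1::2]):
            if b - a > 1e-3:
                intervals.append(Interval(lab[0], lab[1], float(a), float(b)))
    return AnnotationTrack(trial_id, rater_id, duration, intervals).normalized()


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def brute_force_agreement(a: AnnotationTrack, b: AnnotationTrack,
                          step: float = 1.0 / 300.0) -> float:
    """Straight-line reimplementation of timewise agreement with python sets."""
    n = int(round(a.trial_duration / step))
    match = 0
    for k in range(n):
        t = k * step
        sa = {iv.label for iv in a.intervals if iv.t_start <= t < iv.t_end}
        sb = {iv.label for iv in b.intervals if iv.t_start <= t < iv.t_end}
        match += sa == sb
    return 100.0 * match / n


def box_distance_oracle(point, geom: StimulusGeometry) -> float:
    """Exact point-to-cuboid-surface distance for an axis-aligned cuboid at
    the origin (inside points measure to the nearest face)."""
    p = np.abs(np.asarray(point, float))
    half = geom.half_dims
    d = p - half
    if np.any(d > 0):
        return float(np.linalg.norm(np.maximum(d, 0.0)))
    return float(np.min(-d))


def mc_hull_volume(corners: np.ndarray, thumb: np.ndarray, n_pow: int = 17,
                   seed: int = 0) -> float:
    """Quasi-Monte-Carlo hull volume: Sobol samples in the bounding box,
    membership via Delaunay triangulation of the 9 points."""
    from scipy.spatial import Delaunay
    from scipy.stats import qmc

    pts = np.vstack([corners, thumb])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    tri = Delaunay(pts)
    sampler = qmc.Sobol(d=3, scramble=True, seed=seed)
    samples = lo + sampler.random_base2(m=n_pow) * (hi - lo)
    inside = tri.find_simplex(samples) >= 0
    return float(np.prod(hi - lo) * inside.mean())
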