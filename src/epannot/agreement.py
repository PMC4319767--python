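"""Comparison of annotation tracks across raters.

Implements the validation machinery used to compare automatic against
human annotation:

* timewise agreement: the percentage of trial timesteps (3.33 ms grid by
  default) at which two raters' sets of active (EP, hand) labels are
  identical, agreed absence included;
* main/secondary EP: per rater and trial, the two (EP, hand) labels with
  the longest total duration (blanks when fewer than two EPs occur);
* main/secondary overlap: whether the automatic rater's main or secondary
  EP (hand ignored) matches the main or secondary EP of at least one human;
* expected-EP check: each object property has one optimal EP (Lateral
  Motion for roughness, Pressure for hardness, Unsupported Holding for
  weight, Enclosure for volume); the check is whether it appears among a
  rater's top two;
* random baseline: a rater that annotates one uniformly drawn (EP, hand)
  label over the whole trial, scored over several independent runs
  (10 by default) and averaged.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import (
    EPS,
    LABELS,
    AnnotationTrack,
    Interval,
    ThresholdConfig,
)

logger = logging.getLogger("epannot")

__all__ = [
    "EXPECTED_EP",
    "AgreementReport",
    "timewise_agreement",
    "main_secondary",
    "overlap_main_secondary",
    "expected_ep_found",
    "random_track",
    "agreement_report",
    "trial_plan",
]

#: Optimal EP per explored object property.
EXPECTED_EP: Dict[str, str] = {
    "roughness": "LM",
    "hardness": "PR",
    "weight": "UH",
    "volume": "EN",
}

DEFAULT_STEP = 1.0 / 300.0

_LABEL_BIT = {lab: 1 << i for i, lab in enumerate(LABELS)}
_EP_BIT = {ep: 1 << i for i, ep in enumerate(EPS)}


def _state_codes(
    track: AnnotationTrack, step: float, n: int, hand_sensitive: bool
) -> np.ndarray:
    """Bit-coded label set at each grid timestep k*step (half-open intervals)."""
    codes = np.zeros(n, dtype=np.int64)
    for iv in track.intervals:
        k0 = max(0, math.ceil(iv.t_start / step - 1e-9))
        k1 = min(n, math.ceil(iv.t_end / step - 1e-9))
        if k1 > k0:
            bit = _LABEL_BIT[iv.label] if hand_sensitive else _EP_BIT[iv.ep]
            codes[k0:k1] |= bit
    return codes


def timewise_agreement(
    a: AnnotationTrack,
    b: AnnotationTrack,
    step: float = DEFAULT_STEP,
    hand_sensitive: bool = True,
    count_coblank: bool = True,
) -> float:
    """Percent of timesteps at which both raters' active label sets match.

    With ``count_coblank`` (default) a timestep where neither rater marks
    anything counts as agreement; otherwise such timesteps are excluded
    from the denominator (two fully blank tracks then agree at 100%).
    """
    if abs(a.trial_duration - b.trial_duration) > 1e-6:
        raise ValueError("tracks must share the trial duration")
    n = int(round(a.trial_duration / step))
    if n == 0:
        raise ValueError("trial too short for the comparison step")
    ca = _state_codes(a, step, n, hand_sensitive)
    cb = _state_codes(b, step, n, hand_sensitive)
    same = ca == cb
    if count_coblank:
        return 100.0 * float(np.mean(same))
    active = (ca != 0) | (cb != 0)
    if not active.any():
        return 100.0
    return 100.0 * float(np.mean(same[active]))


def main_secondary(
    track: AnnotationTrack, cfg: Optional[ThresholdConfig] = None
) -> Tuple[Optional[Tuple[str, str]], Optional[Tuple[str, str]]]:
    """The two (EP, hand) labels with the largest total duration.

    Ties break by the dominance ranking, then lexicographic hand order;
    blanks (None) fill absent ranks.
    """
    ranking = (cfg or ThresholdConfig()).dominance
    totals = track.total_durations()
    ordered = sorted(
        totals.items(), key=lambda kv: (-kv[1], ranking.index(kv[0][0]), kv[0][1])
    )
    labels: List[Optional[Tuple[str, str]]] = [lab for lab, _ in ordered[:2]]
    while len(labels) < 2:
        labels.append(None)
    return labels[0], labels[1]


def overlap_main_secondary(
    auto: AnnotationTrack,
    humans: Sequence[AnnotationTrack],
    cfg: Optional[ThresholdConfig] = None,
    hand_sensitive: bool = False,
) -> bool:
    """True iff auto's main or secondary EP matches any human's main or secondary.

    By default only the EP identity is compared (hand ignored); blanks
    never match.
    """
    if not humans:
        raise ValueError("need at least one human track")

    def top2(track: AnnotationTrack) -> set:
        pair = main_secondary(track, cfg)
        if hand_sensitive:
            return {lab for lab in pair if lab is not None}
        return {lab[0] for lab in pair if lab is not None}

    auto_set = top2(auto)
    if not auto_set:
        return False
    return any(auto_set & top2(h) for h in humans)


def expected_ep_found(track: AnnotationTrack, object_property: str) -> bool:
    """Whether the property's optimal EP is the track's main or secondary EP."""
    if object_property not in EXPECTED_EP:
        raise ValueError(f"unknown object property {object_property!r}")
    expected = EXPECTED_EP[object_property]
    main, secondary = main_secondary(track)
    return expected in {lab[0] for lab in (main, secondary) if lab is not None}


def random_track(
    duration: float,
    seed: int,
    trial_id: str = "random",
    rater_id: str = "random",
) -> AnnotationTrack:
    """One uniformly drawn (EP, hand) label over the entire trial duration."""
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    ep, hand = LABELS[int(rng.integers(len(LABELS)))]
    return AnnotationTrack(
        trial_id, rater_id, duration, [Interval(ep, hand, 0.0, duration)]
    )


@dataclass
class AgreementReport:
    """Per-trial and aggregated rater-comparison statistics."""

    pairwise: pd.DataFrame  # trial_id, rater_a, rater_b, pair_type, agreement_pct
    main_secondary: pd.DataFrame  # trial_id, rater_id, main/secondary ep+hand
    overlap: pd.DataFrame  # trial_id, overlap (auto vs humans)
    expected: pd.DataFrame  # trial_id, rater_id, rater_type, property, found
    summary: pd.DataFrame  # property x statistic -> mean, sd
    random_baseline: Optional[Dict[str, float]] = None


def _pair_type(a: str, b: str, auto_rater: str) -> str:
    n_auto = (a == auto_rater) + (b == auto_rater)
    return ("human-human", "human-automatic", "automatic-automatic")[n_auto]


def agreement_report(
    tracks: Mapping[str, Mapping[str, AnnotationTrack]],
    trial_properties: Optional[Mapping[str, str]] = None,
    cfg: Optional[ThresholdConfig] = None,
    auto_rater: str = "auto",
    step: float = DEFAULT_STEP,
    random_runs: int = 10,
    random_seed: int = 0,
) -> AgreementReport:
    """Full comparison over a set of trials.

    ``tracks`` maps trial_id -> rater_id -> track.  Trials missing some
    raters are excluded with a logged warning.  The random baseline draws
    one random whole-trial label per trial and run, scores it against the
    human raters, and averages over ``random_runs`` runs.
    """
    cfg = cfg or ThresholdConfig()
    hand_sensitive = cfg.agreement_hand_sensitive
    count_coblank = cfg.agreement_count_coblank

    raters = sorted({r for per_trial in tracks.values() for r in per_trial})
    usable = {}
    for trial_id, per_trial in tracks.items():
        if set(per_trial) >= set(raters):
            usable[trial_id] = per_trial
        else:
            logger.warning("trial %s missing raters %s; excluded",
                           trial_id, sorted(set(raters) - set(per_trial)))

    pair_rows, ms_rows, ov_rows, ex_rows = [], [], [], []
    for trial_id in sorted(usable):
        per_trial = usable[trial_id]
        for ra, rb in itertools.combinations(raters, 2):
            pair_rows.append(
                {
                    "trial_id": trial_id,
                    "rater_a": ra,
                    "rater_b": rb,
                    "pair_type": _pair_type(ra, rb, auto_rater),
                    "agreement_pct": timewise_agreement(
                        per_trial[ra], per_trial[rb], step,
                        hand_sensitive, count_coblank,
                    ),
                }
            )
        for rater in raters:
            main, secondary = main_secondary(per_trial[rater], cfg)
            ms_rows.append(
                {
                    "trial_id": trial_id,
                    "rater_id": rater,
                    "main_ep": main[0] if main else "",
                    "main_hand": main[1] if main else "",
                    "secondary_ep": secondary[0] if secondary else "",
                    "secondary_hand": secondary[1] if secondary else "",
                }
            )
        humans = [per_trial[r] for r in raters if r != auto_rater]
        if auto_rater in per_trial and humans:
            ov_rows.append(
                {
                    "trial_id": trial_id,
                    "overlap": overlap_main_secondary(
                        per_trial[auto_rater], humans, cfg
                    ),
                }
            )
        if trial_properties and trial_id in trial_properties:
            prop = trial_properties[trial_id]
            for rater in raters:
                ex_rows.append(
                    {
                        "trial_id": trial_id,
                        "rater_id": rater,
                        "rater_type": "automatic" if rater == auto_rater else "human",
                        "property": prop,
                        "found": expected_ep_found(per_trial[rater], prop),
                    }
                )

    pairwise = pd.DataFrame(pair_rows)
    ms = pd.DataFrame(ms_rows)
    overlap = pd.DataFrame(ov_rows)
    expected = pd.DataFrame(ex_rows)

    summary_rows = []
    if not pairwise.empty:
        props = trial_properties or {}
        pairwise = pairwise.assign(
            property=pairwise["trial_id"].map(lambda tid: props.get(tid, "all"))
        )
        groups = [("all", pairwise)]
        if trial_properties:
            groups += list(pairwise.groupby("property"))
        for prop, sub in groups:
            for pair_type, sub2 in sub.groupby("pair_type"):
                summary_rows.append(
                    {
                        "property": prop,
                        "statistic": f"agreement[{pair_type}]",
                        "mean": float(sub2["agreement_pct"].mean()),
                        "sd": float(sub2["agreement_pct"].std(ddof=1))
                        if len(sub2) > 1
                        else 0.0,
                        "n": len(sub2),
                    }
                )
        if not overlap.empty:
            summary_rows.append(
                {
                    "property": "all",
                    "statistic": "overlap_main_secondary_pct",
                    "mean": 100.0 * float(overlap["overlap"].mean()),
                    "sd": float("nan"),
                    "n": len(overlap),
                }
            )
        if not expected.empty:
            for (prop, rtype), sub in expected.groupby(["property", "rater_type"]):
                summary_rows.append(
                    {
                        "property": prop,
                        "statistic": f"expected_ep_found_pct[{rtype}]",
                        "mean": 100.0 * float(sub["found"].mean()),
                        "sd": float("nan"),
                        "n": len(sub),
                    }
                )
    summary = pd.DataFrame(summary_rows)

    baseline = None
    human_raters = [r for r in raters if r != auto_rater]
    if usable and human_raters:
        agree_runs, overlap_runs = [], []
        for run in range(random_runs):
            agree_vals, overlap_vals = [], []
            for j, trial_id in enumerate(sorted(usable)):
                per_trial = usable[trial_id]
                duration = per_trial[human_raters[0]].trial_duration
                rnd = random_track(
                    duration, random_seed + 10_000 * run + j, trial_id
                )
                humans = [per_trial[r] for r in human_raters]
                agree_vals += [
                    timewise_agreement(rnd, h, step, hand_sensitive, count_coblank)
                    for h in humans
                ]
                overlap_vals.append(overlap_main_secondary(rnd, humans, cfg))
            agree_runs.append(float(np.mean(agree_vals)))
            overlap_runs.append(100.0 * float(np.mean(overlap_vals)))
        baseline = {
            "agreement_pct": float(np.mean(agree_runs)),
            "overlap_main_secondary_pct": float(np.mean(overlap_runs)),
            "runs": float(random_runs),
        }

    return AgreementReport(pairwise, ms, overlap, expected, summary, baseline)


def trial_plan(
    n_participants: int = 5,
    n_properties: int = 4,
    n_repeats: int = 3,
    n_excluded: int = 1,
) -> List[str]:
    """Enumerate the analyzed trials of the validation design.

    Five participants x four object properties x three repeats, minus the
    one trial excluded for a mismatched video, gives the 59 analyzed
    trials; excluded trials are dropped from the end of the enumeration.
    """
    props = list(EXPECTED_EP)
    ids = [
        f"P{p + 1}_{props[q % len(props)] if n_properties <= len(props) else q}_T{r + 1}"
        for p in range(n_participants)
        for q in range(n_properties)
        for r in range(n_repeats)
    ]
    if n_excluded:
        ids = ids[: len(ids) - n_excluded]
    return ids
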