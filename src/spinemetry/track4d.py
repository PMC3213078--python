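"""Time-lapse protrusion tracking and remodeling analytics.

Spines detected at consecutive time points are linked by minimum-cost
one-to-one assignment on their attachment positions: cost is the absolute
arclength shift along the dendrite plus an azimuthal penalty
(0.5 um per half-turn by default); pairs costlier than the gate (1 um)
stay unmatched. Tracks are contiguous by construction — one appearance and
at most one disappearance.

Fates over the series: *stable* = present at the first and last frame,
*pruned* = present first, absent last; *new* = absent first, present last;
*transient* = absent at both ends (reported separately). Remodeling
analytics condition on presence at t0, exclude newly formed protrusions,
and summarise per initial class the fractions that kept their class,
remodeled to each other class, or were pruned, plus the incidence of each
outcome among all t0 protrusions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import AnalysisConfig
from .spines import CLASSES, SpineRecord

__all__ = [
    "SpineTrack", "TransitionSummary", "link", "fates", "transitions",
    "fate_group_geometry", "track_series",
]

OUTCOMES = ["to_stubby", "to_mushroom", "to_thin", "pruned"]


@dataclass
class SpineTrack:
    track_id: int
    records: Dict[int, SpineRecord] = field(default_factory=dict)
    fate: Optional[str] = None

    @property
    def first_t(self) -> int:
        return min(self.records)

    @property
    def last_t(self) -> int:
        return max(self.records)

    @property
    def initial_class(self) -> str:
        return self.records[self.first_t].spine_class

    @property
    def final_class(self) -> str:
        return self.records[self.last_t].spine_class

    def present(self, t: int) -> bool:
        return t in self.records


@dataclass
class TransitionSummary:
    """Per-initial-class outcome fractions and whole-population incidence."""

    by_class: pd.DataFrame     # index: initial class; columns: OUTCOMES + n
    incidence: pd.DataFrame    # same outcomes as fractions of all t0 spines
    n_t0: int


def _pair_cost(a: SpineRecord, b: SpineRecord, azimuth_weight: float) -> float:
    daz = abs(a.azimuth - b.azimuth) % (2 * np.pi)
    daz = min(daz, 2 * np.pi - daz)
    return abs(a.attachment_arclength - b.attachment_arclength) \
        + azimuth_weight * daz / np.pi


def link(records_per_time: Sequence[List[SpineRecord]],
         traces_per_time: Optional[Sequence] = None,
         gate: float = 1.0, azimuth_weight: float = 0.5) -> List[SpineTrack]:
    """Link per-frame detections into tracks by gated assignment."""
    T = len(records_per_time)
    if T < 2:
        raise ValueError("need at least 2 time points to track")
    if traces_per_time is not None:
        lengths = [tr.length for tr in traces_per_time]
        if max(lengths) > 1.2 * min(lengths):
            warnings.warn(
                "dendrite trace length changes by more than 20% across the "
                "series; drift suspected", stacklevel=2,
            )
    tracks: List[SpineTrack] = []
    active: List[SpineTrack] = []
    for rec in records_per_time[0]:
        tr = SpineTrack(track_id=len(tracks), records={0: rec})
        tracks.append(tr)
        active.append(tr)
    BIG = 1e9
    for t in range(1, T):
        recs = records_per_time[t]
        matched_tracks, matched_recs = set(), set()
        if active and recs:
            C = np.full((len(active), len(recs)), BIG)
            for i, tr in enumerate(active):
                prev = tr.records[t - 1]
                for k, rec in enumerate(recs):
                    c = _pair_cost(prev, rec, azimuth_weight)
                    if c <= gate:
                        C[i, k] = c
            ri, ci = linear_sum_assignment(C)
            for i, k in zip(ri, ci):
                if C[i, k] <= gate:
                    active[i].records[t] = recs[k]
                    matched_tracks.add(i)
                    matched_recs.add(k)
        next_active = [tr for i, tr in enumerate(active) if i in matched_tracks]
        for k, rec in enumerate(recs):
            if k not in matched_recs:
                tr = SpineTrack(track_id=len(tracks), records={t: rec})
                tracks.append(tr)
                next_active.append(tr)
        active = next_active
    return tracks


def fates(tracks: List[SpineTrack], n_time: int) -> List[SpineTrack]:
    """Label each track stable / new / pruned / transient.

    Also asserts the accounting identities: protrusions present at t0 are
    exactly the stable + pruned ones, and those present at the last frame
    the stable + new ones.
    """
    last = n_time - 1
    for tr in tracks:
        at0, atN = tr.present(0), tr.present(last)
        if at0 and atN:
            tr.fate = "stable"
        elif at0:
            tr.fate = "pruned"
        elif atN:
            tr.fate = "new"
        else:
            tr.fate = "transient"
    n0 = sum(tr.present(0) for tr in tracks)
    nN = sum(tr.present(last) for tr in tracks)
    by = {f: sum(tr.fate == f for tr in tracks)
          for f in ("stable", "new", "pruned", "transient")}
    assert n0 == by["stable"] + by["pruned"], "t0 accounting identity violated"
    assert nN == by["stable"] + by["new"], "t_end accounting identity violated"
    return tracks


def transitions(tracks: List[SpineTrack]) -> TransitionSummary:
    """Class-transition fractions for protrusions present at t0.

    Newly formed protrusions are excluded. The outcome of a surviving track
    is its class at the last frame; pruned tracks count as pruned. Classes
    absent at t0 get an undefined (NaN) row, not zeros.
    """
    t0_tracks = [tr for tr in tracks if tr.present(0)]
    counts = pd.DataFrame(0, index=list(CLASSES), columns=OUTCOMES, dtype=float)
    for tr in t0_tracks:
        init = tr.initial_class
        if init not in CLASSES:
            continue
        outcome = "pruned" if tr.fate == "pruned" else f"to_{tr.final_class}"
        counts.loc[init, outcome] += 1
    n = counts.sum(axis=1)
    frac = counts.div(n, axis=0)           # NaN rows where n == 0
    frac["n"] = n.astype(int)
    total = float(n.sum())
    incidence = counts / total if total else counts * np.nan
    incidence["n"] = n.astype(int)
    return TransitionSummary(by_class=frac, incidence=incidence,
                             n_t0=int(total))


def fate_group_geometry(tracks: List[SpineTrack], initial_class: str,
                        remodeled_to: Optional[str] = None) -> pd.DataFrame:
    """Initial (t0) geometry means for stable / remodeled / pruned groups.

    Groups partition the tracked protrusions of ``initial_class`` present
    at t0: *stable* kept the class to the last frame, *remodeled* survived
    with a different final class (optionally restricted to
    ``remodeled_to``), *pruned* disappeared. Empty groups are omitted.
    """
    sel = [tr for tr in tracks
           if tr.present(0) and tr.initial_class == initial_class]
    groups: Dict[str, list] = {"stable": [], "remodeled": [], "pruned": []}
    for tr in sel:
        if tr.fate == "pruned":
            groups["pruned"].append(tr)
        elif tr.final_class == initial_class:
            groups["stable"].append(tr)
        else:
            if remodeled_to is None or tr.final_class == remodeled_to:
                groups["remodeled"].append(tr)
    rows = {}
    for name, members in groups.items():
        if not members:
            continue
        recs = [tr.records[0] for tr in members]
        rows[name] = {
            "n": len(recs),
            "head_width_um": np.mean([r.head_width for r in recs]),
            "neck_width_um": np.mean([r.neck_width for r in recs]),
            "length_um": np.mean([r.length for r in recs]),
            "head_neck_ratio": np.mean([r.head_neck_ratio for r in recs]),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def track_series(volumes, start_points, config: Optional[AnalysisConfig] = None):
    """Analyze every frame, link, and assign fates.

    ``start_points`` is one (z, y, x) um point or one per frame. Returns
    ``(traces, records_per_time, tracks)``.
    """
    from .spines import analyze
    cfg = (config or AnalysisConfig.live()).validate()
    pts = start_points
    if np.ndim(pts) == 1:
        pts = [pts] * len(volumes)
    traces, per_time = [], []
    for vol, p in zip(volumes, pts):
        tr, recs = analyze(vol, p, cfg)
        traces.append(tr)
        per_time.append(recs)
    tracks = link(per_time, traces, gate=cfg.tracking_gate,
                  azimuth_weight=cfg.azimuth_cost_weight)
    fates(tracks, len(volumes))
    return traces, per_time, tracks
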