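"""Rule-based classification of roadblock collisions, inter-DNA transfers
and lesion-recognition events.

All classifiers work on tracked positions only (no simulator internals), so
they can be validated against the simulator's ground-truth logs.

Collision scoring: protein and roadblock cannot be resolved within a
"collision zone" of 3x the localization s.d. around the roadblock (750 bp
= ~200 nm at curtain extension for a 250 bp s.d.).  A collision is a
maximal in-zone episode; it is a bypass when the protein enters from one
side and exits on the other, a rejected collision when it returns to the
entry side, and unresolved when the track ends inside the zone.  Motion is
interpolated linearly between detections, so a fast traversal spanning the
zone within one frame still counts.

Transfer scoring between adjacent DNA axes uses three criteria: (i) >= 4 s
diffusing in register with one DNA, (ii) the switch completes within one
frame, (iii) >= 4 further seconds in register with the neighbour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator
from statsmodels.stats.proportion import proportion_confint

from .obstacles import LesionSite, Roadblock
from .tracking import Trajectory

OUTCOME_BYPASS = "bypass"
OUTCOME_REJECTED = "same-side-return"
OUTCOME_UNRESOLVED = "unresolved-at-track-end"


@dataclass
class CollisionEvent:
    trajectory_id: int
    roadblock_id: str
    entry_time_s: float
    entry_side: str  # "left" | "right"
    exit_time_s: Optional[float]
    exit_side: Optional[str]
    outcome: str


@dataclass
class TransferEvent:
    trajectory_id: int
    source_axis: int
    destination_axis: int
    switch_frame: int
    dwell_before_s: float
    dwell_after_s: float
    in_register_before: bool = True
    single_frame_switch: bool = True
    in_register_after: bool = True

    @property
    def valid(self) -> bool:
        return self.in_register_before and self.single_frame_switch and self.in_register_after


def score_collisions(
    track: Trajectory, roadblocks: Sequence[Roadblock]
) -> List[CollisionEvent]:
    """Maximal collision-zone episodes for each roadblock along one track."""
    pos = track.positions_bp[track.detected]
    times = track.times_s[track.detected]
    if len(pos) == 0:
        return []
    length_bp = track.geometry.length_bp if track.geometry else None
    events: List[CollisionEvent] = []
    for rb in roadblocks:
        if rb.dna_axis_id != track.dna_axis_id:
            continue
        lo = rb.position_bp - rb.collision_zone_halfwidth_bp
        hi = rb.position_bp + rb.collision_zone_halfwidth_bp
        if lo < 0 or (length_bp is not None and hi > length_bp):
            warnings.warn(
                f"collision zone of roadblock {rb.id} clipped at a DNA end"
            )
            lo = max(lo, 0.0)
            if length_bp is not None:
                hi = min(hi, float(length_bp))

        def region(p: float) -> int:
            if p < lo:
                return -1
            if p > hi:
                return 1
            return 0

        state = region(pos[0])
        entry_side = None
        entry_time = None
        if state == 0:
            # starts inside the zone: no defined entry side
            entry_side, entry_time = None, times[0]
        for k in range(1, len(pos)):
            r = region(pos[k])
            if state != 0 and r == 0:
                entry_side = "left" if state == -1 else "right"
                entry_time = times[k]
                state = 0
            elif state == 0 and r != 0:
                exit_side = "left" if r == -1 else "right"
                if entry_side is None:
                    pass  # started in-zone; cannot score a traversal
                else:
                    events.append(
                        CollisionEvent(
                            trajectory_id=track.molecule_id,
                            roadblock_id=rb.id,
                            entry_time_s=float(entry_time),
                            entry_side=entry_side,
                            exit_time_s=float(times[k]),
                            exit_side=exit_side,
                            outcome=OUTCOME_BYPASS
                            if exit_side != entry_side
                            else OUTCOME_REJECTED,
                        )
                    )
                state = r
                entry_side = None
            elif state != 0 and r != 0 and r != state:
                # spanned the whole zone between two detections: linear
                # interpolation passes through it — a single-frame bypass
                side = "left" if state == -1 else "right"
                events.append(
                    CollisionEvent(
                        trajectory_id=track.molecule_id,
                        roadblock_id=rb.id,
                        entry_time_s=float(times[k - 1]),
                        entry_side=side,
                        exit_time_s=float(times[k]),
                        exit_side="right" if side == "left" else "left",
                        outcome=OUTCOME_BYPASS,
                    )
                )
                state = r
        if state == 0 and entry_side is not None:
            events.append(
                CollisionEvent(
                    trajectory_id=track.molecule_id,
                    roadblock_id=rb.id,
                    entry_time_s=float(entry_time),
                    entry_side=entry_side,
                    exit_time_s=None,
                    exit_side=None,
                    outcome=OUTCOME_UNRESOLVED,
                )
            )
    return events


@dataclass
class BypassFrequency:
    fraction: float
    n_bypass: int
    n_resolved: int
    n_unresolved: int
    ci_low: float
    ci_high: float


def bypass_frequency(events: Sequence[CollisionEvent]) -> BypassFrequency:
    """Bypasses / resolved collisions with a Wilson 95% interval."""
    n_bypass = sum(e.outcome == OUTCOME_BYPASS for e in events)
    n_unres = sum(e.outcome == OUTCOME_UNRESOLVED for e in events)
    n_resolved = len(events) - n_unres
    if n_resolved == 0:
        raise ValueError("no resolved collisions to score")
    lo, hi = proportion_confint(n_bypass, n_resolved, alpha=0.05, method="wilson")
    return BypassFrequency(
        fraction=n_bypass / n_resolved,
        n_bypass=n_bypass,
        n_resolved=n_resolved,
        n_unresolved=n_unres,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def score_transfers(
    track: Trajectory,
    axis_lateral_um: Sequence[float],
    min_dwell_s: float = 4.0,
    max_switch_frames: int = 1,
    register_tolerance_um: float = 0.25,
) -> List[TransferEvent]:
    """Inter-DNA transfer events from a track's lateral coordinate.

    Each detection is assigned to the nearest DNA axis within
    ``register_tolerance_um`` (default ~3x the localization s.d. at curtain
    extension); an event is emitted when the assignment changes within
    ``max_switch_frames`` with at least ``min_dwell_s`` of continuous
    assignment on each side.
    """
    if len(axis_lateral_um) < 2:
        return []
    if track.lateral_um is None:
        raise ValueError("track has no lateral coordinate")
    lat = np.asarray(track.lateral_um, dtype=float)
    det = track.detected
    axes = np.asarray(axis_lateral_um, dtype=float)
    assign = np.full(len(lat), -1)
    for k in np.flatnonzero(det):
        d = np.abs(axes - lat[k])
        j = int(np.argmin(d))
        if d[j] <= register_tolerance_um:
            assign[k] = j

    # contiguous runs of a single axis assignment (unassigned frames split)
    runs = []  # (axis, first_frame, last_frame)
    for k, a in enumerate(assign):
        if a < 0:
            continue
        if runs and runs[-1][0] == a and k - runs[-1][2] <= max_switch_frames:
            runs[-1][2] = k
        else:
            runs.append([a, k, k])

    dt = track.frame_interval_s
    events: List[TransferEvent] = []
    for r0, r1 in zip(runs, runs[1:]):
        if r0[0] == r1[0]:
            continue
        dwell_before = (r0[2] - r0[1] + 1) * dt
        dwell_after = (r1[2] - r1[1] + 1) * dt
        ev = TransferEvent(
            trajectory_id=track.molecule_id,
            source_axis=int(r0[0]),
            destination_axis=int(r1[0]),
            switch_frame=int(r1[1]),
            dwell_before_s=dwell_before,
            dwell_after_s=dwell_after,
            in_register_before=dwell_before >= min_dwell_s,
            single_frame_switch=(r1[1] - r0[2]) <= max_switch_frames,
            in_register_after=dwell_after >= min_dwell_s,
        )
        if ev.valid:
            events.append(ev)
    return events


@dataclass
class LesionBindingHistogram:
    bin_edges_bp: np.ndarray
    counts: np.ndarray
    n: int
    center_bp: float = math.nan
    sigma_bp: float = math.nan
    amplitude: float = math.nan
    fit_ok: bool = False
    peaked: bool = False


class LesionPeakFitter(BaseEstimator):
    """Histogram + Gaussian peak fit of lesion-binding positions."""

    def __init__(self, bin_width_bp: float = 500.0):
        self.bin_width_bp = bin_width_bp

    def fit(self, positions_bp):
        positions_bp = np.asarray(positions_bp, dtype=float)
        n = len(positions_bp)
        if n < 10:
            raise ValueError("need >= 10 binding positions to fit a peak")
        lo = self.bin_width_bp * math.floor(positions_bp.min() / self.bin_width_bp)
        hi = self.bin_width_bp * math.ceil(positions_bp.max() / self.bin_width_bp)
        if hi <= lo:
            hi = lo + self.bin_width_bp
        edges = np.arange(lo, hi + self.bin_width_bp / 2, self.bin_width_bp)
        counts, edges = np.histogram(positions_bp, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        self.bin_edges_ = edges
        self.counts_ = counts
        self.n_ = n
        self.fit_ok_ = False
        self.peaked_ = False
        self.center_ = self.sigma_ = self.amplitude_ = math.nan
        try:
            p0 = [counts.max(), positions_bp.mean(), max(positions_bp.std(), self.bin_width_bp / 2)]
            popt, _ = curve_fit(
                lambda x, a, mu, s: a * np.exp(-((x - mu) ** 2) / (2 * s**2)),
                centers,
                counts,
                p0=p0,
                maxfev=2000,
            )
            amp, mu, sig = popt
            sig = abs(sig)
            span = edges[-1] - edges[0]
            if amp > 0 and 0 < sig < span:
                self.fit_ok_ = True
                self.center_, self.sigma_, self.amplitude_ = float(mu), float(sig), float(amp)
                self.peaked_ = bool(amp >= 2.0 * np.median(counts) + 1)
        except Exception:
            pass
        return self

    def result_(self) -> LesionBindingHistogram:
        return LesionBindingHistogram(
            bin_edges_bp=self.bin_edges_,
            counts=self.counts_,
            n=self.n_,
            center_bp=self.center_,
            sigma_bp=self.sigma_,
            amplitude=self.amplitude_,
            fit_ok=self.fit_ok_,
            peaked=self.peaked_,
        )


def lesion_histogram(positions_bp, bin_width_bp: float = 500.0) -> LesionBindingHistogram:
    return LesionPeakFitter(bin_width_bp=bin_width_bp).fit(positions_bp).result_()


MODE_DIRECT = "direct-3D"
MODE_SLIDING = "sliding-1D"
MODE_AMBIGUOUS = "ambiguous"
MODE_NONE = "no recognition"


@dataclass
class RecognitionCall:
    trajectory_id: int
    mode: str
    pre_arrest_path_bp: float
    first_detection_distance_bp: float


def classify_recognition(
    track: Trajectory,
    lesion: LesionSite,
    direct_threshold_bp: float = 300.0,
    sliding_threshold_bp: float = 1000.0,
    arrest_frames: int = 10,
    loc_sigma_bp: float = 250.0,
) -> RecognitionCall:
    """Direct (3D-collision) vs 1D-scanning lesion recognition.

    Arrest = the terminal run of >= ``arrest_frames`` consecutive detected
    frames whose positions stay within one localization s.d. of the final
    position.  A track is a recognition event only if it arrests within
    ``direct_threshold_bp`` of the lesion.  Direct-3D: first detection
    already within the direct threshold and arrest immediate (from the
    first or second frame).  Sliding-1D: cumulative pre-arrest path
    >= ``sliding_threshold_bp``.  Anything in between is ambiguous.
    """
    pos = track.positions_bp[track.detected]
    if len(pos) < arrest_frames:
        return RecognitionCall(track.molecule_id, MODE_NONE, 0.0, math.nan)
    final = pos[-1]
    k = len(pos)
    while k > 0 and abs(pos[k - 1] - final) < loc_sigma_bp:
        k -= 1
    arrest_start = k  # index of first arrested sample
    arrest_len = len(pos) - arrest_start
    first_dist = abs(pos[0] - lesion.position_bp)
    if arrest_len < arrest_frames or abs(final - lesion.position_bp) > direct_threshold_bp:
        return RecognitionCall(track.molecule_id, MODE_NONE, 0.0, float(first_dist))
    pre = pos[: arrest_start + 1]
    path = float(np.sum(np.abs(np.diff(pre)))) if len(pre) > 1 else 0.0
    if first_dist <= direct_threshold_bp and arrest_start <= 1:
        mode = MODE_DIRECT
    elif path >= sliding_threshold_bp:
        mode = MODE_SLIDING
    else:
        mode = MODE_AMBIGUOUS
    return RecognitionCall(track.molecule_id, mode, path, float(first_dist))
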