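"""Gait analysis: stance rasters, duty factors, relative phases, labels.

A gait diagram is obtained by thresholding per-leg vertical ground reaction
forces (default threshold: 10 % of the trial's maximum force, the rule that
yields 1.5 N on a robot peaking near 15 N).  Touchdown events are rising
edges of the stance raster — i.e. they come from sensing, not from the
oscillator's stance intention.  Gait labels are rule-based:

tripod        (L1,R2,L3) and (R1,L2,R3) each mutually in-phase, the two
              triplets in anti-phase;
tetrapod      ipsilateral touchdown order hind -> middle -> fore on both
              sides, at most two legs swinging at a time;
wave          same ordering with duty factor above 0.75;
trot_ls_walk  four intact legs with (L1,R3) and (R1,L3) diagonal pairs
              alternating in near anti-phase (sub-label ``trot`` for
              simultaneous pair touchdowns, ``ls_walk`` for the staggered
              order L1, R3, R1, L3);
other         anything else.

In-phase / anti-phase tests use a tolerance delta (default pi/6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .legs import LEGS, Leg, Rank, Side

__all__ = [
    "clean_diagram",
    "DELTA_DEFAULT",
    "WAVE_DUTY_THRESHOLD",
    "GaitDiagram",
    "DutyFactorTable",
    "GaitLabel",
    "detect_stance",
    "touchdown_times",
    "estimate_period",
    "duty_factors",
    "relative_phases",
    "classify_gait",
    "windowed_labels",
    "convergence_time",
    "InsufficientDataError",
]

DELTA_DEFAULT = math.pi / 6
WAVE_DUTY_THRESHOLD = 0.75
TWO_PI = 2.0 * math.pi

_TRIPOD_A = [Leg.L1.index, Leg.R2.index, Leg.L3.index]
_TRIPOD_B = [Leg.R1.index, Leg.L2.index, Leg.R3.index]


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested statistic."""


@dataclass
class GaitDiagram:
    """Binary stance raster: 1 = stance, 0 = swing, per leg over time."""

    stance: np.ndarray       # (S, 6) uint8
    sample_dt: float         # s between rows
    threshold: float         # N
    t0: float = 0.0          # time of the first row

    def __post_init__(self):
        self.stance = np.asarray(self.stance)
        if self.stance.ndim != 2 or self.stance.shape[1] != 6:
            raise ValueError("stance raster must have shape (S, 6)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        self.stance = (self.stance != 0).astype(np.uint8)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.sample_dt * np.arange(self.stance.shape[0])

    @property
    def duration(self) -> float:
        return self.sample_dt * (self.stance.shape[0] - 1)

    def window(self, t_start: float, t_end: float) -> "GaitDiagram":
        """Sub-diagram restricted to [t_start, t_end]."""
        t = self.times
        mask = (t >= t_start - 1e-12) & (t <= t_end + 1e-12)
        if not mask.any():
            raise InsufficientDataError("window contains no samples")
        return GaitDiagram(self.stance[mask], self.sample_dt, self.threshold,
                           t0=float(t[mask][0]))

    def intact_legs(self) -> Tuple[Leg, ...]:
        """Legs that touch ground at least once (amputated legs are all-zero)."""
        return tuple(leg for leg in LEGS if self.stance[:, leg.index].any())


@dataclass
class DutyFactorTable:
    """Per-leg stance fraction over an averaging window."""

    per_leg: np.ndarray             # (6,), NaN for amputated legs
    window_periods: float
    per_rank: Dict[Rank, float] = field(default_factory=dict)

    def __post_init__(self):
        self.per_leg = np.asarray(self.per_leg, dtype=float)
        if not self.per_rank:
            self.per_rank = {
                rank: float(np.nanmean([
                    self.per_leg[leg.index] for leg in LEGS if leg.rank == rank
                ])) if np.any(np.isfinite([self.per_leg[leg.index]
                                           for leg in LEGS if leg.rank == rank]))
                else float("nan")
                for rank in Rank
            }


@dataclass
class GaitLabel:
    """Rule-based gait label plus the evidence it was derived from."""

    label: str                       # tripod | tetrapod | wave | trot_ls_walk | other
    sub_label: Optional[str] = None  # trot | ls_walk for the quadruped class
    phases: Optional[np.ndarray] = None      # (6, 6) pairwise relative phases, rad
    touchdown_order: Tuple[str, ...] = ()
    mean_duty: float = float("nan")
    note: str = ""


def detect_stance(
    forces: np.ndarray,
    sample_dt: float,
    threshold_mode: Tuple[str, float] = ("fraction", 0.10),
    t0: float = 0.0,
) -> GaitDiagram:
    """Threshold per-leg vertical forces into a stance raster.

    ``threshold_mode`` is ``("fraction", f)`` — stance where the force is at
    least ``f`` times the maximum force anywhere in the trial — or
    ``("absolute", newtons)``.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.ndim != 2 or forces.shape[1] != 6:
        raise ValueError("forces must have shape (S, 6)")
    if forces.shape[0] == 0:
        raise ValueError("empty force series")
    mode, value = threshold_mode
    peak = float(forces.max())
    if mode == "fraction":
        if peak <= 0:
            import warnings
            warnings.warn("all-zero force series: returning an all-swing diagram")
            return GaitDiagram(np.zeros_like(forces, dtype=np.uint8), sample_dt,
                               threshold=np.finfo(float).tiny, t0=t0)
        threshold = value * peak
    elif mode == "absolute":
        threshold = value
    else:
        raise ValueError(f"unknown threshold mode: {mode!r}")
    return GaitDiagram((forces >= threshold).astype(np.uint8), sample_dt,
                       threshold=threshold, t0=t0)


def clean_diagram(diagram: GaitDiagram, min_duration: float) -> GaitDiagram:
    """Suppress raster chatter: swing gaps and stance blobs shorter than
    ``min_duration`` seconds are removed (morphological closing then
    opening per leg).  Brief force dips or spikes around tipping transients
    otherwise produce spurious touchdown events."""
    from scipy.ndimage import binary_closing, binary_opening

    d = max(int(round(min_duration / diagram.sample_dt)), 1)
    if d <= 1:
        return diagram
    structure = np.ones(d, dtype=bool)
    cleaned = np.empty_like(diagram.stance)
    for j in range(6):
        col = diagram.stance[:, j].astype(bool)
        # pad with edge values so stance/swing runs touching the window
        # borders are not eroded
        pad = 2 * d
        padded = np.concatenate([np.full(pad, col[0]), col, np.full(pad, col[-1])])
        padded = binary_closing(padded, structure)
        padded = binary_opening(padded, structure)
        cleaned[:, j] = padded[pad:-pad]
    return GaitDiagram(cleaned, diagram.sample_dt, diagram.threshold, diagram.t0)


def touchdown_times(diagram: GaitDiagram) -> Dict[Leg, np.ndarray]:
    """Times of swing -> stance transitions (rising raster edges) per leg."""
    out = {}
    t = diagram.times
    for leg in LEGS:
        col = diagram.stance[:, leg.index]
        edges = np.flatnonzero((col[1:] == 1) & (col[:-1] == 0)) + 1
        out[leg] = t[edges]
    return out


def estimate_period(touchdowns: Dict[Leg, np.ndarray]) -> float:
    """Median inter-touchdown interval pooled over legs with >= 2 events."""
    diffs = []
    for times in touchdowns.values():
        if len(times) >= 2:
            diffs.append(np.diff(times))
    if not diffs:
        raise InsufficientDataError("no leg has two touchdown events")
    return float(np.median(np.concatenate(diffs)))


def duty_factors(
    diagram: GaitDiagram,
    window_periods: float = 6.0,
    period: Optional[float] = None,
) -> DutyFactorTable:
    """Per-leg stance fraction over the trailing ``window_periods`` periods.

    The period defaults to the median inter-touchdown interval measured from
    the diagram itself.  Legs that never touch ground are reported as NaN.
    """
    if period is None:
        period = estimate_period(touchdown_times(diagram))
    span = window_periods * period
    if span > diagram.duration + diagram.sample_dt / 2:
        raise InsufficientDataError(
            f"diagram spans {diagram.duration:.2f} s but "
            f"{window_periods} x {period:.2f} s = {span:.2f} s are required")
    t_end = diagram.t0 + diagram.duration
    win = diagram.window(t_end - span, t_end)
    values = win.stance.mean(axis=0)
    for leg in LEGS:
        if not diagram.stance[:, leg.index].any():
            values[leg.index] = float("nan")
    return DutyFactorTable(per_leg=values, window_periods=window_periods)


def _circular_mean(angles: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * np.asarray(angles))))) % TWO_PI


def relative_phases(
    touchdowns: Dict[Leg, np.ndarray],
    period: Optional[float] = None,
    min_events: int = 2,
) -> np.ndarray:
    """Pairwise touchdown phase lags in [0, 2*pi).

    ``phase[i, j]`` is the circular mean over cycles of the lag of leg j's
    touchdown after leg i's, as a fraction of the period.  Pairs involving a
    leg with fewer than ``min_events`` touchdowns are NaN.
    """
    if period is None:
        period = estimate_period(touchdowns)
    phase = np.full((6, 6), np.nan)
    for li in LEGS:
        ti = touchdowns[li]
        if len(ti) < min_events:
            continue
        for lj in LEGS:
            tj = touchdowns[lj]
            if len(tj) < min_events:
                continue
            if li is lj:
                phase[li.index, lj.index] = 0.0
                continue
            lags = []
            for tau in ti:
                pos = np.searchsorted(tj, tau)
                if pos < len(tj):
                    lags.append(TWO_PI * ((tj[pos] - tau) % period) / period)
            if lags:
                phase[li.index, lj.index] = _circular_mean(np.array(lags))
    return phase


def _wrap_pi(angle):
    return (angle + math.pi) % TWO_PI - math.pi


def _in_phase(angle: float, delta: float) -> bool:
    return np.isfinite(angle) and abs(_wrap_pi(angle)) <= delta


def _anti_phase(angle: float, delta: float) -> bool:
    return np.isfinite(angle) and abs(_wrap_pi(angle - math.pi)) <= delta


def _order_fraction(touchdowns: Dict[Leg, np.ndarray], sequence: Sequence[Leg]) -> float:
    """Fraction of cycles (anchored on the first leg of ``sequence``) in which
    the remaining legs each touch down exactly once, in the given order."""
    anchor = touchdowns[sequence[0]]
    if len(anchor) < 2:
        return 0.0
    good = 0
    cycles = 0
    for k in range(len(anchor) - 1):
        t_a, t_b = anchor[k], anchor[k + 1]
        cycles += 1
        times = []
        ok = True
        for leg in sequence[1:]:
            inside = touchdowns[leg][(touchdowns[leg] > t_a) & (touchdowns[leg] < t_b)]
            if len(inside) != 1:
                ok = False
                break
            times.append(inside[0])
        if ok and all(times[i] < times[i + 1] for i in range(len(times) - 1)):
            good += 1
    return good / cycles if cycles else 0.0


def _metachronal_ok(touchdowns: Dict[Leg, np.ndarray], side: Side,
                    min_fraction: float = 0.75) -> bool:
    hind = Leg.from_side_rank(side, Rank.HIND)
    middle = Leg.from_side_rank(side, Rank.MIDDLE)
    fore = Leg.from_side_rank(side, Rank.FORE)
    return _order_fraction(touchdowns, (hind, middle, fore)) >= min_fraction


def classify_gait(
    diagram: GaitDiagram,
    phases: Optional[np.ndarray] = None,
    intact: Optional[Iterable[Leg]] = None,
    delta: float = DELTA_DEFAULT,
) -> GaitLabel:
    """Assign a rule-based gait label to a stance raster.

    ``phases`` may carry a precomputed pairwise relative-phase matrix;
    otherwise it is derived from the raster's touchdown events.  ``intact``
    defaults to the legs that ever touch ground.
    """
    touchdowns = touchdown_times(diagram)
    intact = tuple(intact) if intact is not None else diagram.intact_legs()
    intact_idx = [leg.index for leg in intact]
    try:
        period = estimate_period({l: touchdowns[l] for l in intact})
    except InsufficientDataError:
        return GaitLabel("other", note="insufficient touchdown events")
    # de-chatter before event analysis; re-estimate the period afterwards
    diagram = clean_diagram(diagram, 0.15 * period)
    touchdowns = touchdown_times(diagram)
    try:
        period = estimate_period({l: touchdowns[l] for l in intact})
    except InsufficientDataError:
        return GaitLabel("other", note="insufficient touchdown events")
    if phases is None:
        phases = relative_phases(touchdowns, period)

    duty = diagram.stance[:, intact_idx].mean() if intact_idx else float("nan")
    order = _typical_order(touchdowns, intact)

    if len(intact) == 6:
        label = _classify_hexapod(diagram, phases, touchdowns, duty, delta)
    elif set(intact) == {Leg.L1, Leg.R1, Leg.L3, Leg.R3}:
        label = _classify_quadruped(phases, touchdowns, delta)
    else:
        label = GaitLabel("other", note="unsupported intact-leg set")
    label.phases = phases
    label.touchdown_order = order
    label.mean_duty = float(duty)
    return label


def _typical_order(touchdowns: Dict[Leg, np.ndarray], intact) -> Tuple[str, ...]:
    """Touchdown order within a typical cycle, anchored on the first intact
    leg's median cycle."""
    anchor = intact[0]
    times = touchdowns[anchor]
    if len(times) < 3:
        return ()
    k = len(times) // 2
    t_a, t_b = times[k], times[k + 1]
    events = [(t_a, anchor.label)]
    for leg in intact:
        if leg is anchor:
            continue
        inside = touchdowns[leg][(touchdowns[leg] >= t_a) & (touchdowns[leg] < t_b)]
        events.extend((t, leg.label) for t in inside)
    return tuple(label for _, label in sorted(events))


def _triad_coherence(phases, ref: int, members) -> Tuple[float, float]:
    """Circular mean and max deviation of a leg triad's touchdown phases,
    measured relative to ``ref``'s touchdowns."""
    angles = np.array([phases[ref, j] for j in members])
    if not np.all(np.isfinite(angles)):
        return float("nan"), float("inf")
    mean = _circular_mean(angles)
    dev = float(np.max(np.abs(_wrap_pi(angles - mean))))
    return mean, dev


def _classify_hexapod(diagram, phases, touchdowns, duty, delta) -> GaitLabel:
    a, b = _TRIPOD_A, _TRIPOD_B
    # tripod: each triad clusters around its own touchdown phase (every
    # member within delta of the triad circular mean) and the two cluster
    # centers alternate in anti-phase
    ref = a[0]
    mean_a, dev_a = _triad_coherence(phases, ref, a)
    mean_b, dev_b = _triad_coherence(phases, ref, b)
    if (dev_a <= delta and dev_b <= delta
            and _anti_phase(mean_b - mean_a, delta)):
        return GaitLabel("tripod")
    metachronal = (_metachronal_ok(touchdowns, Side.LEFT)
                   and _metachronal_ok(touchdowns, Side.RIGHT))
    if metachronal:
        if duty > WAVE_DUTY_THRESHOLD:
            return GaitLabel("wave")
        # tetrapod keeps most legs loaded most of the time; the 10 %-of-max
        # threshold trims the edges of each stance band, so the gate is a
        # median of at least three simultaneously loaded legs
        swing_count = 6 - diagram.stance.sum(axis=1)
        if np.median(swing_count) <= 3:
            return GaitLabel("tetrapod")
        return GaitLabel("other", note="metachronal order but too few support legs")
    return GaitLabel("other")


def _classify_quadruped(phases, touchdowns, delta) -> GaitLabel:
    l1, r1, l3, r3 = Leg.L1.index, Leg.R1.index, Leg.L3.index, Leg.R3.index
    pairs_alternate = (_anti_phase(phases[l1, r1], delta)
                       and _anti_phase(phases[l3, r3], delta))
    if not pairs_alternate:
        return GaitLabel("other")
    # diagonal partner lands within the half-cycle after its mate
    lag = _wrap_pi(phases[l1, r3])
    diagonal = -delta <= lag <= math.pi / 2 + delta
    lag2 = _wrap_pi(phases[r1, l3])
    diagonal &= -delta <= lag2 <= math.pi / 2 + delta
    if not diagonal:
        return GaitLabel("other", note="contralateral alternation without diagonal pairing")
    if abs(lag) <= delta and abs(lag2) <= delta:
        return GaitLabel("trot_ls_walk", sub_label="trot")
    if _order_fraction(touchdowns, (Leg.L1, Leg.R3, Leg.R1, Leg.L3)) >= 0.75:
        return GaitLabel("trot_ls_walk", sub_label="ls_walk")
    return GaitLabel("trot_ls_walk")


def windowed_labels(
    diagram: GaitDiagram,
    window_periods: float = 6.0,
    step_periods: float = 1.0,
    period: Optional[float] = None,
    delta: float = DELTA_DEFAULT,
    intact: Optional[Iterable[Leg]] = None,
) -> Tuple[List[float], List[GaitLabel]]:
    """Classify sliding windows; returns (window start times, labels)."""
    if period is None:
        period = estimate_period(touchdown_times(diagram))
    span = window_periods * period
    step = step_periods * period
    starts, labels = [], []
    t0, t_end = diagram.t0, diagram.t0 + diagram.duration
    t = t0
    while t + span <= t_end + 1e-9:
        win = diagram.window(t, t + span)
        labels.append(classify_gait(win, delta=delta, intact=intact))
        starts.append(t)
        t += step
    if not labels:
        raise InsufficientDataError("diagram shorter than one analysis window")
    return starts, labels


def convergence_time(window_starts: Sequence[float], labels: Sequence[GaitLabel]) -> float:
    """First window start time from which the label never changes again.

    Non-convergence (the final label held only by the very last window, or no
    windows at all) is reported as infinity.
    """
    if not labels:
        return math.inf
    final = labels[-1].label
    t_conv = math.inf
    run = 0
    for start, lab in zip(reversed(window_starts), reversed(labels)):
        if lab.label == final:
            t_conv = start
            run += 1
        else:
            break
    if run < 2 and len(labels) > 1:
        return math.inf
    return t_conv
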