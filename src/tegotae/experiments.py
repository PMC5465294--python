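"""Scenario harness: seeded multi-trial runs of the five standard experiments.

Scenarios (all with the common gains sigma1 = 0.2, k_a = 0.7, k_p = 0.1,
k_c = 0.2 and amplitudes A = 15 deg, B = 20 deg, B' = 5 deg):

steady_walk      omega = 2.0 rad/s, sigma2 = 1.2
speed_transition linear omega ramp 2.0 -> 4.0 rad/s over 40-42 s, sigma2 = 1.2
load_adaptation  as speed_transition plus a 500 g load on the hind
                 attachment line
amputation       omega = 2.0 rad/s, sigma2 = 1.2, middle legs L2/R2 removed
ablation_sigma2  omega = 2.0 rad/s, sigma2 = 0 (no neighbor feedback)

Each trial runs 50 s from independently drawn uniform-random initial phases;
experiments default to 10 trials.  Trial random streams derive from
(scenario seed, trial index) so results are order-insensitive and fully
reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .body import BodyConfig, amputate, apply_load
from .controller import TWO_PI, ControllerParams
from .gait import (DELTA_DEFAULT, DutyFactorTable, GaitDiagram, GaitLabel,
                   InsufficientDataError, classify_gait, convergence_time,
                   detect_stance, duty_factors, estimate_period,
                   touchdown_times, windowed_labels)
from .legs import Leg, Rank
from .simulate import OmegaRamp, TrialSeries, make_omega_fn, simulate

__all__ = [
    "SCENARIO_NAMES",
    "Scenario",
    "TrialResult",
    "ExperimentSummary",
    "make_scenario",
    "run_trial",
    "run_experiment",
    "compare_duty",
]

SCENARIO_NAMES = (
    "steady_walk",
    "speed_transition",
    "load_adaptation",
    "amputation",
    "ablation_sigma2",
)

#: labels counted as insect-like outcomes
INSECT_LIKE = ("tetrapod", "tripod")


@dataclass(frozen=True)
class Scenario:
    name: str
    params: ControllerParams
    body: BodyConfig
    omega_ramps: Tuple[OmegaRamp, ...] = ()
    duration: float = 50.0
    dt: float = 1e-3
    n_trials: int = 10
    seed: int = 0
    record_every: int = 5
    delta: float = DELTA_DEFAULT
    duty_window_periods: float = 6.0

    def __post_init__(self):
        if self.duration <= 0 or self.n_trials < 1:
            raise ValueError("duration must be positive and n_trials >= 1")

    def replace(self, **kw) -> "Scenario":
        return dataclasses.replace(self, **kw)


@dataclass
class TrialResult:
    trial_index: int
    seed: int
    initial_phases: np.ndarray
    final_label: GaitLabel
    pre_ramp_label: Optional[GaitLabel]
    convergence_time: float
    duty: DutyFactorTable
    fall_fraction: float
    series: TrialSeries
    diagram: GaitDiagram


@dataclass
class ExperimentSummary:
    scenario: Scenario
    trials: List[TrialResult]
    label_counts: Dict[str, int]
    label_fractions: Dict[str, float]
    duty_by_rank: Dict[Rank, Tuple[float, float]]   # mean, sd across trials
    transition_fraction: Optional[float]            # tetrapod -> tripod
    tetrapod_retained_fraction: Optional[float]     # pre and post tetrapod
    insect_like_fraction: float
    fall_trials: int


def _table1_common(**overrides) -> ControllerParams:
    return ControllerParams(**overrides)


def make_scenario(name: str, seed: int = 0, **overrides) -> Scenario:
    """Build one of the named scenarios with its standard parameters.

    ``overrides`` may replace any Scenario field, and ``params`` / ``body``
    accept partial dicts of field overrides.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    param_over = overrides.pop("params", {})
    body_over = overrides.pop("body", {})

    ramps: Tuple[OmegaRamp, ...] = ()
    body = BodyConfig(**body_over) if isinstance(body_over, dict) else body_over
    if name == "steady_walk":
        params = _table1_common(omega=2.0, sigma2=1.2)
    elif name == "speed_transition":
        params = _table1_common(omega=2.0, sigma2=1.2)
        ramps = (OmegaRamp(40.0, 42.0, 2.0, 4.0),)
    elif name == "load_adaptation":
        params = _table1_common(omega=2.0, sigma2=1.2)
        ramps = (OmegaRamp(40.0, 42.0, 2.0, 4.0),)
        # 500 g on the hind attachment line (lever-rule center-of-mass shift)
        hind_x = body.leg_attachment[Leg.L3][0]
        body = apply_load(body, 0.5, (hind_x, 0.0))
    elif name == "amputation":
        params = _table1_common(omega=2.0, sigma2=1.2)
        body = amputate(body, {Leg.L2, Leg.R2})
    else:  # ablation_sigma2
        params = _table1_common(omega=2.0, sigma2=0.0)
    if isinstance(param_over, dict):
        params = params.replace(**param_over)
    else:
        params = param_over
    scenario = Scenario(name=name, params=params, body=body,
                        omega_ramps=ramps, seed=seed)
    if overrides:
        scenario = scenario.replace(**overrides)
    return scenario


def _trial_rng(scenario: Scenario, trial_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=scenario.seed, spawn_key=(trial_index,))
    return np.random.default_rng(ss)


def run_trial(scenario: Scenario, trial_index: int) -> TrialResult:
    """Run one closed-loop trial and analyze its gait.

    Initial phases are independent uniform draws on [0, 2*pi) from a stream
    derived from (scenario.seed, trial_index).  The final label is assessed
    over the trailing six periods; for ramp scenarios a pre-ramp label is
    assessed over the six periods preceding the ramp start.
    """
    rng = _trial_rng(scenario, trial_index)
    init = rng.uniform(0.0, TWO_PI, size=6)
    omega_fn = make_omega_fn(scenario.params.omega, scenario.omega_ramps)
    series = simulate(
        scenario.params, scenario.body, scenario.duration, init,
        dt=scenario.dt, omega_fn=omega_fn, record_every=scenario.record_every,
    )
    diagram = detect_stance(series.forces, series.sample_dt)
    intact = scenario.body.intact()

    t_end = diagram.t0 + diagram.duration
    try:
        period = estimate_period(touchdown_times(diagram))
    except InsufficientDataError:
        period = TWO_PI / omega_fn(scenario.duration)
    span = scenario.duty_window_periods * period

    final_win = diagram.window(max(diagram.t0, t_end - span), t_end)
    final_label = classify_gait(final_win, delta=scenario.delta, intact=intact)
    try:
        duty = duty_factors(final_win, scenario.duty_window_periods, period)
    except InsufficientDataError:
        duty = DutyFactorTable(np.full(6, np.nan), scenario.duty_window_periods)

    pre_label = None
    if scenario.omega_ramps:
        t_ramp = min(r.t_start for r in scenario.omega_ramps)
        pre_period = TWO_PI / omega_fn(0.0)
        try:
            pre_win = diagram.window(max(diagram.t0, t_ramp - 6.0 * pre_period), t_ramp)
            pre_td = touchdown_times(pre_win)
            try:
                pre_period = estimate_period({l: pre_td[l] for l in intact})
            except InsufficientDataError:
                pass
            pre_label = classify_gait(pre_win, delta=scenario.delta, intact=intact)
        except InsufficientDataError:
            pre_label = GaitLabel("other", note="no pre-ramp window")

    try:
        starts, labels = windowed_labels(diagram, period=period,
                                         delta=scenario.delta, intact=intact)
        t_conv = convergence_time(starts, labels)
    except InsufficientDataError:
        t_conv = math.inf

    return TrialResult(
        trial_index=trial_index,
        seed=scenario.seed,
        initial_phases=init,
        final_label=final_label,
        pre_ramp_label=pre_label,
        convergence_time=t_conv,
        duty=duty,
        fall_fraction=float(series.fall.mean()),
        series=series,
        diagram=diagram,
    )


def run_experiment(scenario: Scenario, progress=None) -> ExperimentSummary:
    """Run ``scenario.n_trials`` independent trials and aggregate outcomes."""
    trials = []
    for k in range(scenario.n_trials):
        trials.append(run_trial(scenario, k))
        if progress is not None:
            progress(trials[-1])

    counts: Dict[str, int] = {}
    for tr in trials:
        counts[tr.final_label.label] = counts.get(tr.final_label.label, 0) + 1
    n = len(trials)
    fractions = {lab: c / n for lab, c in counts.items()}

    duty_by_rank = {}
    for rank in Rank:
        vals = [tr.duty.per_rank[rank] for tr in trials
                if np.isfinite(tr.duty.per_rank[rank])]
        duty_by_rank[rank] = ((float(np.mean(vals)), float(np.std(vals)))
                              if vals else (float("nan"), float("nan")))

    transition = None
    retained = None
    if scenario.omega_ramps:
        transition = sum(
            tr.pre_ramp_label is not None
            and tr.pre_ramp_label.label == "tetrapod"
            and tr.final_label.label == "tripod"
            for tr in trials) / n
        retained = sum(
            tr.pre_ramp_label is not None
            and tr.pre_ramp_label.label == "tetrapod"
            and tr.final_label.label == "tetrapod"
            for tr in trials) / n

    insect = sum(tr.final_label.label in INSECT_LIKE for tr in trials) / n
    return ExperimentSummary(
        scenario=scenario,
        trials=trials,
        label_counts=counts,
        label_fractions=fractions,
        duty_by_rank=duty_by_rank,
        transition_fraction=transition,
        tetrapod_retained_fraction=retained,
        insect_like_fraction=insect,
        fall_trials=sum(tr.fall_fraction > 0 for tr in trials),
    )


def compare_duty(summary_a: ExperimentSummary, summary_b: ExperimentSummary):
    """Per-rank duty-factor differences (a minus b) with paired sign tests.

    Both experiments must share the same intact-leg topology.  Returns a dict
    rank -> {mean_diff, n_pairs, sign_test_p}.
    """
    if summary_a.scenario.body.amputated != summary_b.scenario.body.amputated:
        raise ValueError("experiments have different leg topologies")
    out = {}
    for rank in Rank:
        da = [tr.duty.per_rank[rank] for tr in summary_a.trials]
        db = [tr.duty.per_rank[rank] for tr in summary_b.trials]
        pairs = [(x, y) for x, y in zip(da, db)
                 if np.isfinite(x) and np.isfinite(y)]
        if not pairs:
            out[rank] = {"mean_diff": float("nan"), "n_pairs": 0,
                         "sign_test_p": float("nan")}
            continue
        diffs = [x - y for x, y in pairs]
        positive = sum(d > 0 for d in diffs)
        nonzero = sum(d != 0 for d in diffs)
        p = (stats.binomtest(positive, nonzero, 0.5).pvalue
             if nonzero else float("nan"))
        out[rank] = {"mean_diff": float(np.mean(diffs)), "n_pairs": len(pairs),
                     "sign_test_p": float(p)}
    return out
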