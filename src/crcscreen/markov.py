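"""Decision-tree entry and annual-cycle Markov cohort engine.

The decision tree acts once, at baseline: a screening strategy splits the
cohort into detected CRC (screen pathway), undetected CRC (self-referral
pathway), post-colonoscopy healthy, and naive healthy, and charges the
screening costs.  The Markov engine then propagates annual cycles through
tunnel states that carry time since colonoscopy (lower CRC incidence for ten
years) and time since CRC diagnosis (year-specific CRC death probabilities;
survival to year ten is cure).

Conventions: one-year cycles, end-of-cycle state valuation, costs and QALYs
discounted at ``(1+r)^-t`` with baseline (cycle 0) spending undiscounted,
cause-specific CRC death applied before background mortality, CRC treatment
charged once at diagnosis as a detection-mode composite cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .parameters import ParameterSet, ValidationError

__all__ = [
    "StrategySpec",
    "HorizonSpec",
    "InitialDistribution",
    "ModelOutputs",
    "MarkovCohortModel",
    "CohortResults",
    "STATE_LABELS",
    "apply_strategy",
    "build_transitions",
    "run_cohort",
    "discount_factor",
]

STRATEGIES = ("none", "sequential", "colonoscopy")

# state-vector layout
_HN = 0                       # healthy, never colonoscoped
_PC = slice(1, 11)            # post-colonoscopy years 1..10
_CS = slice(11, 21)           # CRC, screen-detected, tunnel years 1..10
_CF = slice(21, 31)           # CRC, self-referred, tunnel years 1..10
_CURED = 31
_DEAD_CRC = 32
_DEAD_OTHER = 33
N_STATES = 34

STATE_LABELS = (
    ["healthy_naive"]
    + [f"healthy_postcolo_{k}" for k in range(1, 11)]
    + [f"crc_screen_{k}" for k in range(1, 11)]
    + [f"crc_self_{k}" for k in range(1, 11)]
    + ["cured", "dead_crc", "dead_other"]
)


def discount_factor(rate: float, cycle: int) -> float:
    """End-of-cycle discount multiplier ``(1 + rate) ** -cycle``."""
    if rate < 0:
        raise ValidationError("discount rate must be non-negative")
    return (1.0 + rate) ** (-cycle)


@dataclass(frozen=True)
class StrategySpec:
    """Screening arm and its colonoscopy acceptance.

    ``colo_acceptance`` is the probability of completing colonoscopy among
    referred high-risk participants (sequential) or among the whole target
    population (direct colonoscopy); it is ignored for ``none``.
    """

    name: str
    colo_acceptance: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in STRATEGIES:
            raise ValidationError(f"unknown strategy {self.name!r}")
        if not (0.0 <= self.colo_acceptance <= 1.0):
            raise ValidationError("colo_acceptance must be in [0, 1]")


@dataclass(frozen=True)
class HorizonSpec:
    """Run length and accounting windows.

    ``cycles``: maximum number of annual cycles; ``count_window``: cycles over
    which the epidemiological tallies (new CRC, cumulative CRC deaths) are
    collected; economics always accrue over the whole run.  ``stop_tol``
    terminates a lifetime run early once the living occupancy falls below it.
    """

    cycles: int
    count_window: int
    stop_tol: float = 0.0

    @classmethod
    def preset(cls, name: str) -> "HorizonSpec":
        if name == "paper-10y":
            return cls(cycles=10, count_window=10)
        if name == "lifetime":
            return cls(cycles=60, count_window=10, stop_tol=1e-6)
        raise ValidationError(f"unknown horizon preset {name!r}")


@dataclass(frozen=True)
class InitialDistribution:
    """Cohort occupancy after the baseline decision tree."""

    occupancy: np.ndarray
    upfront_cost: float          # per-capita screening spend at baseline
    colonoscopies: float         # fraction of the population colonoscoped
    diagnosed_screen: float      # prevalent CRC detected at baseline
    diagnosed_self: float        # prevalent CRC entering via self-referral

    def __post_init__(self) -> None:
        if abs(self.occupancy.sum() - 1.0) > 1e-12:
            raise ValidationError("initial occupancy must sum to 1")
        if self.upfront_cost < 0:
            raise ValidationError("upfront cost must be non-negative")


def apply_strategy(params: ParameterSet, strategy: StrategySpec) -> InitialDistribution:
    """Apply the baseline decision tree of one screening strategy.

    Prevalent CRC (``prev_general``) is split between screen detection and
    self-referral.  Under sequential screening the primary screen flags a
    cancer with probability ``sens_primary``; flagged cancers are detected iff
    the participant completes colonoscopy.  Under direct colonoscopy a
    fraction ``colo_acceptance`` of everyone is colonoscoped and their cancers
    are all found.  Undetected prevalent cancers enter the self-referred
    pathway at baseline.  Colonoscoped non-cancer participants enter the
    post-colonoscopy (low-incidence) state.
    """
    prev = params.prev_general
    occ = np.zeros(N_STATES)
    a = strategy.colo_acceptance

    if strategy.name == "none":
        colos, detected, upfront = 0.0, 0.0, 0.0
    elif strategy.name == "sequential":
        colos = params.p_high * a
        detected = a * params.sens_primary * prev
        upfront = params.c_fit + colos * params.c_colo
    else:  # direct colonoscopy
        colos = a
        detected = a * prev
        upfront = colos * params.c_colo

    healthy_postcolo = colos - detected
    occ[_CS.start] = detected
    occ[_CF.start] = prev - detected
    occ[1] = healthy_postcolo            # post-colonoscopy year 1
    occ[_HN] = 1.0 - prev - healthy_postcolo
    if occ[_HN] < 0:
        raise ValidationError("strategy assigns more mass than the cohort holds")
    return InitialDistribution(occ, upfront, colos, detected, prev - detected)


@dataclass(frozen=True)
class ModelOutputs:
    """Per-capita discounted economics and population-scaled tallies."""

    per_capita_cost: float
    per_capita_qaly: float
    new_crc: float               # incident diagnoses within the count window
    cum_crc_deaths: float        # CRC deaths within the count window
    colonoscopies: float         # completed baseline colonoscopies
    total_crc_deaths: float      # CRC deaths over the whole run
    cycles_run: int


class CohortResults:
    """Results of one cohort run: outputs, cycle trace, and a summary view."""

    def __init__(self, model: "MarkovCohortModel", outputs: ModelOutputs,
                 trace: pd.DataFrame):
        self.model = model
        self.outputs = outputs
        self.trace = trace

    def __getattr__(self, name):
        return getattr(object.__getattribute__(self, "outputs"), name)

    def summary(self) -> str:
        o = self.outputs
        s = self.model.strategy
        lines = [
            "Markov cohort run",
            "-" * 46,
            f"strategy            : {s.name}"
            + ("" if s.name == "none" else f" (acceptance {s.colo_acceptance:.1%})"),
            f"population          : {self.model.params.population:,}",
            f"cycles run          : {o.cycles_run}",
            f"count window        : {self.model.horizon.count_window} years",
            f"colonoscopies       : {o.colonoscopies:,.0f}",
            f"new CRC (window)    : {o.new_crc:,.0f}",
            f"cum CRC deaths      : {o.cum_crc_deaths:,.0f}",
            f"per-capita cost     : {o.per_capita_cost:,.2f} USD",
            f"per-capita QALYs    : {o.per_capita_qaly:.4f}",
        ]
        return "\n".join(lines)


class MarkovCohortModel:
    """Markov cohort model for one screening strategy.

    Parameters
    ----------
    params : ParameterSet
        Model parameters (point values are used; see ``uncertainty`` for
        sampled runs).
    strategy : StrategySpec
        Screening arm applied at baseline.
    horizon : str or HorizonSpec
        ``"paper-10y"`` (10 cycles) or ``"lifetime"`` (run to cohort
        extinction, capped at 60 cycles, epidemiological counts tallied over
        the first 10 years).
    """

    def __init__(self, params: ParameterSet, strategy: StrategySpec,
                 horizon: str | HorizonSpec = "lifetime"):
        self.params = params
        self.strategy = strategy
        self.horizon = (HorizonSpec.preset(horizon)
                        if isinstance(horizon, str) else horizon)
        self._age_weights = np.ones(26) / 26.0  # uniform entry ages 50..75
        self._entry_ages = np.arange(50, 76)

    # -- building blocks ----------------------------------------------------

    def background_mortality(self, cycle: int) -> float:
        """All-cause (non-CRC) death probability during ``cycle`` (1-based)."""
        lt = self.params.life_table
        if lt is None:
            return self.params.mort_bg
        return lt.weighted_mortality(self._entry_ages + cycle - 1,
                                     self._age_weights)

    def _postcolo_incidence(self) -> np.ndarray:
        p = self.params
        return np.where(np.arange(1, 11) <= 5,
                        p.inc_postcolo_0_5, p.inc_postcolo_5_10)

    def transition_matrix(self, cycle: int) -> np.ndarray:
        """Row-stochastic transition matrix for one cycle (rows = origin)."""
        p = self.params
        qx = self.background_mortality(cycle)
        q_screen = p.annual_crc_death("screen")
        q_self = p.annual_crc_death("self")
        M = np.zeros((N_STATES, N_STATES))

        # healthy states: CRC incidence first, background death on the rest
        inc_h = np.concatenate([[p.inc_general], self._postcolo_incidence()])
        rows_h = np.arange(0, 11)              # healthy_naive, postcolo 1..10
        nxt_h = np.concatenate([[_HN], np.arange(2, 11), [_HN]])
        M[rows_h, _CF.start] = inc_h * (1 - qx)
        M[rows_h, _DEAD_OTHER] = qx
        M[rows_h, nxt_h] += (1 - inc_h) * (1 - qx)

        # CRC tunnels: cause-specific death first, background on survivors,
        # year-10 survivors are cured
        for sl, q in ((_CS, q_screen), (_CF, q_self)):
            rows = np.arange(sl.start, sl.stop)
            nxt = np.concatenate([rows[1:], [_CURED]])
            M[rows, _DEAD_CRC] = q
            M[rows, _DEAD_OTHER] = (1 - q) * qx
            M[rows, nxt] = (1 - q) * (1 - qx)

        M[_CURED, _DEAD_OTHER] = qx
        M[_CURED, _CURED] = 1 - qx
        M[_DEAD_CRC, _DEAD_CRC] = 1.0
        M[_DEAD_OTHER, _DEAD_OTHER] = 1.0
        return M

    def _utilities(self) -> np.ndarray:
        p = self.params
        u = np.zeros(N_STATES)
        u[_HN] = p.u_health
        u[_PC] = p.u_health
        u[_CS] = p.u_screen
        u[_CF] = p.u_self
        u[_CURED] = p.u_health
        return u

    # -- main loop ----------------------------------------------------------

    def run(self, trace: bool = True) -> CohortResults:
        p = self.params
        hz = self.horizon
        init = apply_strategy(p, self.strategy)
        u = self._utilities()
        r = p.discount
        inc_pc = self._postcolo_incidence()

        occ = init.occupancy.copy()
        cost = init.upfront_cost
        cost += init.diagnosed_screen * p.c_screen_crc
        cost += init.diagnosed_self * p.c_self_crc
        qaly = 0.0
        new_crc = 0.0
        deaths_window = 0.0
        deaths_total = 0.0
        rows = [self._trace_row(0, occ, cost, 0.0)] if trace else []

        t = 0
        for t in range(1, hz.cycles + 1):
            M = self.transition_matrix(t)
            incident = occ[_HN] * p.inc_general + float(occ[_PC] @ inc_pc)
            prev_dead_crc = occ[_DEAD_CRC]
            occ = occ @ M
            if abs(occ.sum() - 1.0) > 1e-9:
                raise RuntimeError(f"mass leak at cycle {t}: {occ.sum()}")

            d = discount_factor(r, t)
            crc_deaths = occ[_DEAD_CRC] - prev_dead_crc
            deaths_total += crc_deaths
            if t <= hz.count_window:
                new_crc += incident
                deaths_window += crc_deaths
            # incident cases are diagnosed via self-referral and pay the
            # composite treatment cost at diagnosis; bg deaths in the incident
            # year are charged too (diagnosis precedes death within the cycle)
            cost += incident * p.c_self_crc * d
            cyc_qaly = float(occ @ u) * d
            qaly += cyc_qaly
            if trace:
                rows.append(self._trace_row(t, occ,
                                            incident * p.c_self_crc * d,
                                            cyc_qaly))
            living = 1.0 - occ[_DEAD_CRC] - occ[_DEAD_OTHER]
            if hz.stop_tol and living < hz.stop_tol and t >= hz.count_window:
                break

        scale = p.population
        outputs = ModelOutputs(
            per_capita_cost=cost,
            per_capita_qaly=qaly,
            new_crc=new_crc * scale,
            cum_crc_deaths=deaths_window * scale,
            colonoscopies=init.colonoscopies * scale,
            total_crc_deaths=deaths_total * scale,
            cycles_run=t,
        )
        return CohortResults(self, outputs, pd.DataFrame(rows))

    fit = run  # modelling-object alias

    def _trace_row(self, t: int, occ: np.ndarray, cost: float,
                   qaly: float) -> dict:
        return {
            "cycle": t,
            "healthy_naive": occ[_HN],
            "healthy_postcolo": occ[_PC].sum(),
            "crc_screen": occ[_CS].sum(),
            "crc_self": occ[_CF].sum(),
            "cured": occ[_CURED],
            "dead_crc": occ[_DEAD_CRC],
            "dead_other": occ[_DEAD_OTHER],
            "cycle_cost": cost,
            "cycle_qaly": qaly,
        }


def build_transitions(params: ParameterSet, state: str,
                      cycle: int = 1) -> dict[str, float]:
    """Successor-state probability map for one named state and cycle.

    State names follow ``STATE_LABELS`` (tunnel states carry their year
    index, e.g. ``crc_self_3``).
    """
    if state not in STATE_LABELS:
        raise ValidationError(f"unknown state {state!r}")
    model = MarkovCohortModel(params, StrategySpec("none"))
    row = model.transition_matrix(cycle)[STATE_LABELS.index(state)]
    return {lab: float(p) for lab, p in zip(STATE_LABELS, row) if p > 0}


def run_cohort(params: ParameterSet, strategy: StrategySpec,
               horizon: str | HorizonSpec = "lifetime") -> ModelOutputs:
    """Functional wrapper: build the model, run it, return the outputs."""
    return MarkovCohortModel(params, strategy, horizon).run(trace=False).outputs
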