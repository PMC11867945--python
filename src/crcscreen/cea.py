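"""Strategy comparison: incremental cost-effectiveness, deaths averted, and
the colonoscopy-acceptance threshold search."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .markov import (HorizonSpec, MarkovCohortModel, ModelOutputs,
                     StrategySpec, run_cohort)
from .parameters import ParameterSet, ValidationError

__all__ = [
    "Comparison",
    "ThresholdResult",
    "icer",
    "deaths_averted",
    "find_threshold_acceptance",
    "results_table",
    "PAPER_SCENARIOS",
]


@dataclass(frozen=True)
class Comparison:
    """Pairwise incremental comparison (alternative vs reference)."""

    reference: str
    alternative: str
    delta_cost: float
    delta_eff: float
    icer: float          # NaN when delta_eff == 0
    dominance: str       # none | dominant | dominated


def icer(reference: ModelOutputs, alternative: ModelOutputs,
         ref_name: str = "reference", alt_name: str = "alternative") -> Comparison:
    """ICER of ``alternative`` versus ``reference`` on unrounded per-capita
    values.  ``dominant``: cheaper and more effective; ``dominated``: costlier
    and less effective; zero effectiveness difference leaves the ratio NaN."""
    d_cost = alternative.per_capita_cost - reference.per_capita_cost
    d_eff = alternative.per_capita_qaly - reference.per_capita_qaly
    ratio = d_cost / d_eff if d_eff != 0 else float("nan")
    if d_cost < 0 and d_eff > 0:
        dom = "dominant"
    elif d_cost > 0 and d_eff < 0:
        dom = "dominated"
    else:
        dom = "none"
    return Comparison(ref_name, alt_name, d_cost, d_eff, ratio, dom)


def deaths_averted(reference: ModelOutputs,
                   alternative: ModelOutputs) -> tuple[float, float]:
    """CRC deaths averted by the alternative: (count, fraction of reference
    deaths).  The fraction is NaN when the reference has no CRC deaths."""
    count = reference.cum_crc_deaths - alternative.cum_crc_deaths
    frac = (count / reference.cum_crc_deaths
            if reference.cum_crc_deaths > 0 else float("nan"))
    return count, frac


@dataclass(frozen=True)
class ThresholdResult:
    acceptance: float
    achieved_deaths: float
    iterations: int
    tolerance_met: bool


def find_threshold_acceptance(
    params: ParameterSet,
    target_deaths: float,
    strategy_name: str = "colonoscopy",
    horizon: str | HorizonSpec = "lifetime",
    tol: float = 0.5,
    max_iter: int = 40,
) -> ThresholdResult:
    """Bisection on colonoscopy acceptance until cumulative CRC deaths match
    ``target_deaths`` within ``tol`` deaths.

    CRC deaths decrease monotonically in acceptance, so the root is unique;
    the target must lie between the deaths at acceptance 1 and acceptance 0.
    """

    def deaths(a: float) -> float:
        out = run_cohort(params, StrategySpec(strategy_name, a), horizon)
        return out.cum_crc_deaths

    d_lo, d_hi = deaths(1.0), deaths(0.0)
    if not (d_lo - tol <= target_deaths <= d_hi + tol):
        raise ValidationError(
            f"target {target_deaths:.1f} outside achievable bracket "
            f"[{d_lo:.1f}, {d_hi:.1f}]"
        )
    lo, hi = 0.0, 1.0  # deaths(lo) >= target >= deaths(hi)
    a, d = 0.5, float("nan")
    for it in range(1, max_iter + 1):
        a = 0.5 * (lo + hi)
        d = deaths(a)
        if abs(d - target_deaths) <= tol:
            return ThresholdResult(a, d, it, True)
        if d > target_deaths:
            lo = a
        else:
            hi = a
    return ThresholdResult(a, d, max_iter, False)


#: Table 3-style scenario set: (label, strategy, acceptance)
PAPER_SCENARIOS = [
    ("general", "none", 0.0),
    ("colonoscopy_100", "colonoscopy", 1.0),
    ("colonoscopy_37.2", "colonoscopy", 0.372),
    ("colonoscopy_20.3", "colonoscopy", 0.203),
    ("colonoscopy_8.6", "colonoscopy", 0.086),
    ("sequential_situation1", "sequential", 0.422),
    ("sequential_situation2", "sequential", 1.0),
]


def results_table(params: ParameterSet,
                  scenarios=PAPER_SCENARIOS,
                  horizon: str | HorizonSpec = "lifetime") -> pd.DataFrame:
    """Run every scenario and tabulate the Table 3-style rows: New CRC,
    cumulative CRC deaths, cumulative effectiveness and cost per capita, and
    incrementals/ICER versus the no-screening scenario."""
    outs: dict[str, ModelOutputs] = {}
    for label, name, acc in scenarios:
        outs[label] = run_cohort(params, StrategySpec(name, acc), horizon)
    ref_label = scenarios[0][0]
    ref = outs[ref_label]
    cols = {}
    for label, out in outs.items():
        comp = icer(ref, out, ref_label, label)
        cols[label] = {
            "new_crc": out.new_crc,
            "cum_crc_deaths": out.cum_crc_deaths,
            "cum_eff": out.per_capita_qaly,
            "cum_cost": out.per_capita_cost,
            "in_eff": comp.delta_eff if label != ref_label else float("nan"),
            "in_cost": comp.delta_cost if label != ref_label else float("nan"),
            "icer": comp.icer if label != ref_label else float("nan"),
        }
    return pd.DataFrame(cols)
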