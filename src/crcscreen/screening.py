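"""Risk questionnaire scoring and the synthetic screening-cohort generator.

The generator emulates individual-level records of a two-step (FIT + risk
questionnaire) screening programme: each synthetic participant carries a
questionnaire score, two FIT results, a colonoscopy acceptance decision
depending on their screening results, and a colonoscopy finding.  Default
targets reproduce the programme's published marginal rates: 20.3% high-risk,
cell-wise colonoscopy acceptance (26.3/41.3/65.7% for high-score participants
with 0/1/2 FIT positives; 46.8/62.3% for low-score participants with 1/2),
2.7% CRC yield among colonoscoped high-risk participants, and a 65.5/34.5/0
stage mix for screen-detected cancers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import StageMix, ValidationError

__all__ = [
    "RiskProfile",
    "ScreeningRecord",
    "CohortConfig",
    "risk_score",
    "classify_risk",
    "generate_screening_cohort",
    "estimate_rates",
    "compare_stage_proportions",
    "write_records",
    "read_records",
]

HIGH_RISK_SCORE = 5

RECORD_COLUMNS = [
    "id", "score", "risk_class", "fit_positives",
    "colonoscopy_accepted", "finding", "detection_mode",
]


@dataclass(frozen=True)
class RiskProfile:
    """Answers to the seven-item risk questionnaire."""

    polyposis_history: bool
    fap: bool
    age: int
    sex: str  # "female" | "male"
    family_history_crc: bool
    smoker: bool
    bmi: float


def risk_score(profile: RiskProfile) -> int:
    """Questionnaire points: polyposis 5, FAP 5, age 50-54/55-64/65-74 ->
    0/1/2, male +1, family history +1, smoking +1, BMI >= 23 +1."""
    if not (50 <= profile.age <= 75):
        raise ValidationError(f"age {profile.age} outside the 50-75 target span")
    if profile.bmi <= 0:
        raise ValidationError("bmi must be positive")
    pts = 0
    pts += 5 if profile.polyposis_history else 0
    pts += 5 if profile.fap else 0
    if profile.age >= 65:
        pts += 2
    elif profile.age >= 55:
        pts += 1
    pts += 1 if profile.sex == "male" else 0
    pts += 1 if profile.family_history_crc else 0
    pts += 1 if profile.smoker else 0
    pts += 1 if profile.bmi >= 23 else 0
    return pts


def classify_risk(score: int, fit_positives: int) -> str:
    """High risk iff questionnaire score >= 5 or any FIT positive."""
    if score < 0 or fit_positives not in (0, 1, 2):
        raise ValidationError("score must be >= 0 and fit_positives in {0,1,2}")
    return "high" if score >= HIGH_RISK_SCORE or fit_positives >= 1 else "low"


# defaults below reproduce the published cell counts out of 175,550 screened:
# high-score cells (score >= 5) with 0/1/2 FIT positives: 11449/2859/662
# low-score cells with 1/2 FIT positives: 15665/4920; remainder low/0.
_N_PUBLISHED = 175550
_CELL_COUNTS = {
    ("high", 0): 11449, ("high", 1): 2859, ("high", 2): 662,
    ("low", 1): 15665, ("low", 2): 4920,
}
_DEFAULT_ACCEPTANCE = {
    ("high", 0): 0.263, ("high", 1): 0.413, ("high", 2): 0.657,
    ("low", 0): 0.0, ("low", 1): 0.468, ("low", 2): 0.623,
}


def _default_cell_probs() -> dict[tuple[str, int], float]:
    probs = {k: v / _N_PUBLISHED for k, v in _CELL_COUNTS.items()}
    probs[("low", 0)] = 1.0 - sum(probs.values())
    return probs


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort targets.

    ``cell_probs`` gives the joint distribution of (questionnaire class, FIT
    positive count); ``acceptance_grid`` the per-cell colonoscopy acceptance.
    High risk is the union of score >= 5 and >= 1 FIT positive.
    """

    n: int = _N_PUBLISHED
    seed: int = 0
    cell_probs: dict = field(default_factory=_default_cell_probs)
    acceptance_grid: dict = field(default_factory=lambda: dict(_DEFAULT_ACCEPTANCE))
    crc_yield: float = 0.027
    stage_mix_screen: StageMix = field(
        default_factory=lambda: StageMix(0.655, 0.345, 0.0)
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        total = sum(self.cell_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"cell probabilities sum to {total}, not 1")
        for grid in (self.cell_probs, self.acceptance_grid):
            for v in grid.values():
                if not (0 <= v <= 1):
                    raise ValidationError("probabilities must be in [0, 1]")
        if not (0 <= self.crc_yield <= 1):
            raise ValidationError("crc_yield must be in [0, 1]")


@dataclass(frozen=True)
class ScreeningRecord:
    id: int
    score: int
    risk_class: str
    fit_positives: int
    colonoscopy_accepted: bool
    finding: str  # none | crc_early | crc_adv_nomet | crc_adv_met
    detection_mode: str  # screen | self | undetected


_SCORE_BY_CLASS = {"high": 6, "low": 2}  # representative questionnaire scores
_FINDINGS = np.array(["crc_early", "crc_adv_nomet", "crc_adv_met"])


def generate_screening_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort as a DataFrame of screening records.

    CRC prevalence among high-risk participants equals ``crc_yield`` whether
    or not colonoscopy is accepted (prevalence among decliners is assumed
    equal to acceptors); decliners' cancers are tagged ``undetected``.
    """
    rng = np.random.default_rng(config.seed)
    cells = list(config.cell_probs)
    probs = np.array([config.cell_probs[c] for c in cells])
    cell_idx = rng.choice(len(cells), size=config.n, p=probs)

    qclass = np.array([c[0] for c in cells])[cell_idx]
    fitpos = np.array([c[1] for c in cells])[cell_idx]
    score = np.where(qclass == "high", _SCORE_BY_CLASS["high"],
                     _SCORE_BY_CLASS["low"])
    risk = np.where((score >= HIGH_RISK_SCORE) | (fitpos >= 1), "high", "low")

    acc_p = np.array([config.acceptance_grid.get(c, 0.0) for c in cells])[cell_idx]
    accepted = rng.random(config.n) < acc_p

    high = risk == "high"
    has_crc = np.zeros(config.n, bool)
    has_crc[high] = rng.random(high.sum()) < config.crc_yield

    stage_p = np.array(config.stage_mix_screen.as_tuple())
    finding = np.full(config.n, "none", dtype=object)
    n_crc = int(has_crc.sum())
    if n_crc:
        finding[has_crc] = _FINDINGS[rng.choice(3, size=n_crc, p=stage_p)]

    detection = np.full(config.n, "undetected", dtype=object)
    detection[~has_crc] = "undetected"
    detection[has_crc & accepted] = "screen"
    # cancers in decliners remain present but undetected at screening
    detection[has_crc & ~accepted] = "undetected"

    df = pd.DataFrame({
        "id": np.arange(config.n),
        "score": score,
        "risk_class": risk,
        "fit_positives": fitpos,
        "colonoscopy_accepted": accepted,
        "finding": np.where(has_crc, finding, "none"),
        "detection_mode": detection,
    })
    return df


def _wilson(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def estimate_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Observed marginal rates with Wilson 95% intervals.

    Returns one row per quantity: high-risk fraction, per-cell colonoscopy
    acceptance, CRC yield among colonoscoped high-risk participants, and the
    screen-detected stage mix.  Empty cells yield NaN rates, never zero.
    """
    if len(records) == 0:
        raise ValidationError("no records")
    rows = []

    def add(name, k, n):
        rate = k / n if n else float("nan")
        lo, hi = _wilson(k, n)
        rows.append({"quantity": name, "events": k, "total": n,
                     "rate": rate, "ci_low": lo, "ci_high": hi})

    high = records["risk_class"] == "high"
    add("high_risk_fraction", int(high.sum()), len(records))

    qhigh = records["score"] >= HIGH_RISK_SCORE
    for qcls, mask in (("high", qhigh), ("low", ~qhigh)):
        for fp in (0, 1, 2):
            cell = mask & (records["fit_positives"] == fp)
            if qcls == "low" and fp == 0:
                continue  # not referred; acceptance undefined
            add(f"acceptance_q{qcls}_fit{fp}",
                int(records.loc[cell, "colonoscopy_accepted"].sum()),
                int(cell.sum()))

    colo = high & records["colonoscopy_accepted"]
    add("overall_acceptance_high_risk", int(colo.sum()), int(high.sum()))
    crc = colo & (records["detection_mode"] == "screen")
    add("crc_yield", int(crc.sum()), int(colo.sum()))

    n_crc = int(crc.sum())
    for stage in ("crc_early", "crc_adv_nomet", "crc_adv_met"):
        add(f"stage_{stage}", int((records.loc[crc, "finding"] == stage).sum()),
            n_crc)
    return pd.DataFrame(rows)


def compare_stage_proportions(
    a_early: int, a_total: int, b_early: int, b_total: int
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) comparing two binomial
    proportions; returns (statistic, two-sided p-value)."""
    from scipy import stats

    if a_total <= 0 or b_total <= 0:
        raise ValidationError("totals must be positive")
    if a_early > a_total or b_early > b_total:
        raise ValidationError("event counts exceed totals")
    table = np.array([[a_early, a_total - a_early],
                      [b_early, b_total - b_early]], float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return (0.0, 1.0)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return (float(chi2), float(p))


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, columns=RECORD_COLUMNS)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
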