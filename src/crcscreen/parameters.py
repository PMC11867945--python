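"""Model parameters: loading, validation, distribution fitting and the
stage-weighted composite derivations.

The parameter set mirrors the published inputs of the Huzhou colorectal-cancer
screening evaluation: status distribution at baseline, per-stage utilities and
costs, cure rates, post-colonoscopy incidence, and economic constants.  Ranges
are interpreted as 95% intervals, so method-of-moments Beta/Gamma fits use
``sd = (high - low) / 3.92``.

Composite detection-mode parameters (``c_screen_crc``, ``u_screen``,
``cure_screen``, ...) are stored twice: the printed point values (used by the
model) and a derivation path from per-stage components (used for cross-checks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParamSpec",
    "StageMix",
    "ParameterSet",
    "LifeTable",
    "load_parameters",
    "default_parameters",
    "total_stage_cost",
    "weight_by_stage",
    "mixture_prevalence",
    "fit_beta",
    "fit_gamma",
    "annualize_cumulative_mortality",
    "load_life_table",
    "default_life_table",
]

#: ranges are read as central 95% intervals: high - low = 2 * 1.96 sd
_RANGE_TO_SD = 1.96 * 2


class ValidationError(ValueError):
    """A parameter or invariant check failed."""


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain scalar parameter: point value, 95% range and family."""

    name: str
    value: float
    low: float | None = None
    high: float | None = None
    family: str = "fixed"  # beta | gamma | fixed

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValidationError(f"{self.name}: unknown family {self.family!r}")
        if self.family != "fixed":
            if self.low is None or self.high is None:
                raise ValidationError(f"{self.name}: {self.family} requires a range")
            if not (self.low <= self.value <= self.high):
                raise ValidationError(
                    f"{self.name}: range [{self.low}, {self.high}] must bracket "
                    f"value {self.value}"
                )
            if self.family == "beta" and not (0 <= self.low and self.high <= 1):
                raise ValidationError(f"{self.name}: beta range outside [0, 1]")
            if self.family == "gamma" and self.low <= 0:
                raise ValidationError(f"{self.name}: gamma range must be positive")

    def fitted(self):
        """Frozen scipy distribution for PSA sampling (None when fixed)."""
        if self.family == "beta":
            return fit_beta(self.value, self.low, self.high)
        if self.family == "gamma":
            return fit_gamma(self.value, self.low, self.high)
        return None


@dataclass(frozen=True)
class StageMix:
    """Stage distribution of detected CRC: early / advanced without
    metastasis / advanced with metastasis."""

    p_early: float
    p_adv_nomet: float
    p_adv_met: float

    def __post_init__(self) -> None:
        probs = (self.p_early, self.p_adv_nomet, self.p_adv_met)
        if any(not (0 <= p <= 1) for p in probs):
            raise ValidationError(f"stage mix proportions outside [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValidationError(f"stage mix must sum to 1, got {sum(probs)}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_early, self.p_adv_nomet, self.p_adv_met)


def total_stage_cost(direct_cost: float, total_days: float, wage: float) -> float:
    """Total per-patient cost for one stage: direct medical cost plus
    productivity losses for the patient and one caregiver.

    ``direct_cost + total_days * 2 * wage`` — two persons lose ``wage`` per
    hospital/treatment day.
    """
    if direct_cost < 0 or total_days < 0 or wage < 0:
        raise ValidationError("total_stage_cost arguments must be non-negative")
    return direct_cost + total_days * 2.0 * wage


def weight_by_stage(
    mix: StageMix, v_early: float, v_adv_nomet: float, v_adv_met: float
) -> float:
    """Collapse per-stage values into a detection-mode composite."""
    return (
        mix.p_early * v_early
        + mix.p_adv_nomet * v_adv_nomet
        + mix.p_adv_met * v_adv_met
    )


def mixture_prevalence(
    p_high: float, prev_high: float, p_low: float, prev_low: float
) -> float:
    """Population CRC prevalence from the risk-stratified mixture."""
    for x in (p_high, prev_high, p_low, prev_low):
        if not (0 <= x <= 1):
            raise ValidationError("mixture_prevalence arguments must be in [0,1]")
    return p_high * prev_high + p_low * prev_low


def fit_beta(mean: float, low: float, high: float):
    """Method-of-moments Beta fit from a point value and 95% range.

    Returns a frozen ``scipy.stats.beta`` whose mean equals ``mean``.  A
    zero-width range returns a degenerate point mass.  Raises when the implied
    variance is infeasible for a Beta distribution.
    """
    from scipy import stats

    if not (0 < mean < 1):
        raise ValidationError(f"beta mean must be in (0,1), got {mean}")
    if high < low:
        raise ValidationError("range bounds reversed")
    sd = (high - low) / _RANGE_TO_SD
    if sd == 0:
        return _point_mass(mean)
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ValidationError(
            f"beta fit infeasible: variance {var:.3g} >= mean(1-mean) "
            f"{mean * (1 - mean):.3g}"
        )
    k = mean * (1 - mean) / var - 1.0
    return stats.beta(mean * k, (1 - mean) * k)


def fit_gamma(mean: float, low: float, high: float):
    """Method-of-moments Gamma fit: shape=(mean/sd)^2, scale=sd^2/mean."""
    from scipy import stats

    if mean <= 0:
        raise ValidationError(f"gamma mean must be positive, got {mean}")
    if high < low:
        raise ValidationError("range bounds reversed")
    sd = (high - low) / _RANGE_TO_SD
    if sd == 0:
        return _point_mass(mean)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return stats.gamma(shape, scale=scale)


class _PointMass:
    """Degenerate distribution marker for zero-width ranges."""

    def __init__(self, value: float):
        self._v = value

    def rvs(self, size=None, random_state=None):
        return self._v if size is None else np.full(size, self._v)

    def mean(self) -> float:
        return self._v

    def std(self) -> float:
        return 0.0


def _point_mass(value: float) -> _PointMass:
    return _PointMass(value)


def annualize_cumulative_mortality(cum_fracs: Sequence[float]) -> np.ndarray:
    """Convert cumulative death fractions at years 1, 3, 5, 10 after diagnosis
    into ten conditional annual death probabilities.

    Within each reporting segment ([0,1], (1,3], (3,5], (5,10]) the conditional
    hazard is constant, so survivor fractions interpolate geometrically and the
    reconstructed cumulative mortality at the four anchors is exact.
    """
    cum = np.asarray(cum_fracs, dtype=float)
    if cum.shape != (4,):
        raise ValidationError("expected cumulative fractions at years 1, 3, 5, 10")
    if np.any(cum < 0) or np.any(cum >= 1):
        raise ValidationError("cumulative fractions must be in [0, 1)")
    if np.any(np.diff(cum) < 0):
        raise ValidationError("cumulative death fractions must be non-decreasing")

    anchors = [0, 1, 3, 5, 10]
    surv = np.concatenate([[1.0], 1.0 - cum])
    annual = np.empty(10)
    for (a, b, s_a, s_b) in zip(anchors[:-1], anchors[1:], surv[:-1], surv[1:]):
        ratio = (s_b / s_a) ** (1.0 / (b - a)) if s_a > 0 else 0.0
        annual[a:b] = 1.0 - ratio
    return annual


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probability by single year of age."""

    age: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        if len(self.age) != len(self.qx):
            raise ValidationError("age and qx must have equal length")
        if np.any(np.diff(self.age) != 1):
            raise ValidationError("ages must be contiguous")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValidationError("qx must be in [0, 1]")

    def lookup(self, age: np.ndarray | int) -> np.ndarray:
        """qx at given age(s), clamped to the supported span."""
        idx = np.clip(np.asarray(age) - self.age[0], 0, len(self.qx) - 1)
        return self.qx[idx]

    def weighted_mortality(self, ages: Sequence[int], weights: Sequence[float]) -> float:
        w = np.asarray(weights, float)
        return float(np.sum(self.lookup(np.asarray(ages)) * w) / w.sum())


def load_life_table(path: str | Path) -> LifeTable:
    df = pd.read_csv(path, comment="#")
    if not {"age", "qx"} <= set(df.columns):
        raise ValidationError("life table CSV needs 'age' and 'qx' columns")
    df = df.sort_values("age")
    return LifeTable(df["age"].to_numpy(int), df["qx"].to_numpy(float))


def default_life_table() -> LifeTable:
    """Bundled synthetic life table (Gompertz hazard calibrated so the
    age-weighted mortality of the 50-75 target population matches the
    published 0.0063)."""
    with resources.as_file(
        resources.files("crcscreen.data") / "synthetic_lifetable.csv"
    ) as p:
        return load_life_table(p)


# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------

_SPEC_KEYS = [
    "p_high", "p_low", "prev_general", "prev_low", "prev_high",
    "u_health", "u_death", "u_early", "u_adv_nomet", "u_adv_met",
    "u_screen", "u_self",
    "c_fit", "c_colo", "c_early", "c_adv_nomet", "c_adv_met",
    "c_hosp_adv", "c_adjuvant", "wage", "c_screen_crc", "c_self_crc",
    "cure_early", "cure_adv_nomet", "cure_adv_met", "cure_screen", "cure_self",
    "inc_general", "inc_postcolo_0_5", "inc_postcolo_5_10",
    "sens_primary", "discount", "mort_bg", "gdp",
]

_LIST_KEYS = {
    "eq5d_stage": 4,
    "surv10_stage": 4,
    "cumdeath_screen": 4,
    "cumdeath_self": 4,
    "mix_screen": 3,
    "mix_self": 3,
}

_SCALAR_KEYS = [
    "n_adjuvant_nomet", "n_adjuvant_met", "days_early", "days_hosp_adv",
    "days_adjuvant", "population", "horizon",
]


@dataclass(frozen=True)
class ParameterSet:
    """Single source of truth for every model quantity.

    ``specs`` holds the uncertain scalars (with ranges and families);
    vector-valued and structural quantities are plain fields.  Attribute
    access on a scalar name returns its point value.
    """

    specs: Mapping[str, ParamSpec]
    eq5d_stage: tuple[float, ...]
    surv10_stage: tuple[float, ...]
    cumdeath_screen: tuple[float, ...]
    cumdeath_self: tuple[float, ...]
    mix_screen: StageMix
    mix_self: StageMix
    n_adjuvant_nomet: int
    n_adjuvant_met: int
    days_early: float
    days_hosp_adv: float
    days_adjuvant: float
    population: int
    horizon: int
    life_table: LifeTable | None = None

    def __getattr__(self, name):
        specs = object.__getattribute__(self, "specs")
        if name in specs:
            return specs[name].value
        raise AttributeError(name)

    # -- derived composites (one tested derivation path) --------------------

    @property
    def total_cost_early(self) -> float:
        return total_stage_cost(self.c_early, self.days_early, self.wage)

    @property
    def total_cost_adv_nomet(self) -> float:
        days = self.days_hosp_adv + self.n_adjuvant_nomet * self.days_adjuvant
        return total_stage_cost(self.c_adv_nomet, days, self.wage)

    @property
    def total_cost_adv_met(self) -> float:
        days = self.days_hosp_adv + self.n_adjuvant_met * self.days_adjuvant
        return total_stage_cost(self.c_adv_met, days, self.wage)

    def composite_cost(self, mode: str) -> float:
        """Stage-weighted total CRC cost recomputed from components."""
        mix = self.mix_screen if mode == "screen" else self.mix_self
        return weight_by_stage(
            mix,
            self.total_cost_early,
            self.total_cost_adv_nomet,
            self.total_cost_adv_met,
        )

    def composite_cure(self, mode: str) -> float:
        """Stage-weighted 10-year cure rate; advanced-without-metastasis uses
        the mean of stage II and III survival, metastatic uses stage IV."""
        s1, s2, s3, s4 = self.surv10_stage
        mix = self.mix_screen if mode == "screen" else self.mix_self
        return weight_by_stage(mix, s1, (s2 + s3) / 2.0, s4)

    def composite_utility(self, mode: str) -> float:
        e1, e2, e3, e4 = self.eq5d_stage
        mix = self.mix_screen if mode == "screen" else self.mix_self
        return weight_by_stage(mix, e1, (e2 + e3) / 2.0, e4)

    def annual_crc_death(self, mode: str) -> np.ndarray:
        cum = self.cumdeath_screen if mode == "screen" else self.cumdeath_self
        return annualize_cumulative_mortality(cum)

    def with_values(self, **overrides: float) -> "ParameterSet":
        """Copy with scalar point values replaced (ranges untouched)."""
        specs = dict(self.specs)
        other = {}
        for k, v in overrides.items():
            if k in specs:
                s = specs[k]
                lo = min(s.low, v) if s.low is not None else None
                hi = max(s.high, v) if s.high is not None else None
                specs[k] = ParamSpec(k, float(v), lo, hi, s.family)
            elif k in _LIST_KEYS or k in _SCALAR_KEYS or k == "life_table":
                other[k] = v
            else:
                raise ValidationError(f"unknown parameter {k!r}")
        out = replace(self, specs=specs, **other)
        return out

    def validate(self) -> None:
        for name in ("p_high", "p_low", "prev_general", "prev_low", "prev_high",
                     "sens_primary", "mort_bg", "inc_general",
                     "inc_postcolo_0_5", "inc_postcolo_5_10", "discount"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in ("c_fit", "c_colo", "c_early", "c_adv_nomet", "c_adv_met",
                     "wage", "c_screen_crc", "c_self_crc", "gdp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for seq_name in ("cumdeath_screen", "cumdeath_self"):
            seq = getattr(self, seq_name)
            if any(b < a for a, b in zip(seq, seq[1:])):
                raise ValidationError(f"{seq_name} must be non-decreasing")
        if self.p_high + self.p_low > 1.001:
            raise ValidationError("p_high + p_low exceeds 1 beyond rounding")
        mix_prev = mixture_prevalence(
            self.p_high, self.prev_high, self.p_low, self.prev_low
        )
        if abs(mix_prev - self.prev_general) > 5e-4:
            raise ValidationError(
                f"risk-mixture prevalence {mix_prev:.4g} inconsistent with "
                f"prev_general {self.prev_general}"
            )
        if self.life_table is not None:
            ages = np.arange(50, 76)
            w = np.ones_like(ages, float)
            m = self.life_table.weighted_mortality(ages, w)
            if abs(m - self.mort_bg) > 0.1 * self.mort_bg:
                raise ValidationError(
                    f"life-table age-weighted mortality {m:.4g} deviates >10% "
                    f"from mort_bg {self.mort_bg}"
                )


def _parse_entry(name: str, raw) -> ParamSpec:
    if isinstance(raw, Mapping):
        return ParamSpec(
            name,
            float(raw["value"]),
            float(raw["low"]) if "low" in raw else None,
            float(raw["high"]) if "high" in raw else None,
            raw.get("family", "fixed"),
        )
    return ParamSpec(name, float(raw))


def _build(cfg: Mapping) -> ParameterSet:
    missing = [k for k in _SPEC_KEYS if k not in cfg]
    if missing:
        raise ValidationError(f"missing required parameter(s): {', '.join(missing)}")
    specs = {k: _parse_entry(k, cfg[k]) for k in _SPEC_KEYS}
    lists = {}
    for k, n in _LIST_KEYS.items():
        if k not in cfg:
            raise ValidationError(f"missing required parameter(s): {k}")
        seq = tuple(float(x) for x in cfg[k])
        if len(seq) != n:
            raise ValidationError(f"{k} must have {n} entries")
        lists[k] = seq
    scalars = {}
    for k in _SCALAR_KEYS:
        if k not in cfg:
            raise ValidationError(f"missing required parameter(s): {k}")
        scalars[k] = cfg[k]
    ps = ParameterSet(
        specs=specs,
        eq5d_stage=lists["eq5d_stage"],
        surv10_stage=lists["surv10_stage"],
        cumdeath_screen=lists["cumdeath_screen"],
        cumdeath_self=lists["cumdeath_self"],
        mix_screen=StageMix(*lists["mix_screen"]),
        mix_self=StageMix(*lists["mix_self"]),
        n_adjuvant_nomet=int(scalars["n_adjuvant_nomet"]),
        n_adjuvant_met=int(scalars["n_adjuvant_met"]),
        days_early=float(scalars["days_early"]),
        days_hosp_adv=float(scalars["days_hosp_adv"]),
        days_adjuvant=float(scalars["days_adjuvant"]),
        population=int(scalars["population"]),
        horizon=int(scalars["horizon"]),
    )
    ps.validate()
    return ps


def _default_config() -> dict:
    text = (resources.files("crcscreen.data") / "defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_parameters(life_table: bool | LifeTable = True) -> ParameterSet:
    """The packaged default parameter set.

    ``life_table=True`` attaches the bundled synthetic life table; ``False``
    leaves background mortality at the flat ``mort_bg``.
    """
    ps = _build(_default_config())
    if life_table is True:
        ps = replace(ps, life_table=default_life_table())
    elif isinstance(life_table, LifeTable):
        ps = replace(ps, life_table=life_table)
    ps.validate()
    return ps


def load_parameters(source: str | Path | Mapping) -> ParameterSet:
    """Load a parameter set from a YAML document (path or mapping).

    ``use_paper_defaults: true`` starts from the packaged defaults; any other
    keys override individual entries.  Without that flag, every field is
    required.
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        cfg = yaml.safe_load(Path(source).read_text()) or {}
    use_defaults = bool(cfg.pop("use_paper_defaults", False))
    life_table_path = cfg.pop("life_table", None)
    if use_defaults:
        base = _default_config()
        base.update(cfg)
        cfg = base
    ps = _build(cfg)
    if life_table_path:
        ps = replace(ps, life_table=load_life_table(life_table_path))
    ps.validate()
    return ps
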