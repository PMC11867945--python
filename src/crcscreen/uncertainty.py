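"""Sensitivity analysis: one-way (tornado) over parameter ranges,
probabilistic sensitivity analysis with Beta/Gamma draws, net monetary
benefit, cost-effectiveness scatter and acceptability curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import icer
from .markov import HorizonSpec, StrategySpec, run_cohort
from .parameters import ParameterSet, ValidationError

__all__ = [
    "net_monetary_benefit",
    "one_way",
    "run_psa",
    "ceac",
    "psa_scatter",
    "default_wtp_grid",
    "DEFAULT_TORNADO_PARAMS",
    "plot_tornado",
    "plot_ceac",
    "plot_scatter",
]

#: parameters varied by default in one-way analysis: every spec with a range
DEFAULT_TORNADO_PARAMS = [
    "p_high", "prev_general", "prev_low", "prev_high",
    "u_early", "u_adv_nomet", "u_adv_met", "u_screen", "u_self",
    "c_fit", "c_colo", "c_screen_crc", "c_self_crc", "wage",
    "inc_general", "inc_postcolo_0_5", "inc_postcolo_5_10",
    "sens_primary", "discount", "mort_bg",
]


def net_monetary_benefit(cost: float, eff: float, wtp: float) -> float:
    """``wtp * eff - cost`` (USD per capita)."""
    if wtp < 0:
        raise ValidationError("willingness to pay must be non-negative")
    return wtp * eff - cost


def one_way(
    params: ParameterSet,
    comparison: tuple[StrategySpec, StrategySpec],
    parameters_to_vary: list[str] | None = None,
    horizon: str | HorizonSpec = "lifetime",
    top: int | None = 5,
) -> pd.DataFrame:
    """Tornado analysis: re-run a strategy pair with each parameter at its
    range bounds (all others at point values) and record the pairwise ICER.

    Returns entries sorted by spread (|high-bound ICER - low-bound ICER|)
    descending; ``top`` limits the table (None keeps all).
    """
    ref_s, alt_s = comparison
    names = parameters_to_vary or [
        n for n in DEFAULT_TORNADO_PARAMS if params.specs[n].family != "fixed"
    ]

    def metric(ps: ParameterSet) -> float:
        ref = run_cohort(ps, ref_s, horizon)
        alt = run_cohort(ps, alt_s, horizon)
        return icer(ref, alt).icer

    rows = []
    for name in names:
        spec = params.specs[name]
        if spec.family == "fixed" or spec.low is None:
            lo_v = hi_v = metric(params)
        else:
            lo_v = metric(params.with_values(**{name: spec.low}))
            hi_v = metric(params.with_values(**{name: spec.high}))
        rows.append({
            "parameter": name,
            "value_low_result": lo_v,
            "value_high_result": hi_v,
            "spread": abs(hi_v - lo_v),
        })
    df = pd.DataFrame(rows).sort_values(
        "spread", ascending=False, ignore_index=True
    )
    return df.head(top) if top else df


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

#: strategy set used in the published acceptability analysis
PSA_STRATEGIES = {
    "none": StrategySpec("none"),
    "sequential": StrategySpec("sequential", 1.0),
    "colonoscopy": StrategySpec("colonoscopy", 1.0),
}


def _fitted_distributions(params: ParameterSet) -> dict:
    return {name: spec.fitted() for name, spec in params.specs.items()
            if spec.family != "fixed"}


def sample_parameters(params: ParameterSet, rng: np.random.Generator,
                      dists: dict | None = None) -> ParameterSet:
    """One PSA realisation: every Beta/Gamma parameter redrawn from its
    fitted distribution; fixed parameters held at their point values."""
    dists = dists if dists is not None else _fitted_distributions(params)
    draws = {name: float(d.rvs(random_state=rng)) for name, d in dists.items()}
    return params.with_values(**draws)


def run_psa(
    params: ParameterSet,
    n_draws: int,
    seed: int,
    strategies: dict[str, StrategySpec] | None = None,
    horizon: str | HorizonSpec = "lifetime",
) -> pd.DataFrame:
    """Monte-Carlo re-running of the model under parameter uncertainty.

    Returns a long DataFrame with one row per (draw, strategy) carrying the
    per-capita discounted cost and QALYs plus the sampled values of a few
    headline parameters.  Identical seeds give identical draws.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    strategies = strategies or PSA_STRATEGIES
    rng = np.random.default_rng(seed)
    dists = _fitted_distributions(params)
    rows = []
    for i in range(n_draws):
        ps = sample_parameters(params, rng, dists)
        for label, strat in strategies.items():
            out = run_cohort(ps, strat, horizon)
            rows.append({
                "draw": i,
                "strategy": label,
                "cost": out.per_capita_cost,
                "qaly": out.per_capita_qaly,
                "cum_crc_deaths": out.cum_crc_deaths,
                "c_colo": ps.c_colo,
                "sens_primary": ps.sens_primary,
            })
    return pd.DataFrame(rows)


def default_wtp_grid(gdp: float) -> np.ndarray:
    """0 to 3x per-capita GDP in steps of GDP/20."""
    return np.arange(0.0, 3.0 * gdp + 1e-9, gdp / 20.0)


def ceac(draws: pd.DataFrame, wtp_grid=None,
         gdp: float = 17324.0) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    At each willingness-to-pay the probability a strategy is best is the
    fraction of draws in which it attains the strictly highest net monetary
    benefit; exact ties split their weight equally.
    """
    if len(draws) == 0:
        raise ValidationError("no PSA draws")
    grid = default_wtp_grid(gdp) if wtp_grid is None else np.asarray(wtp_grid)
    wide_c = draws.pivot(index="draw", columns="strategy", values="cost")
    wide_e = draws.pivot(index="draw", columns="strategy", values="qaly")
    labels = list(wide_c.columns)
    C = wide_c.to_numpy()
    E = wide_e.to_numpy()
    rows = []
    for w in grid:
        nmb = w * E - C
        best = nmb.max(axis=1, keepdims=True)
        is_best = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        row = {"wtp": float(w)}
        row.update({lab: float(p) for lab, p in zip(labels, probs)})
        rows.append(row)
    return pd.DataFrame(rows)


def psa_scatter(draws: pd.DataFrame, reference: str = "none") -> pd.DataFrame:
    """Per-draw incremental (delta_eff, delta_cost) of each strategy versus
    the reference, for the cost-effectiveness plane."""
    wide_c = draws.pivot(index="draw", columns="strategy", values="cost")
    wide_e = draws.pivot(index="draw", columns="strategy", values="qaly")
    rows = []
    for lab in wide_c.columns:
        if lab == reference:
            continue
        rows.append(pd.DataFrame({
            "strategy": lab,
            "delta_eff": wide_e[lab] - wide_e[reference],
            "delta_cost": wide_c[lab] - wide_c[reference],
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_tornado(entries: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = entries.iloc[::-1]
    base = df[["value_low_result", "value_high_result"]].mean(axis=1).mean()
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(df) + 1.5))
    y = np.arange(len(df))
    left = df[["value_low_result", "value_high_result"]].min(axis=1)
    width = df["spread"]
    ax.barh(y, width, left=left, color="#4878a8")
    ax.set_yticks(y, df["parameter"])
    ax.axvline(base, color="k", lw=0.8, ls="--")
    ax.set_xlabel("ICER (USD/QALY)")
    ax.set_title("One-way sensitivity (tornado)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curves: pd.DataFrame, path, gdp: float = 17324.0) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col in curves.columns:
        if col == "wtp":
            continue
        ax.plot(curves["wtp"], curves[col], label=col)
    for k in (1, 2, 3):
        ax.axvline(k * gdp, color="grey", lw=0.6, ls=":")
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("P(strategy is cost-effective)")
    ax.set_ylim(0, 1)
    ax.legend()
    ax.set_title("Cost-effectiveness acceptability curves")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter(scatter: pd.DataFrame, path, gdp: float = 17324.0) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for lab, grp in scatter.groupby("strategy"):
        ax.scatter(grp["delta_eff"], grp["delta_cost"], s=6, alpha=0.4,
                   label=lab)
    xs = np.linspace(*ax.get_xlim(), 10)
    ax.plot(xs, gdp * xs, color="grey", lw=0.8, ls="--", label="1x GDP")
    ax.axhline(0, color="k", lw=0.6)
    ax.axvline(0, color="k", lw=0.6)
    ax.set_xlabel("Incremental QALYs per capita")
    ax.set_ylabel("Incremental cost per capita (USD)")
    ax.legend()
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
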