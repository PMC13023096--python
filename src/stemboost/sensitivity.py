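"""One-way deterministic sensitivity, probabilistic stress testing, and
key-driver regression on the incremental cost of universal reserve collection.

The one-way (tornado) analysis varies one parameter group at a time over
its stated grid while holding everything else at base case. The
probabilistic stress test draws all six parameters independently and
uniformly over their stress ranges (the least-assumption reading of
"varying parameters within bounds"; ranges name no distribution), runs both
arms per draw, and summarizes the incremental-cost distribution. Sampled
neutropenia (recovery, infection) pairs may sum to less than 1 — the
residual mass remains neutropenic — or to more than 1, in which case the
pair is proportionally renormalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import run_cohort
from .economics import accumulate_costs, incremental_cost
from .model import (
    CostParameters,
    ParameterError,
    StrategyParameters,
    build_transition_matrix,
)

logger = logging.getLogger(__name__)

SPLIT_TOL = 1e-9


@dataclass(frozen=True)
class DsaResult:
    """Incremental cost at the extremes of one parameter's grid."""

    parameter: str
    low: float
    high: float
    incremental_at_low: float
    incremental_at_high: float
    #: whether incremental cost stayed positive at every grid value
    positive_throughout: bool

    @property
    def absolute_range(self) -> float:
        return abs(self.incremental_at_high - self.incremental_at_low)


@dataclass(frozen=True)
class DsaGrid:
    """Grids for the one-way analysis.

    Neutropenia splits are (recovery, infection) pairs that must be
    complementary (sum to 1) because the base-case structure carries no
    residual neutropenia mass. Splits are indexed by their infection
    probability in the tornado.
    """

    noboost_splits: tuple[tuple[float, float], ...] = (
        (0.70, 0.30),
        (0.75, 0.25),
        (0.80, 0.20),
    )
    boost_splits: tuple[tuple[float, float], ...] = (
        (0.85, 0.15),
        (0.90, 0.10),
        (0.95, 0.05),
    )
    hospitalization_costs: tuple[float, ...] = (60_000.0, 64_012.0, 68_000.0)
    reserve_costs: tuple[float, ...] = (16_000.0, 17_918.0, 20_000.0)

    def __post_init__(self) -> None:
        for name in ("noboost_splits", "boost_splits"):
            for rec, inf in getattr(self, name):
                if not (0 <= rec <= 1 and 0 <= inf <= 1):
                    raise ParameterError(f"{name} values must lie in [0, 1]")
                if abs(rec + inf - 1.0) > SPLIT_TOL:
                    raise ParameterError(
                        f"{name} pair (recovery={rec}, infection={inf}) is not "
                        "complementary: recovery + infection must equal 1"
                    )


def _incremental(
    noboost: StrategyParameters,
    boost: StrategyParameters,
    costs: CostParameters,
    n_patients: float,
    n_cycles: int,
    renormalize: bool = False,
) -> tuple[float, float, float]:
    """(incremental cost, infections no-boost, infections boost)."""
    tr_nb = run_cohort(
        build_transition_matrix(noboost, renormalize=renormalize),
        n_patients, n_cycles,
    )
    tr_b = run_cohort(
        build_transition_matrix(boost, renormalize=renormalize),
        n_patients, n_cycles,
    )
    inc = incremental_cost(
        accumulate_costs(tr_b, costs, boost_available=True),
        accumulate_costs(tr_nb, costs, boost_available=False),
    )
    return inc, tr_nb.total_infections, tr_b.total_infections


def run_dsa(
    noboost_params: StrategyParameters,
    boost_params: StrategyParameters,
    costs: CostParameters,
    grid: DsaGrid | None = None,
    n_patients: float = 10_000,
    n_cycles: int = 96,
) -> list[DsaResult]:
    """One-way sensitivity of incremental cost over each parameter grid.

    Returns one result per parameter group, sorted descending by absolute
    incremental-cost range (tornado order); ties break alphabetically by
    parameter name.
    """
    grid = grid or DsaGrid()

    def inc_at(nb=None, b=None, c=None) -> float:
        return _incremental(
            nb or noboost_params, b or boost_params, c or costs,
            n_patients, n_cycles,
        )[0]

    def split_params(base: StrategyParameters, rec: float, inf: float):
        return base.with_updates(
            p_recovery_given_neutropenia=rec, p_infection_given_neutropenia=inf
        )

    results = []

    for name, splits, which in (
        ("noboost_neutropenia_split", grid.noboost_splits, "nb"),
        ("boost_neutropenia_split", grid.boost_splits, "b"),
    ):
        base = noboost_params if which == "nb" else boost_params
        vals = {}
        for rec, inf in splits:
            p = split_params(base, rec, inf)
            vals[inf] = inc_at(nb=p) if which == "nb" else inc_at(b=p)
        lo_inf, hi_inf = min(vals), max(vals)
        results.append(
            DsaResult(
                parameter=name,
                low=lo_inf,
                high=hi_inf,
                incremental_at_low=vals[lo_inf],
                incremental_at_high=vals[hi_inf],
                positive_throughout=all(v > 0 for v in vals.values()),
            )
        )

    for name, values, make in (
        (
            "hospitalization_cost_usd",
            grid.hospitalization_costs,
            lambda v: CostParameters(v, costs.reserve_collection_cost_usd),
        ),
        (
            "reserve_collection_cost_usd",
            grid.reserve_costs,
            lambda v: CostParameters(costs.hospitalization_cost_usd, v),
        ),
    ):
        vals = {v: inc_at(c=make(v)) for v in values}
        lo, hi = min(vals), max(vals)
        results.append(
            DsaResult(
                parameter=name,
                low=lo,
                high=hi,
                incremental_at_low=vals[lo],
                incremental_at_high=vals[hi],
                positive_throughout=all(v > 0 for v in vals.values()),
            )
        )

    results.sort(key=lambda r: (-r.absolute_range, r.parameter))
    return results


def dsa_table(results: list[DsaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "low": r.low,
                "high": r.high,
                "incremental_at_low": r.incremental_at_low,
                "incremental_at_high": r.incremental_at_high,
                "absolute_range": r.absolute_range,
                "positive_throughout": r.positive_throughout,
            }
            for r in results
        ]
    )


@dataclass(frozen=True)
class PsaRanges:
    """Uniform sampling ranges for the probabilistic stress test."""

    noboost_recovery: tuple[float, float] = (0.60, 0.85)
    noboost_infection: tuple[float, float] = (0.15, 0.35)
    boost_recovery: tuple[float, float] = (0.80, 1.00)
    boost_infection: tuple[float, float] = (0.00, 0.20)
    hospitalization_cost: tuple[float, float] = (50_000.0, 70_000.0)
    reserve_cost: tuple[float, float] = (14_000.0, 22_000.0)

    def __post_init__(self) -> None:
        for f in fields(self):
            lo, hi = getattr(self, f.name)
            if lo > hi:
                raise ParameterError(f"degenerate range for {f.name}: {lo} > {hi}")


PSA_PARAMETERS: tuple[str, ...] = tuple(f.name for f in fields(PsaRanges))


@dataclass(frozen=True)
class PsaResult:
    """Draw-level results and decision-robustness summary."""

    draws: pd.DataFrame = field(repr=False)
    seed: int
    n_draws: int

    @property
    def fraction_positive_incremental(self) -> float:
        """Fraction of draws in which boosting is the costlier strategy."""
        return float((self.draws["incremental_cost"] > 0).mean())

    def summary(self) -> dict:
        inc = self.draws["incremental_cost"]
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "fraction_positive_incremental": self.fraction_positive_incremental,
            "incremental_cost_mean": float(inc.mean()),
            "incremental_cost_q025": float(inc.quantile(0.025)),
            "incremental_cost_q975": float(inc.quantile(0.975)),
        }


def run_psa(
    ranges: PsaRanges | None = None,
    n_draws: int = 500,
    seed: int = 0,
    noboost_params: StrategyParameters | None = None,
    boost_params: StrategyParameters | None = None,
    n_patients: float = 10_000,
    n_cycles: int = 96,
) -> PsaResult:
    """Probabilistic stress test: ``n_draws`` independent uniform draws.

    Every draw samples all six parameters, rebuilds both arms (with
    proportional renormalization of over-full neutropenia rows), runs the
    cohort engine, and records infections per arm and incremental cost.
    Reproducible bit-for-bit for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    ranges = ranges or PsaRanges()
    noboost_params = noboost_params or StrategyParameters.no_boost_base_case()
    boost_params = boost_params or StrategyParameters.boost_base_case()

    rng = np.random.default_rng(seed)
    sampled = {
        name: rng.uniform(*getattr(ranges, name), size=n_draws)
        for name in PSA_PARAMETERS
    }

    records = []
    for i in range(n_draws):
        nb = noboost_params.with_updates(
            p_recovery_given_neutropenia=sampled["noboost_recovery"][i],
            p_infection_given_neutropenia=sampled["noboost_infection"][i],
        )
        b = boost_params.with_updates(
            p_recovery_given_neutropenia=sampled["boost_recovery"][i],
            p_infection_given_neutropenia=sampled["boost_infection"][i],
        )
        c = CostParameters(
            hospitalization_cost_usd=sampled["hospitalization_cost"][i],
            reserve_collection_cost_usd=sampled["reserve_cost"][i],
        )
        inc, inf_nb, inf_b = _incremental(
            nb, b, c, n_patients, n_cycles, renormalize=True
        )
        records.append(
            {
                **{name: sampled[name][i] for name in PSA_PARAMETERS},
                "infections_noboost": inf_nb,
                "infections_boost": inf_b,
                "incremental_cost": inc,
                "cost_savings": -inc,  # no-boost minus boost
            }
        )
    return PsaResult(draws=pd.DataFrame(records), seed=seed, n_draws=n_draws)


def key_driver_regression(draws: pd.DataFrame) -> pd.DataFrame:
    """OLS of cost savings (no-boost minus boost) on the sampled parameters.

    Returns a table with the raw and standardized coefficient per
    parameter, ranked by absolute standardized coefficient. Constant
    (zero-variance) parameters are dropped with a logged warning; a design
    with no varying parameter is refused.
    """
    params = [p for p in PSA_PARAMETERS if p in draws.columns]
    if "cost_savings" in draws.columns:
        y = draws["cost_savings"]
    else:
        y = -draws["incremental_cost"]

    kept, dropped = [], []
    for p in params:
        (kept if draws[p].nunique() > 1 else dropped).append(p)
    if dropped:
        logger.warning(
            "dropping constant parameter(s) from key-driver regression: %s",
            ", ".join(dropped),
        )
    if not kept:
        raise ValueError(
            "key-driver regression needs at least one varying parameter; "
            "all sampled parameters are constant"
        )
    if len(draws) < len(kept) + 2:
        raise ValueError(
            f"need at least {len(kept) + 2} draws for {len(kept)} parameters"
        )

    X = sm.add_constant(draws[kept].astype(float))
    fit = sm.OLS(y.astype(float), X).fit()

    y_sd = float(y.std(ddof=0))
    rows = []
    for p in kept:
        coef = float(fit.params[p])
        x_sd = float(draws[p].std(ddof=0))
        rows.append(
            {
                "parameter": p,
                "coefficient": coef,
                "standardized_coefficient": (
                    coef * x_sd / y_sd if y_sd > 0 else float("nan")
                ),
            }
        )
    table = pd.DataFrame(rows)
    table["rank"] = (
        table["standardized_coefficient"].abs().rank(ascending=False).astype(int)
    )
    return table.sort_values("rank").reset_index(drop=True)


def tornado_figure(results: list[DsaResult], path) -> None:
    """Horizontal-bar tornado of incremental-cost swings (widest on top)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base_mid = [
        0.5 * (r.incremental_at_low + r.incremental_at_high) for r in results
    ]
    fig, ax = plt.subplots(figsize=(7, 0.6 * len(results) + 1.5))
    ypos = np.arange(len(results))[::-1]
    for y, r, mid in zip(ypos, results, base_mid):
        lo = min(r.incremental_at_low, r.incremental_at_high)
        hi = max(r.incremental_at_low, r.incremental_at_high)
        ax.barh(y, hi - lo, left=lo, height=0.6, color="#4878b0")
    ax.set_yticks(ypos)
    ax.set_yticklabels([r.parameter for r in results])
    ax.set_xlabel("Incremental cost (boost − no-boost), USD per patient")
    ax.set_title("One-way sensitivity of incremental cost")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def psa_histogram(result: PsaResult, path) -> None:
    """Histogram of cost savings (no-boost minus boost) across PSA draws."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(result.draws["cost_savings"], bins=40, color="#4878b0")
    ax.axvline(0.0, color="k", lw=1)
    ax.set_xlabel("Cost savings (no-boost − boost), USD per patient")
    ax.set_ylabel("Draws")
    ax.set_title(f"Probabilistic stress test ({result.n_draws} draws)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
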