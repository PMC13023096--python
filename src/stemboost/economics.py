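"""Cost accumulation per strategy arm and incremental cost between arms.

Costs are undiscounted 2024/2025 USD: one hospitalization charge per
expected severe-infection episode, plus (in the boost arm only) the
stem-cell reserve collection charge applied universally at cycle 0 —
including to patients who never develop neutropenia.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import CohortTrace
from .model import CostParameters, ParameterError


@dataclass(frozen=True)
class EconomicSummary:
    """Per-patient cost decomposition for one strategy arm (USD)."""

    strategy: str
    n_patients: float
    infection_hospitalization_cost_per_patient: float
    reserve_cost_per_patient: float

    @property
    def total_cost_per_patient(self) -> float:
        return (
            self.infection_hospitalization_cost_per_patient
            + self.reserve_cost_per_patient
        )

    @property
    def total_cohort_cost(self) -> float:
        return self.total_cost_per_patient * self.n_patients


def accumulate_costs(
    trace: CohortTrace, costs: CostParameters, boost_available: bool
) -> EconomicSummary:
    """Accumulate expected per-patient costs for one arm from its trace."""
    if costs.hospitalization_cost_usd < 0 or costs.reserve_collection_cost_usd < 0:
        raise ParameterError("costs must be non-negative")
    infection_component = (
        trace.total_infections * costs.hospitalization_cost_usd / trace.n_patients
    )
    reserve_component = costs.reserve_collection_cost_usd if boost_available else 0.0
    return EconomicSummary(
        strategy="boost" if boost_available else "no_boost",
        n_patients=trace.n_patients,
        infection_hospitalization_cost_per_patient=infection_component,
        reserve_cost_per_patient=reserve_component,
    )


def incremental_cost(boost: EconomicSummary, noboost: EconomicSummary) -> float:
    """Boost minus no-boost total per-patient cost (positive = boosting costlier)."""
    if boost.n_patients != noboost.n_patients:
        raise ValueError("summaries must come from the same cohort size")
    return boost.total_cost_per_patient - noboost.total_cost_per_patient


def break_even_reserve_cost(
    trace_noboost: CohortTrace, trace_boost: CohortTrace, costs: CostParameters
) -> float:
    """Reserve cost at which the incremental cost is exactly zero.

    Equals (infections averted per patient) x hospitalization cost, by
    linearity of both arms' totals in the cost inputs.
    """
    if trace_noboost.n_patients != trace_boost.n_patients:
        raise ValueError("traces must come from the same cohort size")
    averted_per_patient = (
        trace_noboost.total_infections - trace_boost.total_infections
    ) / trace_noboost.n_patients
    return averted_per_patient * costs.hospitalization_cost_usd


def cost_breakdown_table(
    noboost: EconomicSummary, boost: EconomicSummary
) -> pd.DataFrame:
    """Stacked per-patient cost decomposition (rows: strategy)."""
    rows = [
        {
            "strategy": s.strategy,
            "reserve_cost_per_patient": s.reserve_cost_per_patient,
            "infection_cost_per_patient": s.infection_hospitalization_cost_per_patient,
            "total_cost_per_patient": s.total_cost_per_patient,
        }
        for s in (noboost, boost)
    ]
    return pd.DataFrame(rows)
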