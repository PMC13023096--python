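"""State space, parameter containers, and transition-matrix construction.

The model follows patients after CAR T-cell infusion for multiple myeloma
through seven health states:

    CAR_T -> {NEUTROPENIA, RECOVERY}            (first cycle)
    NEUTROPENIA -> {INFECTION, RECOVERY, stay}
    INFECTION -> {DEATH_INFECTION, RECOVERY}    (resolves in one cycle)
    RECOVERY -> {RELAPSE, stay}
    RELAPSE -> {DEATH_RELAPSE, stay}

Death is absorbing and is split by cause (infection vs relapse) so that
event accounting can attribute mortality; the two death states together
represent overall mortality.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from typing import Union

import numpy as np
import pandas as pd


class HealthState(enum.IntEnum):
    """Health states, in the fixed order used for all matrices and traces."""

    CAR_T = 0
    NEUTROPENIA = 1
    INFECTION = 2
    RECOVERY = 3
    RELAPSE = 4
    DEATH_INFECTION = 5
    DEATH_RELAPSE = 6


STATE_ORDER: tuple[HealthState, ...] = tuple(HealthState)
STATE_LABELS: tuple[str, ...] = tuple(s.name for s in STATE_ORDER)
N_STATES: int = len(STATE_ORDER)
DEATH_STATES: tuple[HealthState, HealthState] = (
    HealthState.DEATH_INFECTION,
    HealthState.DEATH_RELAPSE,
)

#: Tolerance on the neutropenia row: infection + recovery may exceed 1 by at
#: most this much before it is treated as an error (or renormalized when the
#: caller opts in, as the probabilistic stress test does).
RENORM_TOL: float = 1e-9

ROW_SUM_TOL: float = 1e-12


class ParameterError(ValueError):
    """A strategy or cost parameter violates its constraints."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class StrategyParameters:
    """Per-cycle transition probabilities for one strategy arm.

    Parameters
    ----------
    p_neutropenia
        Probability of prolonged (>30 day) grade 3-4 neutropenia after CAR T
        infusion; applied in the first cycle.
    p_infection_given_neutropenia
        Per-cycle probability that a neutropenic patient develops a severe
        infection.
    p_recovery_given_neutropenia
        Per-cycle probability that a neutropenic patient recovers.
    p_infection_death
        Case fatality of a severe infection (death within the cycle).
    p_relapse_monthly
        Monthly probability of myeloma relapse from recovery, derived from
        12-month progression-free survival under a constant hazard.
    p_relapse_death_monthly
        Monthly relapse-related mortality while in the relapse state.
    boost_available
        Whether the stem-cell reserve ("boost") is available; selects the
        arm for cost accounting and the default neutropenia split.
    """

    p_neutropenia: float = 0.26
    p_infection_given_neutropenia: float = 0.25
    p_recovery_given_neutropenia: float = 0.75
    p_infection_death: float = 0.125
    p_relapse_monthly: float = 0.023
    p_relapse_death_monthly: float = 0.03
    boost_available: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "boost_available":
                continue
            _check_prob(f.name, getattr(self, f.name))

    @classmethod
    def no_boost_base_case(cls) -> "StrategyParameters":
        """No-reserve arm: 25% infection / 75% recovery among neutropenics."""
        return cls(boost_available=False)

    @classmethod
    def boost_base_case(cls) -> "StrategyParameters":
        """Reserve arm: stem-cell boost shifts the split to 10% / 90%."""
        return cls(
            p_infection_given_neutropenia=0.10,
            p_recovery_given_neutropenia=0.90,
            boost_available=True,
        )

    def neutropenia_row_split(
        self, renormalize: bool = False
    ) -> tuple[float, float, float]:
        """Return (stay, infection, recovery) mass for the NEUTROPENIA row.

        The residual "stay" mass is ``1 - infection - recovery``; it is zero
        in the base case (0.25 + 0.75) but positive under stress-test draws
        such as (0.15, 0.60). If the pair sums to more than 1 the pair is
        rescaled proportionally when ``renormalize`` is set, otherwise a
        :class:`ParameterError` naming the pair is raised.
        """
        p_inf = self.p_infection_given_neutropenia
        p_rec = self.p_recovery_given_neutropenia
        total = p_inf + p_rec
        if total > 1.0 + RENORM_TOL:
            if not renormalize:
                raise ParameterError(
                    "p_infection_given_neutropenia + p_recovery_given_neutropenia "
                    f"= {p_inf} + {p_rec} = {total} exceeds 1; pass "
                    "renormalize=True to rescale the pair proportionally"
                )
            p_inf /= total
            p_rec /= total
        stay = max(0.0, 1.0 - p_inf - p_rec)
        return stay, p_inf, p_rec

    def with_updates(self, **changes) -> "StrategyParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class CostParameters:
    """Costs (2024/2025-inflation-adjusted USD) entering the analysis.

    ``hospitalization_cost_usd`` is charged once per severe-infection
    admission; ``reserve_collection_cost_usd`` is the per-patient cost of
    collecting and storing extra CD34+ stem cells, charged universally in
    the boost arm.
    """

    hospitalization_cost_usd: float = 64_012.0
    reserve_collection_cost_usd: float = 17_918.0

    def __post_init__(self) -> None:
        if self.hospitalization_cost_usd < 0 or self.reserve_collection_cost_usd < 0:
            raise ParameterError("costs must be non-negative")


@dataclass(frozen=True)
class TransitionMatrix:
    """Validated row-stochastic per-cycle transition matrix.

    Rows/columns follow :data:`STATE_ORDER`. The two death rows are unit
    vectors onto themselves (absorbing).
    """

    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_STATES, N_STATES):
            raise ParameterError(f"matrix must be {N_STATES}x{N_STATES}, got {p.shape}")
        if (p < -ROW_SUM_TOL).any() or (p > 1 + ROW_SUM_TOL).any():
            raise ParameterError("matrix entries must lie in [0, 1]")
        row_sums = p.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=ROW_SUM_TOL, rtol=0.0):
            raise ParameterError(f"rows must sum to 1 within {ROW_SUM_TOL}: {row_sums}")
        for d in DEATH_STATES:
            if p[d, d] != 1.0:
                raise ParameterError(f"{d.name} must be absorbing")
        object.__setattr__(self, "probs", p)

    def __getitem__(self, idx) -> Union[np.ndarray, float]:
        return self.probs[idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=STATE_LABELS, columns=STATE_LABELS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="from_state")


def build_transition_matrix(
    params: StrategyParameters, renormalize: bool = False
) -> TransitionMatrix:
    """Construct the per-cycle transition matrix for one strategy arm.

    CAR_T resolves entirely in the first cycle (neutropenia or recovery);
    INFECTION resolves in exactly one cycle (case fatality or recovery);
    the NEUTROPENIA row carries residual "stay" mass when the infection /
    recovery pair does not sum to 1 (see
    :meth:`StrategyParameters.neutropenia_row_split`).
    """
    S = HealthState
    m = np.zeros((N_STATES, N_STATES))

    m[S.CAR_T, S.NEUTROPENIA] = params.p_neutropenia
    m[S.CAR_T, S.RECOVERY] = 1.0 - params.p_neutropenia

    stay, p_inf, p_rec = params.neutropenia_row_split(renormalize=renormalize)
    m[S.NEUTROPENIA, S.NEUTROPENIA] = stay
    m[S.NEUTROPENIA, S.INFECTION] = p_inf
    m[S.NEUTROPENIA, S.RECOVERY] = p_rec

    m[S.INFECTION, S.DEATH_INFECTION] = params.p_infection_death
    m[S.INFECTION, S.RECOVERY] = 1.0 - params.p_infection_death

    m[S.RECOVERY, S.RELAPSE] = params.p_relapse_monthly
    m[S.RECOVERY, S.RECOVERY] = 1.0 - params.p_relapse_monthly

    m[S.RELAPSE, S.DEATH_RELAPSE] = params.p_relapse_death_monthly
    m[S.RELAPSE, S.RELAPSE] = 1.0 - params.p_relapse_death_monthly

    m[S.DEATH_INFECTION, S.DEATH_INFECTION] = 1.0
    m[S.DEATH_RELAPSE, S.DEATH_RELAPSE] = 1.0

    return TransitionMatrix(m)
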