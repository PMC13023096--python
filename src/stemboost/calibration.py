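"""Survival-to-probability conversion and relapse-mortality calibration.

``survival_to_monthly_prob`` converts a survival fraction over a horizon to
a per-cycle transition probability under a constant-hazard assumption
(p = 1 - S**(1/t)); this is how the 12-month progression-free survival of
75.9% from the cilta-cel trial arm becomes the model's 2.3%/month relapse
probability.

``calibrate_relapse_mortality`` searches (by bisection) for the monthly
relapse-death probability at which the cohort model's overall survival at a
given month hits a target. Note: under this model structure, the printed
base-case value of 3%/month does *not* reproduce a 12-month overall
survival of 84% — relapse exposure within the first year is far too short
for ~16% cumulative mortality — so the calibrated root is much larger. The
base case keeps the printed 3%; this utility reports the actual root so the
discrepancy is explicit rather than silently patched.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import overall_survival, run_cohort
from .model import HealthState, StrategyParameters, build_transition_matrix

BISECTION_MAX_ITER = 60


class InfeasibleTargetError(ValueError):
    """The overall-survival target lies outside the achievable bracket."""


def survival_to_monthly_prob(surviving_fraction: float, horizon_months: int) -> float:
    """Per-month event probability implied by ``surviving_fraction`` at ``horizon_months``.

    Round-trips exactly: compounding ``(1 - p) ** horizon_months`` recovers
    the input fraction.
    """
    if horizon_months < 1:
        raise ValueError("horizon_months must be >= 1")
    if surviving_fraction <= 0.0 or surviving_fraction > 1.0:
        raise ValueError(
            "surviving_fraction must lie in (0, 1]; "
            f"got {surviving_fraction!r} (0 implies an infinite hazard)"
        )
    return 1.0 - surviving_fraction ** (1.0 / horizon_months)


@dataclass(frozen=True)
class CalibrationResult:
    """Root of the OS-matching problem and diagnostic context."""

    p_relapse_death_monthly: float
    achieved_os: float
    os_target: float
    at_month: int
    #: OS at the bracket endpoints p=0 (max) and p=1 (min)
    os_at_p0: float
    os_at_p1: float
    iterations: int

    @property
    def matches_printed_base_case(self) -> bool:
        """Whether the root is consistent with the 3%/month base-case value."""
        return abs(self.p_relapse_death_monthly - 0.03) < 0.005


def _os_at(params: StrategyParameters, p: float, at_month: int) -> float:
    m = build_transition_matrix(params.with_updates(p_relapse_death_monthly=p))
    trace = run_cohort(m, n_patients=1.0, n_cycles=at_month,
                       initial_state=HealthState.CAR_T)
    return overall_survival(trace, at_month)


def calibrate_relapse_mortality(
    base_params: StrategyParameters,
    os_target: float,
    at_month: int = 12,
    tolerance: float = 1e-6,
) -> CalibrationResult:
    """Bisect for the relapse-death probability matching ``os_target``.

    Overall survival is strictly decreasing in the relapse-death probability
    (whenever any mass reaches the relapse state), so bisection on [0, 1]
    converges; the tolerance is on the probability scale.
    """
    if not (0.0 < os_target <= 1.0):
        raise ValueError("os_target must lie in (0, 1]")
    os_hi = _os_at(base_params, 0.0, at_month)  # fewest deaths
    os_lo = _os_at(base_params, 1.0, at_month)  # most deaths
    if not (os_lo - tolerance <= os_target <= os_hi + tolerance):
        raise InfeasibleTargetError(
            f"target OS {os_target} at month {at_month} is outside the "
            f"achievable range [{os_lo:.6f}, {os_hi:.6f}] "
            "(OS at relapse-death probability 1 and 0 respectively)"
        )

    lo, hi = 0.0, 1.0
    iterations = 0
    for iterations in range(1, BISECTION_MAX_ITER + 1):
        mid = 0.5 * (lo + hi)
        if _os_at(base_params, mid, at_month) > os_target:
            lo = mid  # OS still too high: need more mortality
        else:
            hi = mid
        if hi - lo <= tolerance:
            break
    root = 0.5 * (lo + hi)
    return CalibrationResult(
        p_relapse_death_monthly=root,
        achieved_os=_os_at(base_params, root, at_month),
        os_target=os_target,
        at_month=at_month,
        os_at_p0=os_hi,
        os_at_p1=os_lo,
        iterations=iterations,
    )
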