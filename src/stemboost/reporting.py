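"""Scenario orchestration and result serialization.

``run_base_case`` drives both strategy arms through the cohort engine
(optionally also the microsimulation) and assembles event counts, cost
summaries, incremental cost, and the overall-survival trajectory.
``full_report`` composes base case, one-way sensitivity, probabilistic
stress testing, key-driver regression, and the survival calibration into a
single machine-readable (JSON) and human-readable (markdown) report with
full parameter/seed provenance. Reports are byte-identical across reruns
of the same configuration.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any, Optional

from .calibration import calibrate_relapse_mortality
from .cohort import averted_events, overall_survival, run_cohort
from .config import ModelConfig
from .economics import (
    accumulate_costs,
    break_even_reserve_cost,
    cost_breakdown_table,
    incremental_cost,
)
from .microsim import simulate_patients
from .model import build_transition_matrix
from .sensitivity import (
    dsa_table,
    key_driver_regression,
    psa_histogram,
    run_dsa,
    run_psa,
    tornado_figure,
)

logger = logging.getLogger(__name__)

try:
    __version__ = version("stemboost")
except PackageNotFoundError:  # pragma: no cover - running from a checkout
    __version__ = "unknown"

#: Documented provenance of each base-case default (data source, not trial
#: patient data): neutropenia/infection/mortality from the CARTITUDE-4 CAR T
#: arm; the boosted neutropenia split from the Mohan et al. stem-cell boost
#: series; costs inflation-adjusted from Schilling et al. (hospitalization)
#: and Ahmed et al. (collection/storage).
PARAMETER_SOURCES = {
    "p_neutropenia": "CARTITUDE-4 grade 3-4 prolonged neutropenia rate",
    "p_infection_given_neutropenia": "derived from CARTITUDE-4 infection rates "
    "(no-boost) / Mohan et al. boost series (boost)",
    "p_recovery_given_neutropenia": "complement of the infection split",
    "p_infection_death": "CARTITUDE-4 infection-related mortality (10-15% range, "
    "12.5% midpoint case fatality)",
    "p_relapse_monthly": "CARTITUDE-4 12-month PFS 75.9% under constant hazard",
    "p_relapse_death_monthly": "stated calibration to CARTITUDE-4 12-month OS 84%",
    "hospitalization_cost_usd": "Schilling et al., 2024-inflation-adjusted",
    "reserve_collection_cost_usd": "Ahmed et al., 2025-inflation-adjusted",
}


def _log_parameters(config: ModelConfig) -> None:
    for arm, params in (("no_boost", config.noboost), ("boost", config.boost)):
        logger.info("effective %s parameters: %s", arm, params)
    logger.info("effective costs: %s", config.costs)
    for name, source in PARAMETER_SOURCES.items():
        logger.info("parameter provenance: %s <- %s", name, source)


def run_base_case(
    config: Optional[ModelConfig] = None, outdir: Optional[Path] = None
) -> dict[str, Any]:
    """Run both arms deterministically and summarize events, costs, and OS."""
    config = config or ModelConfig()
    _log_parameters(config)

    m_nb = build_transition_matrix(config.noboost)
    m_b = build_transition_matrix(config.boost)
    tr_nb = run_cohort(m_nb, config.n_patients, config.n_cycles)
    tr_b = run_cohort(m_b, config.n_patients, config.n_cycles)

    sum_nb = accumulate_costs(tr_nb, config.costs, boost_available=False)
    sum_b = accumulate_costs(tr_b, config.costs, boost_available=True)
    averted = averted_events(tr_nb, tr_b)

    bundle: dict[str, Any] = {
        "n_patients": config.n_patients,
        "n_cycles": config.n_cycles,
        "events": {
            "no_boost": {
                "infections": tr_nb.total_infections,
                "infection_deaths": tr_nb.total_infection_deaths,
                "relapses": tr_nb.total_relapses,
                "relapse_deaths": tr_nb.total_relapse_deaths,
            },
            "boost": {
                "infections": tr_b.total_infections,
                "infection_deaths": tr_b.total_infection_deaths,
                "relapses": tr_b.total_relapses,
                "relapse_deaths": tr_b.total_relapse_deaths,
            },
            "infections_averted": averted.infections_averted,
            "infection_deaths_averted": averted.infection_deaths_averted,
        },
        "costs": {
            "no_boost": {
                "infection_cost_per_patient": round(
                    sum_nb.infection_hospitalization_cost_per_patient, 2
                ),
                "reserve_cost_per_patient": round(sum_nb.reserve_cost_per_patient, 2),
                "total_cost_per_patient": round(sum_nb.total_cost_per_patient, 2),
            },
            "boost": {
                "infection_cost_per_patient": round(
                    sum_b.infection_hospitalization_cost_per_patient, 2
                ),
                "reserve_cost_per_patient": round(sum_b.reserve_cost_per_patient, 2),
                "total_cost_per_patient": round(sum_b.total_cost_per_patient, 2),
            },
            "incremental_cost_per_patient": round(incremental_cost(sum_b, sum_nb), 2),
            "break_even_reserve_cost": round(
                break_even_reserve_cost(tr_nb, tr_b, config.costs), 2
            ),
        },
        "overall_survival": {
            "no_boost": [
                overall_survival(tr_nb, t) for t in range(config.n_cycles + 1)
            ],
            "boost": [overall_survival(tr_b, t) for t in range(config.n_cycles + 1)],
        },
    }

    if config.run_microsim:
        micro = {}
        for arm, params in (("no_boost", config.noboost), ("boost", config.boost)):
            res = simulate_patients(
                params,
                n_patients=int(config.n_patients),
                n_cycles=config.n_cycles,
                seed=config.seed,
                costs=config.costs,
                keep_trajectories=False,
            )
            micro[arm] = {
                "infections": res.total_infections,
                "infection_deaths": res.total_infection_deaths,
                "relapses": res.total_relapses,
                "relapse_deaths": res.total_relapse_deaths,
                "mean_cost_per_patient": round(float(res.cost_per_patient.mean()), 2),
            }
        bundle["microsim"] = {"seed": config.seed, **micro}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tr_nb.to_csv(outdir / "trace_noboost.csv")
        tr_b.to_csv(outdir / "trace_boost.csv")
        cost_breakdown_table(sum_nb, sum_b).to_csv(
            outdir / "cost_breakdown.csv", index=False
        )
        _write_json(bundle, outdir / "base_case.json")
    return bundle


def full_report(
    config: Optional[ModelConfig] = None,
    outdir: Optional[Path] = None,
    make_figures: bool = False,
) -> dict[str, Any]:
    """Compose base case + DSA + PSA + key drivers + calibration."""
    config = config or ModelConfig()

    stage = "base_case"
    try:
        base = run_base_case(config)

        stage = "dsa"
        dsa = run_dsa(
            config.noboost, config.boost, config.costs,
            grid=config.dsa_grid,
            n_patients=config.n_patients, n_cycles=config.n_cycles,
        )

        stage = "psa"
        psa = run_psa(
            ranges=config.psa_ranges,
            n_draws=config.psa_n_draws,
            seed=config.seed,
            noboost_params=config.noboost,
            boost_params=config.boost,
            n_patients=config.n_patients,
            n_cycles=config.n_cycles,
        )

        stage = "key_drivers"
        drivers = key_driver_regression(psa.draws)

        stage = "calibration"
        calib = calibrate_relapse_mortality(
            config.noboost,
            os_target=config.calibration_os_target,
            at_month=config.calibration_at_month,
        )
    except Exception as exc:
        raise RuntimeError(f"report stage {stage!r} failed: {exc}") from exc

    report: dict[str, Any] = {
        "provenance": {
            "artifact_version": __version__,
            "seed": config.seed,
            "parameters": config.to_dict(),
            "parameter_sources": PARAMETER_SOURCES,
        },
        "base_case": base,
        "dsa": {
            "results": dsa_table(dsa).to_dict(orient="records"),
            "note": "Reported dominance of hospitalization cost in the tornado "
            "is an annotation: under the stated one-way grids the reserve-cost "
            "and infection-split ranges produce the widest incremental-cost "
            "swings.",
        },
        "psa": psa.summary(),
        "key_drivers": drivers.round(6).to_dict(orient="records"),
        "calibration": {
            "os_target": calib.os_target,
            "at_month": calib.at_month,
            "calibrated_p_relapse_death_monthly": round(
                calib.p_relapse_death_monthly, 6
            ),
            "achieved_os": round(calib.achieved_os, 6),
            "base_case_p_relapse_death_monthly": config.noboost.p_relapse_death_monthly,
            "consistent_with_base_case": calib.matches_printed_base_case,
            "note": "The base case retains the published 3%/month relapse "
            "mortality; the calibrated root shows that value does not itself "
            "reproduce the stated 12-month overall-survival target under this "
            "state structure.",
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_json(report, outdir / "report.json")
        (outdir / "report.md").write_text(_render_markdown(report), encoding="utf-8")
        dsa_table(dsa).to_csv(outdir / "dsa.csv", index=False)
        psa.draws.to_csv(outdir / "psa_draws.csv", index=False)
        config.to_yaml(outdir / "effective_config.yaml")
        if make_figures:
            tornado_figure(dsa, outdir / "tornado.png")
            psa_histogram(psa, outdir / "psa_histogram.png")
    return report


def _write_json(obj: dict[str, Any], path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _render_markdown(report: dict[str, Any]) -> str:
    base = report["base_case"]
    ev, co = base["events"], base["costs"]
    calib = report["calibration"]
    lines = [
        "# Stem-cell reserve collection for CAR T: model report",
        "",
        f"Cohort: {base['n_patients']:g} patients, {base['n_cycles']} monthly cycles.",
        "",
        "## Base case",
        "",
        "| quantity | no boost | boost |",
        "| --- | --- | --- |",
        f"| severe infections | {ev['no_boost']['infections']:.2f} "
        f"| {ev['boost']['infections']:.2f} |",
        f"| infection deaths | {ev['no_boost']['infection_deaths']:.2f} "
        f"| {ev['boost']['infection_deaths']:.2f} |",
        f"| total cost per patient (USD) | {co['no_boost']['total_cost_per_patient']:,.2f} "
        f"| {co['boost']['total_cost_per_patient']:,.2f} |",
        "",
        f"Infections averted: {ev['infections_averted']:.2f}; "
        f"infection deaths averted: {ev['infection_deaths_averted']:.2f}.",
        f"Incremental cost (boost − no-boost): "
        f"${co['incremental_cost_per_patient']:,.2f} per patient "
        f"(break-even reserve cost ${co['break_even_reserve_cost']:,.2f}).",
        "",
        "## Sensitivity",
        "",
        f"Stress test: {report['psa']['n_draws']} draws, fraction with positive "
        f"incremental cost = {report['psa']['fraction_positive_incremental']:.3f}.",
        "",
        report["dsa"]["note"],
        "",
        "## Calibration",
        "",
        f"Relapse-death probability matching {calib['os_target']:.0%} OS at month "
        f"{calib['at_month']}: {calib['calibrated_p_relapse_death_monthly']:.4f}/month "
        f"(base case uses {calib['base_case_p_relapse_death_monthly']}).",
        calib["note"],
        "",
    ]
    return "\n".join(lines)
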