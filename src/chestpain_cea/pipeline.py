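"""End-to-end orchestration and report rendering.

``run_pipeline`` evaluates the deterministic cost and QALY models for the
requested scenarios, the incremental analysis against the Norwegian
threshold band, and optionally the Markov calibration, the PSA, the
budget impact and the diagnostics worked example, returning a result
bundle.  ``render_report`` serialises the bundle as CSV and
human-readable text with the study's rounding conventions (whole EUR,
five-decimal QALYs) and writes a manifest with content hashes so reruns
are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from typing import Any, Mapping, Sequence

import pandas as pd

from . import budget as budget_mod
from . import diagnostics as diag_mod
from ._rounding import round_eur, round_qaly
from .cea import (IncrementalResult, StrategyOutcome, icer,
                  icer_at_printed_precision, incremental, verdict_band)
from .costing import strategy_total_cost
from .markov import calibrate_schedules
from .params import ModelParameters, ScenarioSpec, load_parameters, resolve_scenario
from .psa import DEFAULT_LAMBDA_GRID, assign_distributions, ceac, run_psa
from .qaly import strategy_qaly

__all__ = ["run_pipeline", "render_report", "strategy_outcome",
           "report_table", "PipelineError"]

SCENARIOS = ("base_case", "conservative")
STRATEGIES = ("primary_care_algorithm", "hospital_standard")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def strategy_outcome(scenario: ScenarioSpec, strategy: str,
                     params: ModelParameters) -> StrategyOutcome:
    """Expected cost, QALY loss and mean LOS for one arm."""
    cost = strategy_total_cost(scenario, strategy, params)
    setting = ("primary_care" if strategy == "primary_care_algorithm"
               else "hospital")
    q = strategy_qaly(scenario, setting, params)
    los = (scenario.los_primary_mean_h if setting == "primary_care"
           else params.time.los_hospital_mean_h)
    return StrategyOutcome(strategy=strategy, scenario=scenario.name.value,
                           cost=cost, qaly=q, mean_los_h=los)


_ROW_ORDER = ["ems_to_primary", "consultation", "algorithm_addon",
              "ems_to_hospital", "hospital_drg", "TOTAL", "LOS_h", "QALY"]


def report_table(outcomes: Mapping[str, Mapping[str, StrategyOutcome]],
                 ) -> pd.DataFrame:
    """Summary table: component rows × (scenario, arm) columns + differences.

    Costs are whole EUR (components rounded before totalling); LOS in
    hours; QALY rows are five-decimal totals of rounded components.  The
    difference columns are primary-care arm minus hospital arm of the
    *rendered* values.
    """
    cols: dict[tuple[str, str], dict[str, float]] = {}
    for scenario, arms in outcomes.items():
        for strategy, out in arms.items():
            col: dict[str, float] = {}
            for comp in out.cost.components:
                col[comp.label] = comp.expected_cost_eur
            col["TOTAL"] = out.cost.total
            col["LOS_h"] = out.mean_los_h
            col["QALY"] = out.qaly.total_printed
            cols[(scenario, strategy)] = col
    df = pd.DataFrame(cols).reindex(_ROW_ORDER)
    for scenario in outcomes:
        p = df[(scenario, "primary_care_algorithm")]
        h = df[(scenario, "hospital_standard")]
        diff = p.fillna(0.0) - h.fillna(0.0)
        df[(scenario, "difference")] = diff
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["scenario", "arm"])
    return df.sort_index(axis=1, level=0)


def run_pipeline(config: str | Mapping[str, Any] | None = None,
                 scenarios: Sequence[str] = SCENARIOS,
                 seed: int = 0,
                 include_markov: bool = True,
                 include_psa: bool = False,
                 psa_draws: int = 10_000,
                 include_budget: bool = True,
                 include_diagnostics: bool = True) -> dict[str, Any]:
    """Run the full analysis and return the result bundle.

    Deterministic stages ignore ``seed``; the PSA consumes it.  Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    bundle: dict[str, Any] = {"seed": seed}
    # configuration problems surface as ConfigError (a validation error,
    # not a stage failure)
    params = load_parameters(config)
    bundle["params"] = params

    outcomes: dict[str, dict[str, StrategyOutcome]] = {}
    incrementals: dict[str, IncrementalResult] = {}
    band = (params.economics.threshold_low, params.economics.threshold_high)
    try:
        for name in scenarios:
            scenario = resolve_scenario(params, name)
            arms = {s: strategy_outcome(scenario, s, params)
                    for s in STRATEGIES}
            outcomes[name] = arms
            dc, dq = incremental(arms["primary_care_algorithm"],
                                 arms["hospital_standard"])
            res = icer_at_printed_precision(dc, dq, scenario=name)
            incrementals[name] = res
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'deterministic' failed: {exc}") from exc
    bundle["outcomes"] = outcomes
    bundle["incremental"] = incrementals
    bundle["verdicts"] = {name: verdict_band(res, band)
                          for name, res in incrementals.items()}
    bundle["table"] = report_table(outcomes)

    if include_markov:
        try:
            u = params.utility
            cal = calibrate_schedules(
                targets=(u.remaining_qalys_no_event, u.remaining_qalys_post_ami),
                settings=params.markov,
                base_utilities=(u.utility_non_cvd, u.utility_cvd, 0.0),
                discount_rate=params.economics.discount_rate)
            bundle["markov_calibration"] = cal
        except Exception as exc:
            raise PipelineError(f"stage 'markov' failed: {exc}") from exc

    if include_psa:
        try:
            dists = assign_distributions(params)
            psa_res = run_psa(dists, params, n_draws=psa_draws, seed=seed)
            bundle["psa"] = psa_res
            bundle["ceac"] = ceac(psa_res, DEFAULT_LAMBDA_GRID)
        except Exception as exc:
            raise PipelineError(f"stage 'psa' failed: {exc}") from exc

    if include_budget:
        try:
            inputs = budget_mod.NationalInputs()
            table = budget_mod.CoverageTable.default()
            bundle["budget"] = budget_mod.budget_report(inputs, table)
        except Exception as exc:
            raise PipelineError(f"stage 'budget' failed: {exc}") from exc

    if include_diagnostics:
        try:
            perf = diag_mod.TestPerformance()
            bundle["diagnostics"] = diag_mod.expected_confusion(1000, perf)
        except Exception as exc:
            raise PipelineError(f"stage 'diagnostics' failed: {exc}") from exc
    return bundle


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_report(bundle: Mapping[str, Any], outdir: str | pathlib.Path,
                  ) -> dict[str, Any]:
    """Write the bundle as CSV/JSON/text files plus a hash manifest.

    Returns the manifest.  Missing optional sections are listed under
    ``warnings`` rather than raising.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[pathlib.Path] = []
    warnings: list[str] = []

    if "table" in bundle:
        path = outdir / "summary_table.csv"
        bundle["table"].to_csv(path)
        written.append(path)
        txt = outdir / "summary_table.txt"
        txt.write_text(bundle["table"].to_string() + "\n")
        written.append(txt)
    else:
        warnings.append("missing section: table")

    if "incremental" in bundle:
        rows = []
        for name, res in bundle["incremental"].items():
            v = bundle.get("verdicts", {}).get(name, {})
            rows.append({"scenario": name,
                         "delta_cost_eur": round_eur(res.delta_cost),
                         "delta_qaly": round_qaly(res.delta_qaly),
                         "quadrant": res.quadrant.value,
                         "icer_eur_per_qaly": res.icer,
                         "verdict_at_low": v.get("at_low"),
                         "verdict_at_high": v.get("at_high")})
        path = outdir / "incremental.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
    else:
        warnings.append("missing section: incremental")

    if "psa" in bundle:
        psa_res = bundle["psa"]
        path = outdir / "psa_draws.csv"
        pd.DataFrame({"delta_cost": psa_res.delta_cost,
                      "delta_qaly": psa_res.delta_qaly}).to_csv(path,
                                                               index=False)
        written.append(path)
        if "ceac" in bundle:
            path = outdir / "ceac.csv"
            pd.DataFrame(bundle["ceac"],
                         columns=["lambda_eur_per_qaly",
                                  "p_cost_effective"]).to_csv(path, index=False)
            written.append(path)

    if "budget" in bundle:
        path = outdir / "budget_impact.csv"
        bundle["budget"].to_csv(path, index=False)
        written.append(path)

    if "diagnostics" in bundle:
        d = bundle["diagnostics"]
        path = outdir / "diagnostics.json"
        path.write_text(json.dumps(
            {"n": d.n, "expected": {"tp": d.tp, "fp": d.fp,
                                    "tn": d.tn, "fn": d.fn},
             "rounded": d.rounded(), "ppv": d.ppv, "npv": d.npv}, indent=2))
        written.append(path)

    if "markov_calibration" in bundle:
        cal = bundle["markov_calibration"]
        path = outdir / "markov_calibration.json"
        path.write_text(json.dumps(
            {"mortality_scale": cal.mortality_scale,
             "utility_scale": cal.utility_scale,
             "achieved_qalys": {"no_event": cal.achieved[0],
                                "post_ami": cal.achieved[1]},
             "residuals": list(cal.residuals)}, indent=2))
        written.append(path)

    manifest = {
        "seed": bundle.get("seed"),
        "files": {p.name: _sha256(p) for p in written},
        "warnings": warnings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
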