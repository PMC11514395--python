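"""Scenario switchboard and end-to-end report generation.

Scenarios mirror the published sensitivity programme: undiscounted
outcomes, frozen age trends, a 5-year horizon, duloxetine as the
alternative therapy, and the half-cycle correction.  Scenario application
is a pure function on the parameter set; the base object is never mutated.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .markov import compare_long_term
from .params import Gene, ParameterSet, Strategy
from .tree import compare_short_term, strategy_outcomes, write_pathways
from .uncertainty import (ceac, default_distribution_specs, run_psa,
                          tornado_regression, univariate_sweep)

__all__ = ["Scenario", "ScenarioSpec", "apply_scenario", "run_scenarios",
           "run_report", "config_hash", "DEFAULT_DULOXETINE_COST"]

#: placeholder 6-week duloxetine course cost per gene sub-model (QAR);
#: the source tables do not price the SNRI alternative, so applied work
#: should override this from config
DEFAULT_DULOXETINE_COST = {Gene.CYP2D6: 50.0, Gene.CYP2C19: 90.0}


class Scenario(str, Enum):
    BASE = "BASE"
    UNDISCOUNTED = "UNDISCOUNTED"
    NO_AGE_TRENDS = "NO_AGE_TRENDS"
    HORIZON_5Y = "HORIZON_5Y"
    ALT_DULOXETINE = "ALT_DULOXETINE"
    HALF_CYCLE = "HALF_CYCLE"


@dataclass
class ScenarioSpec:
    name: Scenario
    duloxetine_cost: dict[Gene, float] = field(
        default_factory=lambda: dict(DEFAULT_DULOXETINE_COST))


def apply_scenario(spec: ScenarioSpec | Scenario | str,
                   base: ParameterSet) -> ParameterSet:
    """Return a new parameter set with the scenario's deltas applied."""
    if not isinstance(spec, ScenarioSpec):
        spec = ScenarioSpec(Scenario(spec))
    ps = base.copy()
    name = spec.name
    if name == Scenario.BASE:
        pass
    elif name == Scenario.UNDISCOUNTED:
        ps.markov.discount_rate = 0.0  # Markov only; the tree is undiscounted anyway
    elif name == Scenario.NO_AGE_TRENDS:
        ps.options.age_trends = False
    elif name == Scenario.HORIZON_5Y:
        ps.options.horizon_years = 5.0
    elif name == Scenario.ALT_DULOXETINE:
        ps.short_costs.alternative_override = dict(spec.duloxetine_cost)
    elif name == Scenario.HALF_CYCLE:
        ps.options.half_cycle = True
    else:  # pragma: no cover - Scenario() already rejects unknown names
        raise ValueError(f"unknown scenario {name!r}")
    return ps


def run_scenarios(ps: ParameterSet) -> pd.DataFrame:
    """Short- and long-term savings for every scenario (the published
    scenario-table layout).  Markov-only scenarios must leave the short-term
    saving untouched; this is asserted as a regression check."""
    base_short = compare_short_term(ps).saving
    rows = []
    for scenario in Scenario:
        sps = apply_scenario(scenario, ps)
        short = compare_short_term(sps).saving
        long = compare_long_term(sps).saving
        if scenario in (Scenario.UNDISCOUNTED, Scenario.NO_AGE_TRENDS,
                        Scenario.HORIZON_5Y, Scenario.HALF_CYCLE):
            if abs(short - base_short) > 1e-9:
                raise AssertionError(
                    f"scenario {scenario.value} altered the short-term saving "
                    f"({base_short} -> {short}) but touches only the Markov model")
        rows.append({"scenario": scenario.value, "short_term_saving": short,
                     "long_term_saving": long})
    return pd.DataFrame(rows)


def config_hash(ps: ParameterSet) -> str:
    """Stable digest of every parameter and flag."""
    payload = dict(sorted(ps.flatten().items()))
    payload["__options__"] = {
        "gene_weights": {g.value: w for g, w in ps.options.gene_weights.items()},
        "carrier_fraction": ps.options.carrier_fraction,
        "count_switch_success": ps.options.count_switch_success,
        "renormalize_dispositions": ps.options.renormalize_dispositions,
        "use_dose_reduction": ps.options.use_dose_reduction,
        "charge_relapse_and_se_costs": ps.options.charge_relapse_and_se_costs,
        "age_trends": ps.options.age_trends,
        "half_cycle": ps.options.half_cycle,
        "horizon_years": ps.options.horizon_years,
        "discount_on": ps.options.discount_on,
        "variant": ps.markov.variant,
        "alternative_override": (
            {g.value: v for g, v in ps.short_costs.alternative_override.items()}
            if ps.short_costs.alternative_override else None),
        "mortality_table": ps.markov.mortality_table,
    }
    blob = json.dumps(payload, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()


def _base_table(ps: ParameterSet) -> pd.DataFrame:
    """Base-case results in the two-arm layout of the published summary."""
    short = compare_short_term(ps)
    long = compare_long_term(ps)
    pgx_s, soc_s = short.detail["PGX"], short.detail["SOC"]
    pgx_l, soc_l = long.detail["PGX"], long.detail["SOC"]
    rows = [
        ("short", "p_success_no_se", pgx_s.p_success_no_se, soc_s.p_success_no_se,
         short.delta_effects["p_success_no_se"],
         short.outcomes["p_success_no_se"].label.value),
        ("short", "p_success_any_se", pgx_s.p_success_any_se, soc_s.p_success_any_se,
         short.delta_effects["p_success_any_se"],
         short.outcomes["p_success_any_se"].label.value),
        ("short", "expected_cost", pgx_s.expected_cost, soc_s.expected_cost,
         short.delta_cost, ""),
        ("long", "ly", pgx_l.ly, soc_l.ly, long.delta_effects["ly"],
         long.outcomes["ly"].label.value),
        ("long", "qaly", pgx_l.qaly, soc_l.qaly, long.delta_effects["qaly"],
         long.outcomes["qaly"].label.value),
    ]
    for cat in pgx_l.cost_by_category:
        rows.append(("long", f"cost_{cat}", pgx_l.cost_by_category[cat],
                     soc_l.cost_by_category[cat],
                     long.detail["category_deltas"][cat], ""))
    rows.append(("long", "total_cost", pgx_l.total_cost, soc_l.total_cost,
                 long.delta_cost, ""))
    return pd.DataFrame(rows, columns=["horizon", "outcome", "pgx", "soc",
                                       "difference", "icer_label"])


def run_report(ps: ParameterSet, which=("base",), out_dir="results",
               seed: int = 0, psa_n: int = 50_000) -> dict[str, Path]:
    """Execute the requested analyses and write their tables under out_dir.

    ``which`` is any subset of {"base", "scenarios", "univariate", "psa"}.
    Returns the paths written; a run manifest (seed, version, config hash)
    accompanies every bundle.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to output directory {out}: {exc}") from exc

    written: dict[str, Path] = {}
    if "base" in which:
        table = _base_table(ps)
        path = out / "base_case.csv"
        table.to_csv(path, index=False)
        written["base_case"] = path
        for strat in Strategy:
            written[f"pathways_{strat.value}"] = write_pathways(
                strategy_outcomes(strat, ps, keep_pathways=True), out)
    if "scenarios" in which:
        path = out / "scenarios.csv"
        run_scenarios(ps).to_csv(path, index=False)
        written["scenarios"] = path
    if "univariate" in which:
        rows = []
        sweeps = [
            ("cost.short.genotyping_panel", "short_term_saving",
             lambda p: compare_short_term(p).saving),
            ("markov.discount_rate", "long_term_saving",
             lambda p: compare_long_term(p).saving),
        ]
        for pid, endpoint, fn in sweeps:
            low, high = univariate_sweep(ps, pid, fn, fraction=0.25)
            rows.append({"parameter": pid, "endpoint": endpoint,
                         "low": low, "high": high, "base": fn(ps)})
        path = out / "univariate.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written["univariate"] = path
    if "psa" in which:
        specs = default_distribution_specs(ps)
        psa = run_psa(ps, specs, psa_n, seed)
        path = out / "psa_draws.csv"
        psa.draws.to_csv(path, index=False)
        written["psa_draws"] = path
        grid = np.linspace(0.0, 2.0 * ps.wtp, 41)
        for eff, cost, tag in (("d_p_no_se", "d_cost_short", "short_no_se"),
                               ("d_p_any_se", "d_cost_short", "short_any_se"),
                               ("d_ly", "d_cost_long", "long_ly"),
                               ("d_qaly", "d_cost_long", "long_qaly")):
            curve = ceac(psa.draws[cost], psa.draws[eff], grid)
            cpath = out / f"ceac_{tag}.csv"
            curve.to_csv(cpath, index=False)
            written[f"ceac_{tag}"] = cpath
        for y, tag in (("d_cost_short", "short_saving"),
                       ("d_cost_long", "long_saving")):
            entries = tornado_regression(psa.inputs, -psa.draws[y])
            tpath = out / f"tornado_{tag}.csv"
            pd.DataFrame([{"parameter": e.param_id, "coefficient": e.coefficient,
                           "rank": e.rank} for e in entries]).to_csv(tpath, index=False)
            written[f"tornado_{tag}"] = tpath
        with open(out / "psa_summary.json", "w") as fh:
            json.dump(psa.summary(), fh, indent=2)
        written["psa_summary"] = out / "psa_summary.json"

    manifest = {
        "seed": seed,
        "package_version": __version__,
        "config_hash": config_hash(ps),
        "markov_variant": ps.markov.variant,
        "mortality_schedule": "synthetic Gompertz stand-in"
        if ps.markov.mortality_table and _is_default_synthetic(ps) else "user-supplied",
        "analyses": list(which),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    written["manifest"] = out / "manifest.json"
    return written


def _is_default_synthetic(ps: ParameterSet) -> bool:
    from .synthetic import SyntheticSpec, synthetic_mortality_table
    default = synthetic_mortality_table(SyntheticSpec())
    table = [(float(a), float(r)) for a, r in ps.markov.mortality_table]
    if len(table) != len(default):
        return False
    return all(abs(a - b) < 1e-9 and abs(x - y) < 5e-7
               for (a, x), (b, y) in zip(table, default))
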