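"""The 6-week decision tree.

Each strategy's cohort is partitioned by gene, metabolizer class and carrier
status.  Within a cell a patient either responds (with or without side
effects, then with or without relapse) or does not respond; after relapse or
no response a disposition follows (switch, titrate [no response only],
observe, discontinue, or a suicide attempt which resolves to death or
survival).  The leaf grammar yields 18 leaves per cell.  Leaf probabilities
partition the cohort exactly; leaf costs sum the acquisition, genotyping,
lab/screening, consultation, side-effect management, event and
disposition-specific components.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .economics import StrategyComparison, classify_icer
from .params import (Carrier, Gene, MetClass, ParameterSet, Strategy)

__all__ = [
    "Outcome", "Disposition", "SuicideResult", "Pathway", "ShortTermResult",
    "enumerate_pathways", "pathway_cost", "strategy_outcomes",
    "compare_short_term", "write_pathways",
]


class Outcome(str, Enum):
    RESPONSE_NO_SE_NO_RELAPSE = "RESPONSE_NO_SE_NO_RELAPSE"
    RESPONSE_SE_NO_RELAPSE = "RESPONSE_SE_NO_RELAPSE"
    RESPONSE_NO_SE_RELAPSE = "RESPONSE_NO_SE_RELAPSE"
    RESPONSE_SE_RELAPSE = "RESPONSE_SE_RELAPSE"
    NO_RESPONSE = "NO_RESPONSE"


class Disposition(str, Enum):
    SWITCH = "SWITCH"
    TITRATE = "TITRATE"
    OBSERVE = "OBSERVE"
    DISCONTINUE = "DISCONTINUE"
    SUICIDE_ATTEMPT = "SUICIDE_ATTEMPT"


class SuicideResult(str, Enum):
    DEATH = "DEATH"
    SURVIVAL = "SURVIVAL"


@dataclass
class Pathway:
    strategy: Strategy
    gene: Gene
    met_class: MetClass
    carrier: Carrier
    outcome: Outcome
    disposition: Disposition | None
    suicide_result: SuicideResult | None
    probability: float
    cost: float


@dataclass
class ShortTermResult:
    strategy: Strategy
    p_success_no_se: float    # response, no side effects, no relapse
    p_success_any_se: float   # response with/without side effects, no relapse
    expected_cost: float
    n_pathways: int
    pathways: list[Pathway] = field(default_factory=list, repr=False)


_RELAPSE_OUTCOMES = (Outcome.RESPONSE_NO_SE_RELAPSE, Outcome.RESPONSE_SE_RELAPSE)


def _acq(ps: ParameterSet, strategy: Strategy, gene: Gene, cls: MetClass):
    """Acquisition-cost row; with dose reduction disabled the PGx arm falls
    back to the standard (SoC) entries."""
    s = strategy if ps.options.use_dose_reduction else Strategy.SOC
    return ps.short_costs.acquisition[(gene, cls, s)]


def _alternative_cost(ps: ParameterSet, strategy: Strategy, gene: Gene,
                      cls: MetClass) -> float:
    if ps.short_costs.alternative_override is not None:
        return ps.short_costs.alternative_override[gene]
    return _acq(ps, strategy, gene, cls).first_line


def pathway_cost(pathway: Pathway, ps: ParameterSet) -> float:
    """Cost (QAR) of one root-to-leaf route, rebuilt from the cost table."""
    sc = ps.short_costs
    strategy, gene, cls = pathway.strategy, pathway.gene, pathway.met_class
    try:
        acq = _acq(ps, strategy, gene, cls)
    except KeyError as exc:
        raise KeyError(
            f"no acquisition cost entry for {gene.value}/{cls.value}/{strategy.value}"
        ) from exc
    alt = _alternative_cost(ps, strategy, gene, cls)
    cost = acq.first_line + sc.lab_screening + sc.consultation
    if strategy == Strategy.PGX:
        cost += sc.genotyping_panel
    has_se = pathway.outcome in (Outcome.RESPONSE_SE_NO_RELAPSE,
                                 Outcome.RESPONSE_SE_RELAPSE)
    has_relapse = pathway.outcome in _RELAPSE_OUTCOMES
    if has_se and (ps.options.charge_relapse_and_se_costs or not has_relapse):
        cost += sc.side_effect_total
    if has_relapse:
        cost += sc.event_relapse
    d = pathway.disposition
    if d == Disposition.SWITCH:
        cost += alt
    elif d == Disposition.TITRATE:
        cost += acq.increased_dose
    elif d == Disposition.DISCONTINUE:
        cost += acq.discontinuation + alt
    elif d == Disposition.SUICIDE_ATTEMPT:
        cost += sc.event_suicide_attempt
        if pathway.suicide_result == SuicideResult.DEATH:
            cost += sc.event_suicide_death
        else:
            cost += sc.event_survival + alt  # failed attempt -> switch
    return cost


def _leaves(strategy: Strategy, ps: ParameterSet):
    """Yield (gene, class, carrier, outcome, disposition, suicide_result,
    probability, cost, success_flag) over the whole tree."""
    renorm = ps.options.renormalize_dispositions
    disp = ps.dispositions[strategy]
    w_rel = disp.context_weights("relapse", renorm)
    w_nr = disp.context_weights("no_response", renorm)
    p_die = disp.p_suicide_death_given_attempt
    sc = ps.short_costs
    se_total = sc.side_effect_total
    charge_both = ps.options.charge_relapse_and_se_costs
    count_switch = ps.options.count_switch_success

    for gene, gw in ps.options.gene_weights.items():
        for w_cell, cls, carrier, cell in ps.cells(strategy, gene):
            w = gw * w_cell
            acq = _acq(ps, strategy, gene, cls)
            alt = _alternative_cost(ps, strategy, gene, cls)
            base = acq.first_line + sc.lab_screening + sc.consultation
            if strategy == Strategy.PGX:
                base += sc.genotyping_panel
            pr, prel, pse = (cell.p_response, cell.p_relapse_given_response,
                             cell.p_side_effect)

            yield (gene, cls, carrier, Outcome.RESPONSE_NO_SE_NO_RELAPSE, None,
                   None, w * pr * (1 - pse) * (1 - prel), base, "no_se")
            yield (gene, cls, carrier, Outcome.RESPONSE_SE_NO_RELAPSE, None,
                   None, w * pr * pse * (1 - prel), base + se_total, "any_se")

            for outcome, p_branch, se_flag in (
                    (Outcome.RESPONSE_NO_SE_RELAPSE, w * pr * (1 - pse) * prel, False),
                    (Outcome.RESPONSE_SE_RELAPSE, w * pr * pse * prel, True)):
                extra = sc.event_relapse + (se_total if se_flag and charge_both else 0.0)
                for dname, dw in w_rel.items():
                    p = p_branch * dw
                    if dname == "switch":
                        yield (gene, cls, carrier, outcome, Disposition.SWITCH, None,
                               p, base + extra + alt,
                               "conv" if count_switch else None)
                    elif dname == "observe":
                        yield (gene, cls, carrier, outcome, Disposition.OBSERVE, None,
                               p, base + extra, None)
                    elif dname == "discontinue":
                        yield (gene, cls, carrier, outcome, Disposition.DISCONTINUE,
                               None, p, base + extra + acq.discontinuation + alt,
                               "conv" if count_switch else None)
                    else:
                        yield (gene, cls, carrier, outcome, Disposition.SUICIDE_ATTEMPT,
                               SuicideResult.DEATH, p * p_die,
                               base + extra + sc.event_suicide_attempt
                               + sc.event_suicide_death, None)
                        yield (gene, cls, carrier, outcome, Disposition.SUICIDE_ATTEMPT,
                               SuicideResult.SURVIVAL, p * (1 - p_die),
                               base + extra + sc.event_suicide_attempt
                               + sc.event_survival + alt,
                               "conv" if count_switch else None)

            p_nr = w * (1 - pr)
            for dname, dw in w_nr.items():
                p = p_nr * dw
                if dname == "switch":
                    yield (gene, cls, carrier, Outcome.NO_RESPONSE, Disposition.SWITCH,
                           None, p, base + alt, "conv" if count_switch else None)
                elif dname == "titrate":
                    yield (gene, cls, carrier, Outcome.NO_RESPONSE, Disposition.TITRATE,
                           None, p, base + acq.increased_dose, None)
                elif dname == "observe":
                    yield (gene, cls, carrier, Outcome.NO_RESPONSE, Disposition.OBSERVE,
                           None, p, base, None)
                elif dname == "discontinue":
                    yield (gene, cls, carrier, Outcome.NO_RESPONSE,
                           Disposition.DISCONTINUE, None, p,
                           base + acq.discontinuation + alt,
                           "conv" if count_switch else None)
                else:
                    yield (gene, cls, carrier, Outcome.NO_RESPONSE,
                           Disposition.SUICIDE_ATTEMPT, SuicideResult.DEATH,
                           p * p_die, base + sc.event_suicide_attempt
                           + sc.event_suicide_death, None)
                    yield (gene, cls, carrier, Outcome.NO_RESPONSE,
                           Disposition.SUICIDE_ATTEMPT, SuicideResult.SURVIVAL,
                           p * (1 - p_die), base + sc.event_suicide_attempt
                           + sc.event_survival + alt,
                           "conv" if count_switch else None)


def enumerate_pathways(strategy: Strategy, ps: ParameterSet) -> list[Pathway]:
    """All root-to-leaf pathways of the tree; probabilities partition 1."""
    return [Pathway(strategy, gene, cls, carrier, outcome, disp, sres, p, c)
            for gene, cls, carrier, outcome, disp, sres, p, c, _flag
            in _leaves(strategy, ps)]


def strategy_outcomes(strategy: Strategy, ps: ParameterSet,
                      keep_pathways: bool = False) -> ShortTermResult:
    """Prevalence-weighted success probabilities and expected 6-week cost.

    Success is defined on the initial regimen: response without relapse,
    either excluding (primary) or including (secondary) side effects.
    Switch/discontinuation/post-attempt courses are assumed successful but by
    default do not count toward either endpoint
    (``options.count_switch_success`` flips this).
    """
    p_no_se = p_any_se = cost = 0.0
    n = 0
    pathways: list[Pathway] = []
    for gene, cls, carrier, outcome, disp, sres, p, c, flag in _leaves(strategy, ps):
        n += 1
        cost += p * c
        if flag == "no_se":
            p_no_se += p
            p_any_se += p
        elif flag == "any_se":
            p_any_se += p
        elif flag == "conv":
            p_no_se += p
            p_any_se += p
        if keep_pathways:
            pathways.append(Pathway(strategy, gene, cls, carrier, outcome,
                                    disp, sres, p, c))
    return ShortTermResult(strategy, p_no_se, p_any_se, cost, n, pathways)


def compare_short_term(ps: ParameterSet) -> StrategyComparison:
    """PGx versus SoC over six weeks: incremental success probabilities,
    incremental cost (negative = saving), and dominance classification for
    both success endpoints."""
    pgx = strategy_outcomes(Strategy.PGX, ps)
    soc = strategy_outcomes(Strategy.SOC, ps)
    delta_cost = pgx.expected_cost - soc.expected_cost
    deltas = {
        "p_success_no_se": pgx.p_success_no_se - soc.p_success_no_se,
        "p_success_any_se": pgx.p_success_any_se - soc.p_success_any_se,
    }
    outcomes = {k: classify_icer(delta_cost, v, ps.wtp) for k, v in deltas.items()}
    return StrategyComparison(
        delta_cost=delta_cost, delta_effects=deltas, outcomes=outcomes,
        detail={"PGX": pgx, "SOC": soc})


def write_pathways(result: ShortTermResult, out_dir: str | Path) -> Path:
    """Audit outputs: one CSV row per pathway plus a summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [{
        "strategy": pw.strategy.value, "gene": pw.gene.value,
        "met_class": pw.met_class.value, "carrier": pw.carrier.value,
        "outcome": pw.outcome.value,
        "disposition": pw.disposition.value if pw.disposition else "",
        "suicide_result": pw.suicide_result.value if pw.suicide_result else "",
        "probability": pw.probability, "cost": pw.cost,
    } for pw in result.pathways]
    csv_path = out / f"pathways_{result.strategy.value.lower()}.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    summary = {
        "strategy": result.strategy.value,
        "p_success_no_se": result.p_success_no_se,
        "p_success_any_se": result.p_success_any_se,
        "expected_cost": result.expected_cost,
        "n_pathways": result.n_pathways,
    }
    with open(out / f"summary_{result.strategy.value.lower()}.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return csv_path
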