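"""Lifetime Markov cohort model.

A closed cohort enters the response state at age 48 and is tracked in
3-month cycles until age 81 over five states: response (without relapse,
with or without side effects), relapse, no response, suicide death, and
non-suicide death.  Life-years, quality-adjusted life-years and costs
(events, medications, screening/lab, follow-up) accumulate per cycle with
annual discounting, optionally half-cycle corrected.

Two parameterization variants are supported.  ``as_printed`` applies the
published per-cycle transition block verbatim: suicide death from the two
failure states, non-suicide death from every living state at the printed
constant, return-to-response from both failure states, the two relapse
components summed.  ``reconciled`` (default) replaces the implausible
printed death columns: background mortality comes from a polynomial
age-trend fitted to an age-group schedule, and per-cycle suicide death is
derived from the short-term disposition attempt shares times the fatality
given an attempt.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import StrategyComparison, classify_icer, discount_factor
from .params import ParameterSet, Strategy

__all__ = [
    "STATES", "MortalityCurve", "CohortTrace", "LongTermResult",
    "fit_mortality_curve", "per_cycle_probability", "build_transition_matrix",
    "run_cohort", "compare_long_term", "write_trace",
]

logger = logging.getLogger(__name__)

#: state order used throughout
STATES = ("RESPONSE", "RELAPSE", "NO_RESPONSE", "SUICIDE_DEATH", "NONSUICIDE_DEATH")
RESPONSE, RELAPSE, NO_RESPONSE, SUICIDE_DEATH, NONSUICIDE_DEATH = range(5)
COST_CATEGORIES = ("events", "medications", "screening_lab", "follow_up")


@dataclass
class MortalityCurve:
    """Annual all-cause mortality as a polynomial in age, clamped to [0, 1]."""
    coefficients: np.ndarray  # ascending powers
    degree: int

    def __call__(self, age):
        rate = np.polynomial.polynomial.polyval(age, self.coefficients)
        return np.clip(rate, 0.0, 1.0)


def fit_mortality_curve(age_group_table, degree: int = 2) -> MortalityCurve:
    """Least-squares polynomial through (midpoint age, annual rate) points."""
    table = [(float(a), float(r)) for a, r in age_group_table]
    ages = np.array([a for a, _ in table])
    rates = np.array([r for _, r in table])
    if len(np.unique(ages)) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct midpoint ages for degree {degree}, "
            f"got {len(np.unique(ages))}")
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("annual mortality rates must lie in [0, 1]")
    poly = np.polynomial.Polynomial.fit(ages, rates, degree).convert()
    return MortalityCurve(poly.coef, degree)


def per_cycle_probability(p_annual: float, cycle_years: float) -> float:
    """Convert an annual event probability to a shorter cycle:
    1 - (1 - p)**cycle_years (constant-hazard assumption)."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual must be in [0, 1], got {p_annual}")
    if cycle_years <= 0:
        raise ValueError(f"cycle_years must be > 0, got {cycle_years}")
    return 1.0 - (1.0 - p_annual) ** cycle_years


def _suicide_rates(ps: ParameterSet, strategy: Strategy) -> tuple[float, float, float, float]:
    """(attempt from relapse, attempt from no-response, fatality, per-cycle SD)."""
    disp = ps.dispositions[strategy]
    w_rel = disp.context_weights("relapse", ps.options.renormalize_dispositions)
    w_nr = disp.context_weights("no_response", ps.options.renormalize_dispositions)
    return (w_rel["suicide_attempt"], w_nr["suicide_attempt"],
            disp.p_suicide_death_given_attempt, 0.0)


def build_transition_matrix(strategy: Strategy, age: float, ps: ParameterSet,
                            mortality_curve: MortalityCurve | None = None,
                            age_trends: bool | None = None) -> np.ndarray:
    """Per-cycle 5x5 transition matrix at the given age.

    Living rows are closed by assigning the remainder to self-transition;
    death rows are absorbing.  If printed off-diagonals sum beyond 1 in a
    row, they are scaled down with a logged warning.
    """
    rates = ps.markov.transitions[strategy]
    variant = ps.markov.variant
    if age_trends is None:
        age_trends = ps.options.age_trends

    if variant == "as_printed":
        q_ns = rates.nonsuicide_death
        q_sd_rel = q_sd_nr = rates.suicide_death
    else:
        if mortality_curve is None:
            mortality_curve = fit_mortality_curve(ps.markov.mortality_table,
                                                  ps.markov.mortality_degree)
        eval_age = age if age_trends else ps.markov.start_age
        q_ns = per_cycle_probability(float(mortality_curve(eval_age)),
                                     ps.markov.cycle_years)
        att_rel, att_nr, p_die, _ = _suicide_rates(ps, strategy)
        q_sd_rel = att_rel * p_die
        q_sd_nr = att_nr * p_die

    M = np.zeros((5, 5))
    rows = {
        RESPONSE: {RELAPSE: rates.relapse_total, NO_RESPONSE: rates.to_no_response,
                   NONSUICIDE_DEATH: q_ns},
        RELAPSE: {RESPONSE: rates.to_response, SUICIDE_DEATH: q_sd_rel,
                  NONSUICIDE_DEATH: q_ns},
        NO_RESPONSE: {RESPONSE: rates.to_response, SUICIDE_DEATH: q_sd_nr,
                      NONSUICIDE_DEATH: q_ns},
    }
    for s, entries in rows.items():
        total = sum(entries.values())
        scale = 1.0
        if total > 1.0:
            logger.warning(
                "transition row %s (%s, age %.1f) sums to %.4f > 1; renormalizing",
                STATES[s], strategy.value, age, total)
            scale = 1.0 / total
            total = 1.0
        for dest, p in entries.items():
            M[s, dest] = p * scale
        M[s, s] = 1.0 - total
    M[SUICIDE_DEATH, SUICIDE_DEATH] = 1.0
    M[NONSUICIDE_DEATH, NONSUICIDE_DEATH] = 1.0
    return M


@dataclass
class CohortTrace:
    strategy: Strategy
    records: pd.DataFrame            # per-cycle occupancies and discounted rewards
    ly: float                        # discounted life-years per person
    qaly: float
    cost_by_category: dict[str, float]

    @property
    def total_cost(self) -> float:
        return sum(self.cost_by_category.values())


@dataclass
class LongTermResult:
    strategy: Strategy
    ly: float
    qaly: float
    total_cost: float
    cost_by_category: dict[str, float]
    trace: CohortTrace = field(repr=False, default=None)

    def scaled(self, multiplier: float) -> dict[str, float]:
        """Cohort-scaled totals (e.g. multiplier = cohort size)."""
        out = {"ly": self.ly * multiplier, "qaly": self.qaly * multiplier,
               "total_cost": self.total_cost * multiplier}
        out.update({f"cost_{k}": v * multiplier
                    for k, v in self.cost_by_category.items()})
        return out


def run_cohort(strategy: Strategy, ps: ParameterSet, *,
               half_cycle: bool | None = None, age_trends: bool | None = None,
               horizon_years: float | None = None,
               discount_on: bool | None = None) -> CohortTrace:
    """Propagate the cohort and accumulate discounted rewards.

    Everyone starts in the response state.  State rewards (0.25 life-years,
    utility-weighted QALYs, per-cycle medication/lab/follow-up costs) accrue
    on start-of-cycle occupancy; one-off event costs (relapse, suicide
    attempt/death/survival, non-suicide death) are charged on incident
    transitions during the cycle.  With the half-cycle correction the first
    and last cycles carry half weight (trapezoidal approximation of
    mid-cycle transitions).
    """
    opts = ps.options
    half_cycle = opts.half_cycle if half_cycle is None else half_cycle
    age_trends = opts.age_trends if age_trends is None else age_trends
    horizon_years = (opts.horizon_years if horizon_years is None else horizon_years)
    discount_on = opts.discount_on if discount_on is None else discount_on

    mk = ps.markov
    cycle = mk.cycle_years
    max_years = mk.end_age - mk.start_age
    if horizon_years is not None:
        max_years = min(max_years, horizon_years)
    n_cycles = int(round(max_years / cycle))
    rate = mk.discount_rate if discount_on else 0.0
    lt = ps.long_costs
    curve = None
    if mk.variant != "as_printed":
        curve = fit_mortality_curve(mk.mortality_table, mk.mortality_degree)
        att_rel, att_nr, p_die, _ = _suicide_rates(ps, strategy)

    occ = np.zeros(5)
    occ[RESPONSE] = 1.0
    ly = qaly = 0.0
    costs = dict.fromkeys(COST_CATEGORIES, 0.0)
    rows = []
    for t in range(n_cycles):
        age = mk.start_age + cycle * t
        w = 0.5 if half_cycle and t in (0, n_cycles - 1) else 1.0
        d = w * discount_factor(cycle * t, rate)
        alive = occ[:3].sum()
        u = (occ[RESPONSE] * ps.utilities.response(age)
             + occ[RELAPSE] * ps.utilities.relapse
             + occ[NO_RESPONSE] * ps.utilities.no_response)
        d_ly = d * cycle * alive
        d_qaly = d * cycle * u
        ly += d_ly
        qaly += d_qaly
        costs["medications"] += d * lt.acquisition[strategy] * alive
        costs["screening_lab"] += d * lt.lab_screening * alive
        costs["follow_up"] += d * lt.follow_up * alive

        M = build_transition_matrix(strategy, age, ps, mortality_curve=curve,
                                    age_trends=age_trends)
        new_relapse = occ[RESPONSE] * M[RESPONSE, RELAPSE]
        sd_flow = (occ[RELAPSE] * M[RELAPSE, SUICIDE_DEATH]
                   + occ[NO_RESPONSE] * M[NO_RESPONSE, SUICIDE_DEATH]
                   + occ[RESPONSE] * M[RESPONSE, SUICIDE_DEATH])
        nsd_flow = sum(occ[s] * M[s, NONSUICIDE_DEATH] for s in range(3))
        ev = (new_relapse * lt.event_relapse
              + sd_flow * lt.event_suicide_death
              + nsd_flow * lt.event_nonsuicide_death)
        if mk.variant != "as_printed":
            attempts = occ[RELAPSE] * att_rel + occ[NO_RESPONSE] * att_nr
            ev += (attempts * lt.event_suicide_attempt
                   + attempts * (1.0 - p_die) * lt.event_survival)
        costs["events"] += d * ev
        rows.append((t, age, *occ, d_ly, d_qaly))
        occ = occ @ M

    records = pd.DataFrame(
        rows, columns=["cycle", "age", *[s.lower() for s in STATES],
                       "disc_ly", "disc_qaly"])
    return CohortTrace(strategy, records, ly, qaly, costs)


def _result(trace: CohortTrace) -> LongTermResult:
    return LongTermResult(trace.strategy, trace.ly, trace.qaly,
                          trace.total_cost, dict(trace.cost_by_category), trace)


def compare_long_term(ps: ParameterSet, **flags) -> StrategyComparison:
    """PGx versus SoC over the lifetime horizon: per-person incremental
    discounted life-years, QALYs and cost (negative delta = saving)."""
    pgx = _result(run_cohort(Strategy.PGX, ps, **flags))
    soc = _result(run_cohort(Strategy.SOC, ps, **flags))
    delta_cost = pgx.total_cost - soc.total_cost
    deltas = {"ly": pgx.ly - soc.ly, "qaly": pgx.qaly - soc.qaly}
    outcomes = {k: classify_icer(delta_cost, v, ps.wtp) for k, v in deltas.items()}
    category_deltas = {k: pgx.cost_by_category[k] - soc.cost_by_category[k]
                       for k in COST_CATEGORIES}
    return StrategyComparison(delta_cost=delta_cost, delta_effects=deltas,
                              outcomes=outcomes,
                              detail={"PGX": pgx, "SOC": soc,
                                      "category_deltas": category_deltas})


def write_trace(trace: CohortTrace, path) -> None:
    trace.records.to_csv(path, index=False)
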