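"""Synthetic model inputs for testing and development.

Generates random — but structurally valid — parameter sets (probability
simplexes, positive costs, utilities in [0, 1]) and Gompertz-like age-group
mortality schedules that stand in for a national life table.  Everything
produced here passes the same validators as hand-written config; nothing is
presented as observed data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (AcquisitionCosts, Carrier, ClinicalCell, Dispositions,
                     Gene, LongTermCosts, MarkovParameters, MetClass,
                     ModelOptions, ParameterSet, ShortTermCosts, Strategy,
                     TransitionRates, UtilityTable, VARIANT_CLASSES)

__all__ = ["SyntheticSpec", "random_parameter_set", "synthetic_mortality_table",
           "perturbed_set"]


@dataclass
class SyntheticSpec:
    seed: int = 0
    prob_low: float = 0.05
    prob_high: float = 0.6
    cost_scale: float = 500.0          # typical magnitude of cost entries (QAR)
    utility_low: float = 0.4
    utility_high: float = 0.95
    #: Gompertz-like mortality: annual rate at the anchor age, doubling time
    mortality_baseline: float = 0.002
    mortality_anchor_age: float = 48.0
    mortality_doubling_years: float = 8.0
    age_band_midpoints: tuple = (47, 52, 57, 62, 67, 72, 77, 82)
    markov_variant: str = "reconciled"

    def validate(self) -> None:
        if not (0 <= self.prob_low < self.prob_high <= 1):
            raise ValueError("need 0 <= prob_low < prob_high <= 1")
        if self.cost_scale <= 0:
            raise ValueError("cost_scale must be > 0")
        if not (0 <= self.utility_low < self.utility_high <= 1):
            raise ValueError("need 0 <= utility_low < utility_high <= 1")
        if not 0 <= self.mortality_baseline <= 1:
            raise ValueError("mortality_baseline must be in [0, 1]")


def synthetic_mortality_table(spec: SyntheticSpec) -> list[tuple[float, float]]:
    """Deterministic Gompertz-like schedule over 5-year bands (45-85).

    Rates double every ``mortality_doubling_years`` (infinite doubling time
    gives a flat schedule) and are clipped to [0, 1]."""
    spec.validate()
    table = []
    for mid in spec.age_band_midpoints:
        if np.isinf(spec.mortality_doubling_years):
            rate = spec.mortality_baseline
        else:
            rate = spec.mortality_baseline * 2.0 ** (
                (mid - spec.mortality_anchor_age) / spec.mortality_doubling_years)
        table.append((float(mid), float(min(max(rate, 0.0), 1.0))))
    return table


def random_parameter_set(spec: SyntheticSpec) -> ParameterSet:
    """A fully valid random parameter set with the study's structure."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    def prob(size=None):
        return rng.uniform(spec.prob_low, spec.prob_high, size)

    def cost():
        return float(rng.gamma(2.0, spec.cost_scale / 2.0))

    prevalence = {}
    for gene in Gene:
        classes = VARIANT_CLASSES[gene]
        # Dirichlet split of a random variant mass keeps the simplex valid
        mass = rng.uniform(0.2, 0.8)
        shares = rng.dirichlet(np.ones(len(classes)))
        prevalence[gene] = {c: float(mass * s) for c, s in zip(classes, shares)}

    clinical = {}
    for strat in Strategy:
        for gene in Gene:
            for cls in (*VARIANT_CLASSES[gene], MetClass.NORMAL):
                carriers = ((Carrier.CARRIER, Carrier.NONCARRIER)
                            if cls != MetClass.NORMAL else (Carrier.NONCARRIER,))
                for car in carriers:
                    clinical[(strat, gene, cls, car)] = ClinicalCell(
                        float(prob()), float(prob()), float(prob()))

    dispositions = {
        strat: Dispositions(*(float(rng.uniform(0.05, 0.7)) for _ in range(5)),
                            p_suicide_death_given_attempt=float(rng.uniform(0.001, 0.05)))
        for strat in Strategy
    }

    acquisition = {}
    for gene in Gene:
        for cls in (*VARIANT_CLASSES[gene], MetClass.NORMAL):
            for strat in Strategy:
                first = cost() / 10
                acquisition[(gene, cls, strat)] = AcquisitionCosts(
                    first, first * float(rng.uniform(0.3, 0.7)),
                    first * float(rng.uniform(1.2, 2.5)))
    short_costs = ShortTermCosts(
        acquisition=acquisition,
        side_effect_management={f"se_{i}": cost() / 2 for i in range(3)},
        event_relapse=cost(), event_suicide_death=cost() / 10,
        event_suicide_attempt=cost(), event_nonsuicide_death=cost(),
        event_survival=cost(), consultation=cost(), lab_screening=cost(),
        genotyping_panel=cost(),
    )
    long_costs = LongTermCosts(
        acquisition={s: cost() for s in Strategy},
        lab_screening=cost(), follow_up=cost(), event_relapse=cost(),
        event_suicide_death=cost() / 10, event_suicide_attempt=cost(),
        event_nonsuicide_death=cost(), event_survival=cost(),
    )

    bands = (40, 50, 60, 70, 80)
    u = np.sort(rng.uniform(spec.utility_low, spec.utility_high, len(bands)))[::-1]
    utilities = UtilityTable(
        response_by_age={b: float(v) for b, v in zip(bands, u)},
        relapse=float(rng.uniform(spec.utility_low, spec.utility_high)),
        no_response=float(rng.uniform(spec.utility_low, spec.utility_high)),
    )

    transitions = {}
    for strat in Strategy:
        # keep row budgets feasible: destination probabilities scaled to sum < 1
        raw = rng.uniform(0.02, 0.25, 5)
        transitions[strat] = TransitionRates(
            to_response=float(raw[0]), to_relapse=[float(raw[1]), float(raw[2])],
            to_no_response=float(raw[3]),
            suicide_death=float(rng.uniform(0.0005, 0.02)),
            nonsuicide_death=float(raw[4] / 10),
        )

    markov = MarkovParameters(
        discount_rate=float(rng.uniform(0.0, 0.05)),
        variant=spec.markov_variant,
        transitions=transitions,
        mortality_table=synthetic_mortality_table(spec),
    )
    ps = ParameterSet(
        prevalence=prevalence, clinical=clinical, dispositions=dispositions,
        short_costs=short_costs, long_costs=long_costs, utilities=utilities,
        markov=markov, wtp=float(rng.uniform(1e5, 1e6)), options=ModelOptions(),
    )
    ps.validate()
    return ps


def perturbed_set(base: ParameterSet, epsilon: float,
                  seed: int = 0, param_ids=None) -> ParameterSet:
    """Multiply each numeric parameter by a factor in [1 - eps, 1 + eps].

    Probability-like values are clamped back into [0, 1]; epsilon 0 is the
    identity.  ``param_ids`` restricts the perturbation to a subset."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        return base.copy()
    rng = np.random.default_rng(seed)
    flat = base.flatten()
    ids = list(flat) if param_ids is None else list(param_ids)
    updates = {}
    for pid in ids:
        factor = rng.uniform(1 - epsilon, 1 + epsilon)
        val = flat[pid] * factor
        if not pid.startswith("cost.") and pid != "wtp":
            val = min(max(val, 0.0), 1.0)
        updates[pid] = val
    # independent jitter can break the age-monotonicity of response utilities;
    # reassign the perturbed values in descending order across bands
    u_ids = sorted((p for p in updates if p.startswith("utility.response.")),
                   key=lambda p: int(p.rsplit(".", 1)[1]))
    if u_ids:
        ordered = sorted((updates[p] for p in u_ids), reverse=True)
        updates.update(dict(zip(u_ids, ordered)))
    ps = base.with_values(updates)
    ps.validate()
    return ps
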