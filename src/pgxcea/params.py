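"""Model parameterization: typed inputs, validation, and config I/O.

The parameter set describes a two-arm comparison — pharmacogenetic (PGx)
panel-guided antidepressant prescribing versus standard of care (SoC) — for
adults with moderate-severe major depressive disorder.  It is structured by
strategy x gene (CYP2D6, CYP2C19) x allele-carrier status x metabolizer
class (PM, IM, RM, URM, NORMAL), and covers the short-term (6-week) decision
tree, the lifetime Markov model, costs in Qatari Riyal (QAR), utilities and
discounting.

All parameters are addressable by a dotted flat id (see
:func:`ParameterSet.flatten`), which is how the uncertainty machinery
(probabilistic sensitivity analysis, univariate sweeps, perturbations)
refers to them.
"""
from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "Strategy", "Gene", "MetClass", "Carrier",
    "ClinicalCell", "Dispositions", "AcquisitionCosts", "ShortTermCosts",
    "LongTermCosts", "UtilityTable", "TransitionRates", "MarkovParameters",
    "ModelOptions", "ParameterSet",
    "SchemaError", "ValidationError",
    "load_parameters", "write_parameters", "metabolizer_distribution",
]


class Strategy(str, Enum):
    PGX = "PGX"
    SOC = "SOC"


class Gene(str, Enum):
    CYP2D6 = "CYP2D6"
    CYP2C19 = "CYP2C19"


class MetClass(str, Enum):
    PM = "PM"          # poor metabolizer
    IM = "IM"          # intermediate
    RM = "RM"          # rapid (CYP2C19 only)
    URM = "URM"        # ultra-rapid
    NORMAL = "NORMAL"


class Carrier(str, Enum):
    CARRIER = "CARRIER"
    NONCARRIER = "NONCARRIER"


#: variant (non-NORMAL) classes per gene; CYP2D6 has no rapid-metabolizer class
VARIANT_CLASSES = {
    Gene.CYP2D6: (MetClass.PM, MetClass.IM, MetClass.URM),
    Gene.CYP2C19: (MetClass.PM, MetClass.IM, MetClass.URM, MetClass.RM),
}


class SchemaError(KeyError):
    """A required field is missing from a parameter source."""


class ValidationError(ValueError):
    """One or more parameter values violate their domain constraints."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid parameter set:\n" + "\n".join(self.violations))


@dataclass
class ClinicalCell:
    """Short-term clinical probabilities for one strategy/gene/class/carrier cell."""
    p_response: float
    p_relapse_given_response: float
    p_side_effect: float


@dataclass
class Dispositions:
    """Management actions after treatment failure.

    The printed weights do not form a simplex; they are renormalized within
    each decision context: after relapse the options are {switch, observe,
    discontinue, suicide attempt}; after no response, {switch, titrate,
    observe, discontinue, suicide attempt}.  ``p_suicide_death_given_attempt``
    conditions the fatal outcome on an attempt.
    """
    switch: float
    titrate: float
    observe: float
    discontinue: float
    suicide_attempt: float
    p_suicide_death_given_attempt: float

    RELAPSE_CONTEXT = ("switch", "observe", "discontinue", "suicide_attempt")
    NO_RESPONSE_CONTEXT = ("switch", "titrate", "observe", "discontinue",
                           "suicide_attempt")

    def context_weights(self, context: str, renormalize: bool = True) -> dict[str, float]:
        names = (self.RELAPSE_CONTEXT if context == "relapse"
                 else self.NO_RESPONSE_CONTEXT)
        raw = {n: getattr(self, n) for n in names}
        if not renormalize:
            return raw
        total = sum(raw.values())
        if total <= 0:
            raise ValidationError([f"disposition weights in {context} context sum to {total}"])
        return {n: v / total for n, v in raw.items()}


@dataclass
class AcquisitionCosts:
    """6-week antidepressant course costs (QAR) for one gene/class/strategy cell."""
    first_line: float      # also the alternative course (same drug mix)
    discontinuation: float  # therapy until discontinuation (~3 weeks)
    increased_dose: float   # titrated course


@dataclass
class ShortTermCosts:
    acquisition: dict[tuple[Gene, MetClass, Strategy], AcquisitionCosts]
    side_effect_management: dict[str, float]
    event_relapse: float
    event_suicide_death: float
    event_suicide_attempt: float
    event_nonsuicide_death: float
    event_survival: float
    consultation: float
    lab_screening: float
    genotyping_panel: float
    #: optional replacement cost per gene for the alternative course
    #: (duloxetine scenario); None means alternative = first line
    alternative_override: dict[Gene, float] | None = None

    @property
    def side_effect_total(self) -> float:
        return sum(self.side_effect_management.values())


@dataclass
class LongTermCosts:
    """Per-cycle recurring and one-off event costs (QAR) for the Markov model."""
    acquisition: dict[Strategy, float]   # per 3-month cycle alive
    lab_screening: float                 # per cycle alive
    follow_up: float                     # per cycle alive
    event_relapse: float
    event_suicide_death: float
    event_suicide_attempt: float
    event_nonsuicide_death: float
    event_survival: float


@dataclass
class UtilityTable:
    """EQ-5D utility weights; response utility is age-banded (half-open bands)."""
    response_by_age: dict[int, float]    # band lower bound (years) -> utility
    relapse: float
    no_response: float
    suicide_attempt: float = 0.0

    def response(self, age: float) -> float:
        best = None
        for lo in sorted(self.response_by_age):
            if age >= lo:
                best = self.response_by_age[lo]
        if best is None:  # younger than the first band: use the first band
            best = self.response_by_age[min(self.response_by_age)]
        return best


@dataclass
class TransitionRates:
    """Per-cycle transition probabilities printed for one strategy.

    ``to_relapse`` keeps the two printed relapse components; the model sums
    them.  ``suicide_death`` applies from the relapse and no-response states,
    ``nonsuicide_death`` from every living state, and ``to_response`` is the
    return-to-response flow from both failure states.
    """
    to_response: float
    to_relapse: list[float]
    to_no_response: float
    suicide_death: float
    nonsuicide_death: float

    @property
    def relapse_total(self) -> float:
        return sum(self.to_relapse)


@dataclass
class MarkovParameters:
    start_age: float = 48.0
    end_age: float = 81.0
    cycle_years: float = 0.25
    discount_rate: float = 0.03
    cohort_size: int = 15_000
    #: "reconciled" (default) derives suicide death from the short-term
    #: attempt rates and background death from the fitted mortality curve;
    #: "as_printed" uses the transition block exactly as published.
    variant: str = "reconciled"
    transitions: dict[Strategy, TransitionRates] = field(default_factory=dict)
    mortality_table: list[tuple[float, float]] = field(default_factory=list)
    mortality_degree: int = 2


@dataclass
class ModelOptions:
    gene_weights: dict[Gene, float] = field(
        default_factory=lambda: {Gene.CYP2D6: 0.5, Gene.CYP2C19: 0.5})
    carrier_fraction: float = 1.0   # fraction of variant-class patients who are carriers
    count_switch_success: bool = False
    renormalize_dispositions: bool = True
    use_dose_reduction: bool = True
    charge_relapse_and_se_costs: bool = True
    age_trends: bool = True
    half_cycle: bool = False
    horizon_years: float | None = None
    discount_on: bool = True


@dataclass
class ParameterSet:
    prevalence: dict[Gene, dict[MetClass, float]]
    clinical: dict[tuple[Strategy, Gene, MetClass, Carrier], ClinicalCell]
    dispositions: dict[Strategy, Dispositions]
    short_costs: ShortTermCosts
    long_costs: LongTermCosts
    utilities: UtilityTable
    markov: MarkovParameters
    wtp: float = 546_000.0   # QAR per QALY / life-year (USD 150,000 x 3.64)
    options: ModelOptions = field(default_factory=ModelOptions)

    # ---------------------------------------------------------------- validation
    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every violation found."""
        v: list[str] = []

        def prob(x, name):
            if not (0.0 <= x <= 1.0):
                v.append(f"{name} = {x!r} outside [0, 1]")

        def nonneg(x, name):
            if x < 0:
                v.append(f"{name} = {x!r} is negative")

        for gene, classes in self.prevalence.items():
            s = 0.0
            for cls, p in classes.items():
                prob(p, f"prevalence.{gene.value}.{cls.value}")
                s += p
            if s > 1.0 + 1e-12:
                v.append(f"prevalence.{gene.value} variant classes sum to {s} > 1")
            if gene == Gene.CYP2D6 and MetClass.RM in classes:
                v.append("prevalence.CYP2D6 must not contain an RM entry")
        for key, cell in self.clinical.items():
            name = ".".join(k.value for k in key)
            prob(cell.p_response, f"clinical.{name}.p_response")
            prob(cell.p_relapse_given_response, f"clinical.{name}.p_relapse_given_response")
            prob(cell.p_side_effect, f"clinical.{name}.p_side_effect")
        for strat, d in self.dispositions.items():
            for fname in ("switch", "titrate", "observe", "discontinue",
                          "suicide_attempt", "p_suicide_death_given_attempt"):
                prob(getattr(d, fname), f"disposition.{strat.value}.{fname}")
        for (gene, cls, strat), acq in self.short_costs.acquisition.items():
            for fname in ("first_line", "discontinuation", "increased_dose"):
                nonneg(getattr(acq, fname),
                       f"cost.short.acquisition.{gene.value}.{cls.value}.{strat.value}.{fname}")
        for name, c in self.short_costs.side_effect_management.items():
            nonneg(c, f"cost.short.side_effect.{name}")
        for fname in ("event_relapse", "event_suicide_death", "event_suicide_attempt",
                      "event_nonsuicide_death", "event_survival", "consultation",
                      "lab_screening", "genotyping_panel"):
            nonneg(getattr(self.short_costs, fname), f"cost.short.{fname}")
        for strat, c in self.long_costs.acquisition.items():
            nonneg(c, f"cost.long.acquisition.{strat.value}")
        for fname in ("lab_screening", "follow_up", "event_relapse",
                      "event_suicide_death", "event_suicide_attempt",
                      "event_nonsuicide_death", "event_survival"):
            nonneg(getattr(self.long_costs, fname), f"cost.long.{fname}")
        ages = sorted(self.utilities.response_by_age)
        for lo in ages:
            prob(self.utilities.response_by_age[lo], f"utility.response.{lo}")
        for a, b in zip(ages, ages[1:]):
            if self.utilities.response_by_age[b] > self.utilities.response_by_age[a] + 1e-12:
                v.append(f"utility.response must be non-increasing across age bands "
                         f"({a}: {self.utilities.response_by_age[a]} < {b}: "
                         f"{self.utilities.response_by_age[b]})")
        prob(self.utilities.relapse, "utility.relapse")
        prob(self.utilities.no_response, "utility.no_response")
        m = self.markov
        if not m.start_age < m.end_age:
            v.append(f"markov.start_age {m.start_age} must be < end_age {m.end_age}")
        if m.cycle_years <= 0:
            v.append(f"markov.cycle_years {m.cycle_years} must be > 0")
        if m.discount_rate < 0:
            v.append(f"markov.discount_rate {m.discount_rate} must be >= 0")
        if m.variant not in ("reconciled", "as_printed"):
            v.append(f"markov.variant {m.variant!r} not one of 'reconciled', 'as_printed'")
        for strat, tr in m.transitions.items():
            prob(tr.to_response, f"markov.transition.{strat.value}.to_response")
            for i, p in enumerate(tr.to_relapse):
                prob(p, f"markov.transition.{strat.value}.to_relapse.{i}")
            prob(tr.to_no_response, f"markov.transition.{strat.value}.to_no_response")
            prob(tr.suicide_death, f"markov.transition.{strat.value}.suicide_death")
            prob(tr.nonsuicide_death, f"markov.transition.{strat.value}.nonsuicide_death")
        for mid, rate in m.mortality_table:
            prob(rate, f"markov.mortality_table[{mid}]")
        if self.wtp <= 0:
            v.append(f"wtp {self.wtp} must be > 0")
        prob(self.options.carrier_fraction, "options.carrier_fraction")
        if abs(sum(self.options.gene_weights.values()) - 1.0) > 1e-9:
            v.append("options.gene_weights must sum to 1")
        if v:
            raise ValidationError(v)

    # ---------------------------------------------------------------- helpers
    def cells(self, strategy: Strategy, gene: Gene) -> Iterator[tuple[float, MetClass, Carrier, ClinicalCell]]:
        """Yield (weight, class, carrier, clinical cell) covering the gene cohort.

        Weights sum to 1 over a gene: variant classes split between carrier
        and non-carrier by ``options.carrier_fraction``; the NORMAL remainder
        is non-carrier.
        """
        cf = self.options.carrier_fraction
        total_var = 0.0
        for cls in VARIANT_CLASSES[gene]:
            p = self.prevalence[gene][cls]
            total_var += p
            yield p * cf, cls, Carrier.CARRIER, self.clinical[(strategy, gene, cls, Carrier.CARRIER)]
            yield p * (1 - cf), cls, Carrier.NONCARRIER, self.clinical[(strategy, gene, cls, Carrier.NONCARRIER)]
        p_normal = 1.0 - total_var
        yield p_normal, MetClass.NORMAL, Carrier.NONCARRIER, \
            self.clinical[(strategy, gene, MetClass.NORMAL, Carrier.NONCARRIER)]

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # ------------------------------------------------------------- flat access
    def flatten(self) -> dict[str, float]:
        """Dotted-id view of every numeric parameter."""
        out: dict[str, float] = {}
        for gene, classes in self.prevalence.items():
            for cls, p in classes.items():
                out[f"prevalence.{gene.value}.{cls.value}"] = p
        for (strat, gene, cls, car), cell in self.clinical.items():
            base = f"clinical.{strat.value}.{gene.value}.{cls.value}.{car.value}"
            out[f"{base}.p_response"] = cell.p_response
            out[f"{base}.p_relapse_given_response"] = cell.p_relapse_given_response
            out[f"{base}.p_side_effect"] = cell.p_side_effect
        for strat, d in self.dispositions.items():
            for fname in ("switch", "titrate", "observe", "discontinue",
                          "suicide_attempt", "p_suicide_death_given_attempt"):
                out[f"disposition.{strat.value}.{fname}"] = getattr(d, fname)
        for (gene, cls, strat), acq in self.short_costs.acquisition.items():
            base = f"cost.short.acquisition.{gene.value}.{cls.value}.{strat.value}"
            out[f"{base}.first_line"] = acq.first_line
            out[f"{base}.discontinuation"] = acq.discontinuation
            out[f"{base}.increased_dose"] = acq.increased_dose
        for name, c in self.short_costs.side_effect_management.items():
            out[f"cost.short.side_effect.{name}"] = c
        for fname in ("event_relapse", "event_suicide_death", "event_suicide_attempt",
                      "event_nonsuicide_death", "event_survival", "consultation",
                      "lab_screening", "genotyping_panel"):
            out[f"cost.short.{fname}"] = getattr(self.short_costs, fname)
        for strat, c in self.long_costs.acquisition.items():
            out[f"cost.long.acquisition.{strat.value}"] = c
        for fname in ("lab_screening", "follow_up", "event_relapse",
                      "event_suicide_death", "event_suicide_attempt",
                      "event_nonsuicide_death", "event_survival"):
            out[f"cost.long.{fname}"] = getattr(self.long_costs, fname)
        for lo, u in self.utilities.response_by_age.items():
            out[f"utility.response.{lo}"] = u
        out["utility.relapse"] = self.utilities.relapse
        out["utility.no_response"] = self.utilities.no_response
        out["utility.suicide_attempt"] = self.utilities.suicide_attempt
        for strat, tr in self.markov.transitions.items():
            base = f"markov.transition.{strat.value}"
            out[f"{base}.to_response"] = tr.to_response
            for i, p in enumerate(tr.to_relapse):
                out[f"{base}.to_relapse.{i}"] = p
            out[f"{base}.to_no_response"] = tr.to_no_response
            out[f"{base}.suicide_death"] = tr.suicide_death
            out[f"{base}.nonsuicide_death"] = tr.nonsuicide_death
        out["markov.discount_rate"] = self.markov.discount_rate
        out["wtp"] = self.wtp
        return out

    def with_values(self, updates: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with the given flat ids replaced (no validation)."""
        ps = self.copy()
        for key, value in updates.items():
            _assign_flat(ps, key, float(value))
        return ps


def _assign_flat(ps: ParameterSet, key: str, value: float) -> None:
    parts = key.split(".")
    try:
        if parts[0] == "prevalence":
            ps.prevalence[Gene(parts[1])][MetClass(parts[2])] = value
        elif parts[0] == "clinical":
            cell = ps.clinical[(Strategy(parts[1]), Gene(parts[2]),
                                MetClass(parts[3]), Carrier(parts[4]))]
            setattr(cell, parts[5], value)
        elif parts[0] == "disposition":
            setattr(ps.dispositions[Strategy(parts[1])], parts[2], value)
        elif parts[:2] == ["cost", "short"] and parts[2] == "acquisition":
            acq = ps.short_costs.acquisition[(Gene(parts[3]), MetClass(parts[4]),
                                              Strategy(parts[5]))]
            setattr(acq, parts[6], value)
        elif parts[:2] == ["cost", "short"] and parts[2] == "side_effect":
            ps.short_costs.side_effect_management[parts[3]] = value
        elif parts[:2] == ["cost", "short"]:
            setattr(ps.short_costs, parts[2], value)
        elif parts[:2] == ["cost", "long"] and parts[2] == "acquisition":
            ps.long_costs.acquisition[Strategy(parts[3])] = value
        elif parts[:2] == ["cost", "long"]:
            setattr(ps.long_costs, parts[2], value)
        elif parts[0] == "utility" and parts[1] == "response":
            ps.utilities.response_by_age[int(parts[2])] = value
        elif parts[0] == "utility":
            setattr(ps.utilities, parts[1], value)
        elif parts[:2] == ["markov", "transition"]:
            tr = ps.markov.transitions[Strategy(parts[2])]
            if parts[3] == "to_relapse":
                tr.to_relapse[int(parts[4])] = value
            else:
                setattr(tr, parts[3], value)
        elif key == "markov.discount_rate":
            ps.markov.discount_rate = value
        elif key == "wtp":
            ps.wtp = value
        else:
            raise KeyError(key)
    except (KeyError, ValueError) as exc:
        raise KeyError(f"unknown parameter id {key!r}") from exc


# ------------------------------------------------------------------ config I/O

_REQUIRED_SCALARS = [
    "wtp", "cost.short.genotyping_panel", "cost.short.lab_screening",
    "cost.short.consultation",
]


def _data_dir() -> Path:
    return Path(importlib.resources.files("pgxcea") / "data")


def load_parameters(source: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter set.

    ``source`` is a YAML config referencing CSV tables (paths relative to the
    config file); ``None`` loads the packaged default, which transcribes the
    published base case.
    """
    path = Path(source) if source is not None else _data_dir() / "parameters.yaml"
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = path.parent

    def need(mapping, key, context):
        cur = mapping
        for part in key.split("."):
            if not isinstance(cur, dict) or part not in cur:
                raise SchemaError(f"missing field {key!r} in {context}")
            cur = cur[part]
        return cur

    def table(name):
        fname = need(cfg, f"tables.{name}", str(path))
        return pd.read_csv(base / fname)

    prev_df = table("prevalence")
    prevalence: dict[Gene, dict[MetClass, float]] = {g: {} for g in Gene}
    for row in prev_df.itertuples():
        prevalence[Gene(row.gene)][MetClass(row.met_class)] = float(row.prevalence)

    clin_df = table("clinical")
    clinical = {}
    for row in clin_df.itertuples():
        key = (Strategy(row.strategy), Gene(row.gene), MetClass(row.met_class),
               Carrier(row.carrier))
        clinical[key] = ClinicalCell(float(row.p_response),
                                     float(row.p_relapse_given_response),
                                     float(row.p_side_effect))

    disp_df = table("dispositions")
    dispositions = {}
    for row in disp_df.itertuples():
        dispositions[Strategy(row.strategy)] = Dispositions(
            float(row.switch), float(row.titrate), float(row.observe),
            float(row.discontinue), float(row.suicide_attempt),
            float(row.p_suicide_death_given_attempt))

    acq_df = table("acquisition_costs")
    acquisition = {}
    for row in acq_df.itertuples():
        acquisition[(Gene(row.gene), MetClass(row.met_class), Strategy(row.strategy))] = \
            AcquisitionCosts(float(row.first_line), float(row.discontinuation),
                             float(row.increased_dose))

    se_df = table("side_effect_costs")
    side_effects = {row.side_effect: float(row.cost) for row in se_df.itertuples()}

    costs = cfg.get("costs", {})
    sc = need(costs, "short", str(path))
    lc = need(costs, "long", str(path))

    def cost_field(d, key, label):
        if key not in d:
            raise SchemaError(f"missing field {label!r} in {path}")
        val = d[key]
        if val is None:
            raise SchemaError(f"missing field {label!r} in {path}")
        return float(val)

    alt_override = None
    if sc.get("alternative_override"):
        alt_override = {Gene(g): float(v) for g, v in sc["alternative_override"].items()}
    short_costs = ShortTermCosts(
        acquisition=acquisition,
        side_effect_management=side_effects,
        event_relapse=cost_field(sc, "event_relapse", "cost.short.event_relapse"),
        event_suicide_death=cost_field(sc, "event_suicide_death", "cost.short.event_suicide_death"),
        event_suicide_attempt=cost_field(sc, "event_suicide_attempt", "cost.short.event_suicide_attempt"),
        event_nonsuicide_death=cost_field(sc, "event_nonsuicide_death", "cost.short.event_nonsuicide_death"),
        event_survival=cost_field(sc, "event_survival", "cost.short.event_survival"),
        consultation=cost_field(sc, "consultation", "cost.short.consultation"),
        lab_screening=cost_field(sc, "lab_screening", "cost.short.lab_screening"),
        genotyping_panel=cost_field(sc, "genotyping_panel", "genotyping panel cost"),
        alternative_override=alt_override,
    )
    long_costs = LongTermCosts(
        acquisition={Strategy(s): float(v) for s, v in need(lc, "acquisition", str(path)).items()},
        lab_screening=cost_field(lc, "lab_screening", "cost.long.lab_screening"),
        follow_up=cost_field(lc, "follow_up", "cost.long.follow_up"),
        event_relapse=cost_field(lc, "event_relapse", "cost.long.event_relapse"),
        event_suicide_death=cost_field(lc, "event_suicide_death", "cost.long.event_suicide_death"),
        event_suicide_attempt=cost_field(lc, "event_suicide_attempt", "cost.long.event_suicide_attempt"),
        event_nonsuicide_death=cost_field(lc, "event_nonsuicide_death", "cost.long.event_nonsuicide_death"),
        event_survival=cost_field(lc, "event_survival", "cost.long.event_survival"),
    )

    util_df = table("utilities")
    response_by_age = {}
    relapse_u = no_response_u = None
    for row in util_df.itertuples():
        if row.state == "response":
            response_by_age[int(row.age_band_lower)] = float(row.utility)
        elif row.state == "relapse":
            relapse_u = float(row.utility)
        elif row.state == "no_response":
            no_response_u = float(row.utility)
    if relapse_u is None or no_response_u is None or not response_by_age:
        raise SchemaError(f"utilities table in {path} must define response bands, "
                          "relapse and no_response")
    utilities = UtilityTable(response_by_age, relapse_u, no_response_u)

    trans_df = table("transitions")
    transitions = {}
    for strat in Strategy:
        sub = trans_df[trans_df.strategy == strat.value]
        if sub.empty:
            raise SchemaError(f"missing transitions for strategy {strat.value}")
        rows = dict(zip(sub.target, sub.probability))
        rel = sorted(float(v) for k, v in rows.items() if k.startswith("relapse"))
        transitions[strat] = TransitionRates(
            to_response=float(rows["response"]),
            to_relapse=rel,
            to_no_response=float(rows["no_response"]),
            suicide_death=float(rows["suicide_death"]),
            nonsuicide_death=float(rows["nonsuicide_death"]),
        )

    mort_df = table("mortality")
    mortality = [(float(r.midpoint_age), float(r.annual_rate)) for r in mort_df.itertuples()]

    mk = cfg.get("markov", {})
    markov = MarkovParameters(
        start_age=float(mk.get("start_age", 48.0)),
        end_age=float(mk.get("end_age", 81.0)),
        cycle_years=float(mk.get("cycle_years", 0.25)),
        discount_rate=float(need(cfg, "markov.discount_rate", str(path))),
        cohort_size=int(mk.get("cohort_size", 15_000)),
        variant=str(mk.get("variant", "reconciled")),
        transitions=transitions,
        mortality_table=mortality,
        mortality_degree=int(mk.get("mortality_degree", 2)),
    )

    opts = cfg.get("options", {})
    options = ModelOptions(
        gene_weights={Gene(g): float(w) for g, w in opts.get(
            "gene_weights", {"CYP2D6": 0.5, "CYP2C19": 0.5}).items()},
        carrier_fraction=float(opts.get("carrier_fraction", 1.0)),
        count_switch_success=bool(opts.get("count_switch_success", False)),
        renormalize_dispositions=bool(opts.get("renormalize_dispositions", True)),
        use_dose_reduction=bool(opts.get("use_dose_reduction", True)),
        charge_relapse_and_se_costs=bool(opts.get("charge_relapse_and_se_costs", True)),
        age_trends=bool(opts.get("age_trends", True)),
        half_cycle=bool(opts.get("half_cycle", False)),
        horizon_years=opts.get("horizon_years"),
        discount_on=bool(opts.get("discount_on", True)),
    )

    ps = ParameterSet(
        prevalence=prevalence, clinical=clinical, dispositions=dispositions,
        short_costs=short_costs, long_costs=long_costs, utilities=utilities,
        markov=markov, wtp=float(need(cfg, "wtp", str(path))), options=options,
    )
    ps.validate()
    return ps


def write_parameters(ps: ParameterSet, out_dir: str | Path) -> Path:
    """Serialize a parameter set as a YAML config + CSV tables; returns the YAML path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [(g.value, c.value, p) for g, classes in ps.prevalence.items()
         for c, p in classes.items()],
        columns=["gene", "met_class", "prevalence"],
    ).to_csv(out / "prevalence.csv", index=False)

    pd.DataFrame(
        [(s.value, g.value, c.value, k.value, cell.p_response,
          cell.p_relapse_given_response, cell.p_side_effect)
         for (s, g, c, k), cell in ps.clinical.items()],
        columns=["strategy", "gene", "met_class", "carrier", "p_response",
                 "p_relapse_given_response", "p_side_effect"],
    ).to_csv(out / "clinical.csv", index=False)

    pd.DataFrame(
        [(s.value, d.switch, d.titrate, d.observe, d.discontinue,
          d.suicide_attempt, d.p_suicide_death_given_attempt)
         for s, d in ps.dispositions.items()],
        columns=["strategy", "switch", "titrate", "observe", "discontinue",
                 "suicide_attempt", "p_suicide_death_given_attempt"],
    ).to_csv(out / "dispositions.csv", index=False)

    pd.DataFrame(
        [(g.value, c.value, s.value, a.first_line, a.discontinuation, a.increased_dose)
         for (g, c, s), a in ps.short_costs.acquisition.items()],
        columns=["gene", "met_class", "strategy", "first_line", "discontinuation",
                 "increased_dose"],
    ).to_csv(out / "acquisition_costs.csv", index=False)

    pd.DataFrame(
        sorted(ps.short_costs.side_effect_management.items()),
        columns=["side_effect", "cost"],
    ).to_csv(out / "side_effect_costs.csv", index=False)

    util_rows = [("response", lo, u) for lo, u in sorted(ps.utilities.response_by_age.items())]
    util_rows += [("relapse", "", ps.utilities.relapse),
                  ("no_response", "", ps.utilities.no_response)]
    pd.DataFrame(util_rows, columns=["state", "age_band_lower", "utility"]) \
        .to_csv(out / "utilities.csv", index=False)

    trans_rows = []
    for s, tr in ps.markov.transitions.items():
        trans_rows.append((s.value, "response", tr.to_response))
        for i, p in enumerate(tr.to_relapse):
            trans_rows.append((s.value, f"relapse_{i}", p))
        trans_rows.append((s.value, "no_response", tr.to_no_response))
        trans_rows.append((s.value, "suicide_death", tr.suicide_death))
        trans_rows.append((s.value, "nonsuicide_death", tr.nonsuicide_death))
    pd.DataFrame(trans_rows, columns=["strategy", "target", "probability"]) \
        .to_csv(out / "transitions.csv", index=False)

    pd.DataFrame(ps.markov.mortality_table, columns=["midpoint_age", "annual_rate"]) \
        .to_csv(out / "mortality.csv", index=False)

    sc, lc = ps.short_costs, ps.long_costs
    cfg = {
        "wtp": ps.wtp,
        "tables": {
            "prevalence": "prevalence.csv", "clinical": "clinical.csv",
            "dispositions": "dispositions.csv",
            "acquisition_costs": "acquisition_costs.csv",
            "side_effect_costs": "side_effect_costs.csv",
            "utilities": "utilities.csv", "transitions": "transitions.csv",
            "mortality": "mortality.csv",
        },
        "costs": {
            "short": {
                "event_relapse": sc.event_relapse,
                "event_suicide_death": sc.event_suicide_death,
                "event_suicide_attempt": sc.event_suicide_attempt,
                "event_nonsuicide_death": sc.event_nonsuicide_death,
                "event_survival": sc.event_survival,
                "consultation": sc.consultation,
                "lab_screening": sc.lab_screening,
                "genotyping_panel": sc.genotyping_panel,
                "alternative_override": (
                    {g.value: v for g, v in sc.alternative_override.items()}
                    if sc.alternative_override else None),
            },
            "long": {
                "acquisition": {s.value: v for s, v in lc.acquisition.items()},
                "lab_screening": lc.lab_screening, "follow_up": lc.follow_up,
                "event_relapse": lc.event_relapse,
                "event_suicide_death": lc.event_suicide_death,
                "event_suicide_attempt": lc.event_suicide_attempt,
                "event_nonsuicide_death": lc.event_nonsuicide_death,
                "event_survival": lc.event_survival,
            },
        },
        "markov": {
            "start_age": ps.markov.start_age, "end_age": ps.markov.end_age,
            "cycle_years": ps.markov.cycle_years,
            "discount_rate": ps.markov.discount_rate,
            "cohort_size": ps.markov.cohort_size, "variant": ps.markov.variant,
            "mortality_degree": ps.markov.mortality_degree,
        },
        "options": {
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
        },
    }
    cfg_path = out / "parameters.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return cfg_path


def metabolizer_distribution(gene: Gene,
                             prevalences: Mapping[MetClass, float]) -> dict[MetClass, float]:
    """Complete a gene's metabolizer-class distribution with the NORMAL remainder.

    The variant-class prevalences must sum to at most 1; NORMAL takes the
    remainder so the returned map is a simplex.
    """
    gene = Gene(gene)
    for cls in prevalences:
        if MetClass(cls) not in VARIANT_CLASSES[gene]:
            raise ValidationError(
                [f"{MetClass(cls).value} is not a variant class of {gene.value}"])
    total = float(sum(prevalences.values()))
    if total > 1.0 + 1e-12:
        raise ValidationError(
            [f"variant prevalences for {gene.value} sum to {total} > 1"])
    out = {MetClass(c): float(p) for c, p in prevalences.items()}
    out[MetClass.NORMAL] = 1.0 - total
    return out
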