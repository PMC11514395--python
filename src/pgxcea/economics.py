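"""Health-economic primitives: discounting, ICER/dominance, net monetary
benefit, and cross-country cost adaptation."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "ICERLabel", "ICEROutcome", "StrategyComparison", "CostAdaptationIndices",
    "discount_factor", "classify_icer", "nmb", "adapt_cost",
]


class ICERLabel(str, Enum):
    DOMINANT = "DOMINANT"              # cheaper and more effective
    COST_EFFECTIVE = "COST_EFFECTIVE"  # dearer but ICER below willingness to pay
    NOT_COST_EFFECTIVE = "NOT_COST_EFFECTIVE"
    DOMINATED = "DOMINATED"            # dearer and less effective
    INDIFFERENT = "INDIFFERENT"


@dataclass
class ICEROutcome:
    delta_cost: float
    delta_effect: float
    label: ICERLabel
    icer: float | None  # QAR per effect unit; None when undefined


@dataclass
class StrategyComparison:
    """Paired results of the PGx arm versus standard of care.

    ``delta_cost`` is cost(PGX) - cost(SOC), so a negative value is a saving;
    ``saving`` reports the conventional positive-is-cheaper sign.  Effects are
    PGX minus SOC per endpoint name.
    """
    delta_cost: float
    delta_effects: dict[str, float]
    outcomes: dict[str, ICEROutcome]
    detail: dict = field(default_factory=dict)

    @property
    def saving(self) -> float:
        return -self.delta_cost


def discount_factor(t_years: float, rate: float) -> float:
    """Present-value factor (1 + rate)**(-t), continuous in t."""
    if t_years < 0:
        raise ValueError(f"t_years must be >= 0, got {t_years}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-t_years)


def classify_icer(delta_cost: float, delta_effect: float, wtp: float) -> ICEROutcome:
    """Classify an incremental (cost, effect) pair against a WTP threshold.

    Dominant strategies (cheaper, more effective) and dominated ones do not
    report a ratio, following standard practice.
    """
    if wtp <= 0:
        raise ValueError(f"wtp must be > 0, got {wtp}")
    if delta_cost == 0 and delta_effect == 0:
        return ICEROutcome(delta_cost, delta_effect, ICERLabel.INDIFFERENT, None)
    if delta_cost < 0 and delta_effect > 0:
        return ICEROutcome(delta_cost, delta_effect, ICERLabel.DOMINANT, None)
    if delta_cost > 0 and delta_effect < 0:
        return ICEROutcome(delta_cost, delta_effect, ICERLabel.DOMINATED, None)
    if delta_effect == 0:
        label = ICERLabel.NOT_COST_EFFECTIVE if delta_cost > 0 else ICERLabel.DOMINANT
        return ICEROutcome(delta_cost, delta_effect, label, None)
    icer = delta_cost / delta_effect
    if delta_effect > 0:
        label = ICERLabel.COST_EFFECTIVE if icer < wtp else ICERLabel.NOT_COST_EFFECTIVE
    else:
        # less effective but cheaper: acceptable if savings per effect lost exceed WTP
        label = ICERLabel.COST_EFFECTIVE if icer > wtp else ICERLabel.NOT_COST_EFFECTIVE
    return ICEROutcome(delta_cost, delta_effect, label, icer)


def nmb(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """Incremental net monetary benefit, WTP x dEffect - dCost (QAR)."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return wtp * delta_effect - delta_cost


@dataclass
class CostAdaptationIndices:
    """Factors to transfer a foreign cost estimate to QAR at 2024 prices."""
    source_currency: str
    exchange_rate_to_qar: float
    expenditure_index_source: float  # per-capita health expenditure
    expenditure_index_target: float
    price_index_source: float        # health price level
    price_index_target: float
    inflation_factor: float          # source year -> 2024

    def validate(self) -> None:
        for name in ("exchange_rate_to_qar", "expenditure_index_source",
                     "expenditure_index_target", "price_index_source",
                     "price_index_target", "inflation_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


def adapt_cost(amount: float, indices: CostAdaptationIndices,
               provenance_path=None) -> float:
    """Transfer a foreign cost (source currency, source year) to 2024 QAR.

    Applies inflation, a health-expenditure utilisation correction, a health
    price-level correction, and the exchange rate, in that order:

        amount x inflation x (E_target / E_source)
               / (P_source / P_target) x FX

    The factor composition is recorded so alternative compositions remain a
    configuration change; when ``provenance_path`` is given the full factor
    breakdown is serialized there as JSON.
    """
    if amount < 0:
        raise ValueError(f"amount must be >= 0, got {amount}")
    indices.validate()
    expenditure = indices.expenditure_index_target / indices.expenditure_index_source
    price = indices.price_index_source / indices.price_index_target
    result = (amount * indices.inflation_factor * expenditure / price
              * indices.exchange_rate_to_qar)
    if provenance_path is not None:
        record = {
            "amount_source": amount,
            "source_currency": indices.source_currency,
            "inflation_factor": indices.inflation_factor,
            "expenditure_correction": expenditure,
            "price_correction_divisor": price,
            "exchange_rate_to_qar": indices.exchange_rate_to_qar,
            "result_qar_2024": result,
        }
        with open(provenance_path, "w") as fh:
            json.dump(record, fh, indent=2)
    return result
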