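"""National projection and cost-offset arithmetic.

From claims-derived rates (NVAF prevalence, treatment-eligibility and
untreated fractions, annual stroke risk among untreated patients, stroke
case fatality) and cost parameters (excess first-year stroke cost, therapy
cost per member per month, bleed rate and cost), project strokes prevented,
deaths prevented, dollar savings, and the net treatment benefit for each
surveillance method and their difference.

The national NVAF populations per method are config inputs, not computed
values: the claims-to-census intermediate step behind them is not derivable
from the stated rates, so the pipeline computes forward from the "needing
treatment" counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ClaimsRates:
    """Rates observed in the claims population (counts kept for round-trip)."""
    nvaf_prevalence: float = 967_801 / 63_296_120
    eligible_fraction: float = 816_240 / 967_801       # CHA2DS2-VASc>=2, no CI
    untreated_fraction: float = 495_749 / 816_240
    stroke_risk: float = 0.0444                        # annual, untreated
    stroke_death_risk: float = 0.0599
    counts: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "nvaf_prevalence": (967_801, 63_296_120),
        "eligible_fraction": (816_240, 967_801),
        "untreated_fraction": (495_749, 816_240),
        "stroke_risk": (22_021, 495_749),
        "stroke_death_risk": (1_320, 22_021),
    })

    def validate(self) -> None:
        for name in ("nvaf_prevalence", "eligible_fraction",
                     "untreated_fraction", "stroke_risk",
                     "stroke_death_risk"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


@dataclass
class CostParams:
    pre_stroke_monthly: float = 2_763.33        # USD/month before stroke
    post_stroke_monthly: float = 11_538.0       # USD/month after stroke
    adjusted_monthly_savings: float = 8_556.66  # inflation-adjusted USD/month
    bleed_rate: float = 0.0034                  # annual major-bleed risk on OAC
    bleed_cost: float = 23_777.67               # USD per major bleed
    therapy_cost_pmpm: float = 76.19            # USD per member per month
    inflation_rate: float = 0.019               # annual
    #: Printed national annual therapy cost; when set it replaces the
    #: pmpm x 12 x needing-treatment product for the combined column (the
    #: treated-population denominator behind it is not stated upstream).
    national_therapy_cost: float | None = 3_750_758_790.0
    include_bleed_offset: bool = False

    def validate(self) -> None:
        for name in ("pre_stroke_monthly", "post_stroke_monthly",
                     "adjusted_monthly_savings", "bleed_rate", "bleed_cost",
                     "therapy_cost_pmpm", "inflation_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def annual_savings_per_stroke(cp: CostParams) -> int:
    """Yearly excess-cost savings per stroke avoided, to the nearest dollar."""
    return round_half_up(12.0 * cp.adjusted_monthly_savings)


def event_rate(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage numerator/denominator rounded to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def inflation_adjust(amount: float, years: int, rate: float) -> float:
    if years < 0:
        raise ValueError("years must be non-negative")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return amount * (1.0 + rate) ** years


def project_events(needing_treatment: int, rates: ClaimsRates,
                   cp: CostParams,
                   therapy_cost_override: float | None = None) -> dict:
    """Forward chain from an untreated-eligible count to events and dollars.

    Counts are rounded half-up at each stage; dollar totals are exact
    products of the rounded counts.
    """
    if needing_treatment < 0:
        raise ValueError("needing_treatment must be non-negative")
    rates.validate()
    cp.validate()
    per_stroke = annual_savings_per_stroke(cp)
    strokes = round_half_up(needing_treatment * rates.stroke_risk)
    deaths = round_half_up(strokes * rates.stroke_death_risk)
    savings = strokes * per_stroke
    bleeds = round_half_up(needing_treatment * cp.bleed_rate)
    bleed_cost = bleeds * cp.bleed_cost
    therapy = (therapy_cost_override if therapy_cost_override is not None
               else needing_treatment * cp.therapy_cost_pmpm * 12.0)
    net = savings - therapy - (bleed_cost if cp.include_bleed_offset else 0.0)
    return {
        "needing_treatment": needing_treatment,
        "strokes_prevented": strokes,
        "deaths_prevented": deaths,
        "per_stroke_annual_savings": per_stroke,
        "cost_savings_usd": float(savings),
        "bleeds_induced": bleeds,
        "bleed_cost_usd": float(bleed_cost),
        "therapy_cost_usd": float(therapy),
        "net_benefit_usd": float(net),
    }


_TABLE4_FIELDS = (
    "nvaf_population", "eligible_population", "needing_treatment",
    "strokes_prevented", "deaths_prevented", "cost_savings_usd",
    "bleeds_induced", "bleed_cost_usd", "therapy_cost_usd",
    "net_benefit_usd",
)


@dataclass
class ExtrapolationResult:
    structured: dict
    combined: dict
    difference: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in _TABLE4_FIELDS:
            rows.append({
                "quantity": name,
                "structured": self.structured.get(name),
                "combined": self.combined.get(name),
                "difference": self.difference.get(name),
            })
        return pd.DataFrame(rows)


def build_table4(rates: ClaimsRates, cp: CostParams,
                 national_pop: int = 316_005_000,
                 structured_needing: int = 3_009_840,
                 combined_needing: int = 3_976_057,
                 nvaf_populations: tuple[int, int] = (4_955_284, 6_545_930),
                 eligible_populations: tuple[int, int] = (4_543_995,
                                                          6_002_707),
                 ) -> ExtrapolationResult:
    """Three-column projection (structured / combined / difference).

    The combined column's therapy cost uses ``cp.national_therapy_cost``
    when set; the structured column always uses the pmpm product.
    """
    if structured_needing > combined_needing:
        raise ValueError("structured_needing must not exceed combined_needing")
    structured = project_events(structured_needing, rates, cp)
    combined = project_events(combined_needing, rates, cp,
                              therapy_cost_override=cp.national_therapy_cost)
    structured["nvaf_population"] = nvaf_populations[0]
    combined["nvaf_population"] = nvaf_populations[1]
    structured["eligible_population"] = eligible_populations[0]
    combined["eligible_population"] = eligible_populations[1]
    difference = {name: combined[name] - structured[name]
                  for name in _TABLE4_FIELDS}
    return ExtrapolationResult(structured, combined, difference)


def load_params(path: str | Path) -> tuple[ClaimsRates, CostParams, dict]:
    """Read a YAML parameter file into (ClaimsRates, CostParams, extras)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    rates_raw = dict(raw.get("claims_rates", {}))
    counts = {k: tuple(v) for k, v in rates_raw.pop("counts", {}).items()}
    rates = ClaimsRates(**rates_raw) if rates_raw or not counts else \
        ClaimsRates(**rates_raw)
    if counts:
        rates.counts = counts
    cp = CostParams(**raw.get("cost_params", {}))
    extras = raw.get("national", {})
    rates.validate()
    cp.validate()
    return rates, cp, extras
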