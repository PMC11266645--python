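"""Bio-economic layer: revenue, cost, profit, and the profitability reference.

Revenue assigns a market price (EUR/kg) to each fish by its individual
weight via the price table; cost is a convex power law in total catch
weight, standing in for landings-proportional expenses (storage, labour,
fuel) that grow faster than linearly. The profitability benchmark is the
mean annual profit over a 2000-2018 hindcast of the fishery, against which
the risk analysis measures profit shortfall.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .synthetic_data import PriceTable, StockBiology

KG_PER_TONNE = 1000.0


@dataclass(frozen=True)
class EconParams:
    price_table: PriceTable
    cost_scale: float  # EUR per tonne^cost_exponent
    cost_exponent: float = 1.2
    reference_profit: float = 0.0  # EUR, profitability benchmark

    def __post_init__(self):
        if self.cost_scale < 0:
            raise InvalidArgumentError("cost_scale must be non-negative")
        if self.cost_exponent < 1:
            raise InvalidArgumentError("cost_exponent must be >= 1")


def revenue(catch_numbers_at_age, biology: StockBiology,
            prices: PriceTable) -> float:
    """EUR earned from a catch: sum_a n_a * w_a(kg) * price(w_a)."""
    n = np.asarray(catch_numbers_at_age, float)
    if n.shape[-1] != biology.n_ages:
        raise InvalidArgumentError("age dimension does not match biology")
    w = biology.weight_at_age
    return float(np.sum(n * w * prices.price_for_weight(w)))


def cost(total_catch_tonnes: float, params: EconParams) -> float:
    """EUR of harvesting cost: cost_scale * catch^cost_exponent."""
    if total_catch_tonnes < 0:
        raise InvalidArgumentError("catch must be non-negative")
    return float(params.cost_scale * total_catch_tonnes ** params.cost_exponent)


def profit(year_record, biology: StockBiology, params: EconParams) -> float:
    """Annual profit = revenue - cost; may be negative."""
    rev = revenue(year_record["catch_numbers_at_age"], biology,
                  params.price_table)
    return rev - cost(year_record["catch"], params)


def calibrate_reference(hindcast: pd.DataFrame, biology: StockBiology,
                        params: EconParams,
                        target_mean_profit: float | None = None) -> EconParams:
    """Set the profitability benchmark from a hindcast of annual catches.

    ``hindcast`` is the long table produced by
    `synthetic_data.generate_hindcast_catches` (year, age, catch_numbers,
    total_catch_tonnes). The reference is the mean annual profit over the
    hindcast years. If ``target_mean_profit`` is given, ``cost_scale`` is
    first rescaled so the hindcast mean profit equals the target exactly
    (the synthetic analogue of anchoring the benchmark at the fishery's
    historical profit level).
    """
    if hindcast is None or len(hindcast) == 0:
        raise InvalidArgumentError("hindcast is empty")
    revenues, catch_pows = [], []
    for _, grp in hindcast.groupby("year"):
        grp = grp.sort_values("age")
        revenues.append(revenue(grp["catch_numbers"].to_numpy(float),
                                biology, params.price_table))
        tot = float(grp["total_catch_tonnes"].iloc[0])
        catch_pows.append(tot ** params.cost_exponent)
    revenues = np.asarray(revenues)
    catch_pows = np.asarray(catch_pows)

    if target_mean_profit is not None:
        mean_rev = revenues.mean()
        if mean_rev < target_mean_profit:
            raise InvalidArgumentError(
                "hindcast revenue too low to reach the target mean profit")
        scale = (mean_rev - target_mean_profit) / catch_pows.mean()
        params = replace(params, cost_scale=float(scale))
    mean_profit = float(np.mean(revenues - params.cost_scale * catch_pows))
    return replace(params, reference_profit=mean_profit)
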