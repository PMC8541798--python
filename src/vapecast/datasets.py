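"""Small bundled reference inputs.

The package ships the published global e-cigarette market revenue trend
(2012-2023, in percent of 2018 revenue, derived from public market-research
revenue forecasts) and the published 2018 headline estimate of worldwide
current e-cigarette users that this methodology produced. Together they let
the forward projection be reproduced without any external download.
"""

from __future__ import annotations

from importlib import resources

from .country_data import MarketIndexSeries, read_market_index

__all__ = ["load_market_index_trend", "WORLD_VAPERS_2018"]

#: Published 2018 estimate of worldwide current e-cigarette users (persons),
#: the sum over ~201 countries of prevalence x adult (15+) population.
WORLD_VAPERS_2018 = 58_107_606


def load_market_index_trend() -> MarketIndexSeries:
    """The bundled market revenue index, percent relative to 2018."""
    path = resources.files("vapecast").joinpath("data/market_revenue_index.csv")
    with path.open("r") as fh:
        return read_market_index(fh, base_year=2018)
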