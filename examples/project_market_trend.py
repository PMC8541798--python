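"""Project the 2018 global user total forward along the market-revenue index.

Loads the bundled 2012-2023 market-revenue trend (percent of 2018 revenue),
calibrates it at 2018, and scales the published 2018 world estimate of
58,107,606 current users to every year, in both projection modes. The index
mode applies the raw revenue ratio; the correlation-damped mode shrinks the
revenue change by the revenue-prevalence correlation (rho = 0.933).
"""

from vapecast import WORLD_VAPERS_2018, load_market_index_trend, projection_table

frame = projection_table(WORLD_VAPERS_2018, load_market_index_trend())

print(f"Base: {WORLD_VAPERS_2018:,} users in 2018 (index = 100%)")
print(f"{'year':>6}{'index %':>9}{'index mode':>16}{'damped mode':>16}")
for _, row in frame.iterrows():
    print(
        f"{int(row['year']):>6}{row['index_pct']:>9.0f}"
        f"{row['projected_index']:>16,.0f}{row['projected_damped']:>16,.0f}"
    )

row_2020 = frame[frame["year"] == 2020].iloc[0]
print()
print(
    f"2020 projection: {row_2020['projected_index'] / 1e6:.2f} m (index mode), "
    f"i.e. about {round(row_2020['projected_index'] / 1e6)} million users; the "
    f"damped mode gives {row_2020['projected_damped'] / 1e6:.2f} m."
)
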