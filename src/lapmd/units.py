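"""Unit-conversion constants used across the pipeline.

All conversions between the inventory scale (ton/yr) and the dispersion scale
(g/s, mg/m3) go through these constants so the chain is auditable in one place.
"""

SECONDS_PER_YEAR = 3.1536e7  # 365 d x 86 400 s
GRAMS_PER_TON = 1.0e6
KG_PER_TON = 1.0e3
MG_PER_G = 1.0e3
M2_PER_HM2 = 1.0e4
SO2_TO_S_MOLECULAR_RATIO = 2.0  # M(SO2)/M(S) = 64/32


def tons_per_year_to_grams_per_second(q_ton_yr: float) -> float:
    return q_ton_yr * GRAMS_PER_TON / SECONDS_PER_YEAR
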