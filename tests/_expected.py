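"""Frozen expected values used as test oracles.

These were transcribed directly from the published tables/narrative and are
kept separate from the package's own data module so the fixture-fidelity
tests compare two independent transcriptions.
"""

# Clinical response/remission percentages: measure -> 8 columns in the order
# (NEG aba, NEG ada, POS aba, POS ada, Q1 aba, Q1 ada, Q4 aba, Q4 ada).
TABLE1_PERCENT = {
    "ACR20": (47.0, 44.4, 69.2, 66.0, 59.5, 60.0, 78.3, 68.6),
    "ACR50": (34.8, 31.5, 52.4, 53.2, 40.5, 45.5, 63.0, 54.9),
    "ACR70": (19.7, 24.1, 37.8, 33.0, 26.2, 32.7, 43.5, 35.3),
    "ACR90": (7.6, 5.6, 18.9, 10.3, 16.7, 10.9, 17.4, 11.8),
    "HAQ_DI": (47.0, 29.6, 62.2, 56.7, 57.1, 54.5, 73.9, 60.8),
    "DAS28_REMISSION": (45.1, 40.5, 55.1, 57.5, 51.5, 56.1, 73.2, 66.7),
    "CDAI_REMISSION": (23.5, 27.0, 38.7, 32.1, 30.3, 31.7, 51.2, 30.8),
    "SDAI_REMISSION": (21.6, 27.0, 36.8, 34.0, 30.3, 36.3, 51.2, 35.9),
}

TABLE1_COLUMNS = (
    ("ACPA_NEG", "abatacept"),
    ("ACPA_NEG", "adalimumab"),
    ("ACPA_POS", "abatacept"),
    ("ACPA_POS", "adalimumab"),
    ("Q1", "abatacept"),
    ("Q1", "adalimumab"),
    ("Q4", "abatacept"),
    ("Q4", "adalimumab"),
)

TABLE1_ARM_N = {
    ("ACPA_NEG", "abatacept"): 66,
    ("ACPA_NEG", "adalimumab"): 54,
    ("ACPA_POS", "abatacept"): 185,
    ("ACPA_POS", "adalimumab"): 203,
    ("Q1", "abatacept"): 42,
    ("Q1", "adalimumab"): 55,
    ("Q4", "abatacept"): 46,
    ("Q4", "adalimumab"): 51,
}

# Biologic pack prices and printed per-mg prices per country:
# country -> drug -> (unit_size_mg, unit_price, printed_price_per_mg)
BIOLOGIC_PRICES = {
    "DE": {"abatacept": (125, 346.16, 2.77), "adalimumab": (40, 871.89, 21.80)},
    "IT": {"abatacept": (125, 230.14, 1.84), "adalimumab": (40, 482.19, 12.05)},
    "ES": {"abatacept": (125, 194.41, 1.56), "adalimumab": (40, 475.58, 11.89)},
    "US": {"abatacept": (125, 800.82, 6.41), "adalimumab": (40, 1601.05, 40.03)},
    "CA": {"abatacept": (125, 366.10, 2.93), "adalimumab": (40, 740.36, 18.51)},
}

# Monitoring unit costs: country -> (radiographic exam, outpatient visit,
# blood-test series).
MONITORING = {
    "DE": (11.06, 62.60, 7.80),
    "IT": (90.38, 20.66, 17.59),
    "ES": (23.08, 100.37, 7.59),
    "US": (1125.60, 88.50, 103.82),
    "CA": (42.60, 75.00, 23.26),
}

# Reported per-1000-patient safety/discontinuation event counts:
# (subgroup, event) -> (abatacept, adalimumab).
REPORTED_COUNTS = {
    ("ACPA_NEG", "SAE"): (30, 93),
    ("ACPA_NEG", "LISR"): (30, 130),
    ("ACPA_POS", "discontinuation_safety"): (43, 99),
    ("ACPA_POS", "SAE"): (43, 54),
    ("ACPA_POS", "LISR"): (49, 94),
    ("Q1", "discontinuation_safety"): (48, 109),
    ("Q1", "SAE"): (24, 73),
    ("Q1", "LISR"): (48, 127),
    ("Q4", "LISR"): (22, 78),
    ("Q4", "SAE"): (22, 20),
}

# Direction of the deterministic incremental health gain (abatacept minus
# adalimumab) per the results narrative: +1 higher for abatacept, -1 lower.
GAIN_SIGNS = {
    "ACPA_NEG": {
        "ACR20": +1, "ACR50": +1, "ACR70": -1, "ACR90": +1, "HAQ_DI": +1,
        "DAS28_REMISSION": +1,
    },
    "ACPA_POS": {
        "ACR20": +1, "ACR50": -1, "ACR70": +1, "ACR90": +1, "HAQ_DI": +1,
        "DAS28_REMISSION": -1, "CDAI_REMISSION": +1, "SDAI_REMISSION": +1,
    },
    "Q1": {
        "ACR90": +1, "HAQ_DI": +1,
        "DAS28_REMISSION": -1, "CDAI_REMISSION": -1, "SDAI_REMISSION": -1,
    },
    "Q4": {
        "ACR20": +1, "ACR50": +1, "ACR70": +1, "ACR90": +1, "HAQ_DI": +1,
        "DAS28_REMISSION": +1, "CDAI_REMISSION": +1, "SDAI_REMISSION": +1,
    },
}
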