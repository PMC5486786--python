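"""Bundled input data.

Two kinds of values live here and are kept strictly apart:

* Published clinical response/remission percentages, trial arm sizes, drug pack
  prices and monitoring unit costs for Germany (DE), Italy (IT), Spain (ES),
  the United States (US) and Canada (CA), as printed in the source cost tables.
* SYNTHETIC adverse-event management tariffs.  The published analysis costed AE
  management from national DRG tariff databases that are not reproduced in any
  printed table; the values below are package-supplied stand-ins on a realistic
  scale (GP visit / day case for frequent AEs and injection-site reactions,
  hospitalization for serious events), clearly labelled synthetic.
"""

from __future__ import annotations

# --- clinical inputs -------------------------------------------------------
# Percentages of patients responding / in remission per outcome, by ACPA
# subgroup and arm.  Column order: (subgroup, arm) pairs below.

CLINICAL_COLUMNS = [
    ("ACPA_NEG", "abatacept"),
    ("ACPA_NEG", "adalimumab"),
    ("ACPA_POS", "abatacept"),
    ("ACPA_POS", "adalimumab"),
    ("Q1", "abatacept"),
    ("Q1", "adalimumab"),
    ("Q4", "abatacept"),
    ("Q4", "adalimumab"),
]

CLINICAL_PERCENT = {
    "ACR20": [47.0, 44.4, 69.2, 66.0, 59.5, 60.0, 78.3, 68.6],
    "ACR50": [34.8, 31.5, 52.4, 53.2, 40.5, 45.5, 63.0, 54.9],
    "ACR70": [19.7, 24.1, 37.8, 33.0, 26.2, 32.7, 43.5, 35.3],
    "ACR90": [7.6, 5.6, 18.9, 10.3, 16.7, 10.9, 17.4, 11.8],
    "HAQ_DI": [47.0, 29.6, 62.2, 56.7, 57.1, 54.5, 73.9, 60.8],
    "DAS28_REMISSION": [45.1, 40.5, 55.1, 57.5, 51.5, 56.1, 73.2, 66.7],
    "CDAI_REMISSION": [23.5, 27.0, 38.7, 32.1, 30.3, 31.7, 51.2, 30.8],
    "SDAI_REMISSION": [21.6, 27.0, 36.8, 34.0, 30.3, 36.3, 51.2, 35.9],
}

ARM_N = {
    ("ACPA_NEG", "abatacept"): 66,
    ("ACPA_NEG", "adalimumab"): 54,
    ("ACPA_POS", "abatacept"): 185,
    ("ACPA_POS", "adalimumab"): 203,
    ("Q1", "abatacept"): 42,
    ("Q1", "adalimumab"): 55,
    ("Q4", "abatacept"): 46,
    ("Q4", "adalimumab"): 51,
}

# --- drug costs ------------------------------------------------------------
# name -> (route, unit_size_mg, unit_price, printed_price_per_mg)
# unit_size_mg is the total milligrams in one priced unit (pack or syringe).
# printed_price_per_mg is kept for audit; the two biologics reproduce it at
# 2-decimal half-up rounding, some concomitant rows in the source table do not.

DRUG_COSTS = {
    "DE": {
        "abatacept": ("subcutaneous", 125.0, 346.16, 2.77),
        "adalimumab": ("subcutaneous", 40.0, 871.89, 21.80),
        "methotrexate": ("oral", 2.5, 1.31, 0.52),
        "hydroxychloroquine": ("oral", 200.0, 0.31, 0.0015),
        "sulfasalazine": ("oral", 500.0, 0.26, 0.00052),
        "prednisone": ("oral", 5.0, 0.16, 0.03282),
        "cyclosporine": ("oral", 100.0, 3.98, 0.03983),
        "nsaid": ("oral", 400.0, 0.16, 0.00041),
    },
    "IT": {
        "abatacept": ("subcutaneous", 125.0, 230.14, 1.84),
        "adalimumab": ("subcutaneous", 40.0, 482.19, 12.05),
        "methotrexate": ("subcutaneous", 50.0, 22.15, 0.443),
        "hydroxychloroquine": ("oral", 20000.0, 3.68, 0.00018),
        "sulfasalazine": ("oral", 50000.0, 9.03, 0.00018),
        "prednisone": ("oral", 800.0, 15.51, 0.01939),
        "cyclosporine": ("oral", 3000.0, 74.51, 0.02484),
        "nsaid": ("oral", 3000.0, 3.21, 0.00107),
    },
    "ES": {
        "abatacept": ("subcutaneous", 125.0, 194.41, 1.56),
        "adalimumab": ("subcutaneous", 40.0, 475.58, 11.89),
        "methotrexate": ("subcutaneous", 25.0, 15.24, 0.61),
        "hydroxychloroquine": ("oral", 6000.0, 6.78, 0.00113),
        "sulfasalazine": ("oral", 25000.0, 2.75, 0.00011),
        "prednisone": ("oral", 300.0, 1.48, 0.00493),
        "nsaid": ("oral", 24000.0, 1.26, 0.00005),
    },
    "US": {
        "abatacept": ("subcutaneous", 125.0, 800.82, 6.41),
        "adalimumab": ("subcutaneous", 40.0, 1601.05, 40.03),
        "methotrexate": ("oral", 50.0, 95.82, 1.92),
        "hydroxychloroquine": ("oral", 20000.0, 638.00, 0.0319),
        "sulfasalazine": ("oral", 50000.0, 96.14, 0.00192),
        "prednisone": ("oral", 800.0, 211.36, 0.2642),
        "cyclosporine": ("oral", 3000.0, 204.51, 0.06817),
    },
    "CA": {
        "abatacept": ("subcutaneous", 125.0, 366.10, 2.93),
        "adalimumab": ("subcutaneous", 40.0, 740.36, 18.51),
        "methotrexate": ("oral", 2.5, 0.63, 0.25),
        "hydroxychloroquine": ("oral", 200.0, 0.26, 0.0013),
        "sulfasalazine": ("oral", 500.0, 0.18, 0.00036),
        "prednisone": ("oral", 5.0, 0.02, 0.004),
        "cyclosporine": ("oral", 100.0, 3.88, 0.0388),
        "nsaid": ("oral", 200.0, 0.05, 0.00025),
    },
}

CURRENCY = {"DE": "EUR", "IT": "EUR", "ES": "EUR", "US": "USD", "CA": "CAD"}
PRICE_YEAR = {"DE": 2016, "IT": 2015, "ES": 2016, "US": 2015, "CA": 2015}

# Per-item monitoring unit costs: radiographic exam (per session), outpatient
# visit (per visit), routine blood exams (per series of tests).
MONITORING_COSTS = {
    "DE": {"radiographic_exam": 11.06, "outpatient_visit": 62.60, "blood_test_series": 7.80},
    "IT": {"radiographic_exam": 90.38, "outpatient_visit": 20.66, "blood_test_series": 17.59},
    "ES": {"radiographic_exam": 23.08, "outpatient_visit": 100.37, "blood_test_series": 7.59},
    "US": {"radiographic_exam": 1125.60, "outpatient_visit": 88.50, "blood_test_series": 103.82},
    "CA": {"radiographic_exam": 42.60, "outpatient_visit": 75.00, "blood_test_series": 23.26},
}

# --- SYNTHETIC adverse-event management tariffs ----------------------------
# Per-episode management costs by event class.  These are NOT published
# values: frequent AEs and LISRs are costed at a GP-visit/day-case scale,
# serious events, malignancies and autoimmune disorders at a hospitalization
# (DRG) scale, with a per-country level shift reflecting the currencies and
# overall price levels of the five systems.

_AE_BASE_CLASS = {"frequent_AE": 35.0, "LISR": 35.0, "SAE": 3500.0,
                  "malignancy": 8000.0, "autoimmune": 4500.0}
_AE_BASE_ITEMS = {
    "upper_respiratory_tract_infection": 35.0,
    "nasopharyngitis": 25.0,
    "headache": 20.0,
    "nausea": 30.0,
    "urinary_tract_infection": 40.0,
}
_AE_COUNTRY_FACTOR = {"DE": 1.0, "IT": 0.9, "ES": 0.85, "US": 3.0, "CA": 1.4}

AE_CLASS_COSTS = {
    c: {k: round(v * f, 2) for k, v in _AE_BASE_CLASS.items()}
    for c, f in _AE_COUNTRY_FACTOR.items()
}
FREQUENT_AE_COSTS = {
    c: {k: round(v * f, 2) for k, v in _AE_BASE_ITEMS.items()}
    for c, f in _AE_COUNTRY_FACTOR.items()
}
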