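"""Published reference dataset: 13 model compounds screened for melanin binding.

These tables hold the fitted binding parameters (MST Kd with 68%
confidence, Sips Kd/Bmax/n with standard errors, target capacities) and
the reported unbound fractions and classifications for a benchmark panel
of ophthalmically relevant drugs. They drive the end-to-end reproduction
pipeline and serve as fixtures: all downstream numbers (unbound-fraction
tables, rank correlation, regression slope, class limits) can be
recomputed from them.

Units: Kd µM, Bmax nmol/mg, target capacity µM, unbound fractions percent.
MST assay melanin: 0.5 mg/mL = 12.5 µM at 40 kDa. Traditional assay
melanin: 1 mg/mL. ``mode`` marks compounds whose MST Kd came from the
initial-fluorescence readout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import SipsParameters

__all__ = [
    "binding_parameters",
    "reported_classification",
    "sips_parameters",
    "MST_TARGET_CONC",
    "SIPS_ASSAY_MELANIN",
    "INVIVO_MELANIN",
    "LITERATURE_FU_MELANIN",
]

MST_TARGET_CONC = 12.5  # µM melanin in the MST assay
MST_ASSAY_MELANIN = 0.5  # mg/mL, same assay in mass units
SIPS_ASSAY_MELANIN = 1.0  # mg/mL in the traditional assay
INVIVO_MELANIN = 34.8  # mg/mL, human RPE-choroid average
LITERATURE_FU_MELANIN = 3.6  # mg/mL, assay behind the literature fu values

_BINDING = [
    # compound, kd_mst, kd_mst_ci68, mst_mode, kd_sips, se_kd, bmax, se_bmax,
    # n, se_n, target_capacity, se_capacity
    ("terazosin",    29.0,   28.0, "initial_fluorescence", 46.0, 16.0, 112.0, 13.0, 0.64,  0.018, 56.0, 6.5),
    ("penicillin_g",  3.2,    7.6, "mst",                  None, None, None,  None, None,  None,  None, None),
    ("chloroquine",   0.8,    7.7, "mst",                  76.0, 23.0, 380.0, 40.0, 0.605, 0.012, 190.0, 20.0),
    ("levofloxacin", 46.5,   40.1, "mst",                 157.0, 56.0,  72.0, 11.0, 0.73,  0.02,  36.0, 5.5),
    ("papaverine",   28.0,   23.0, "initial_fluorescence", 66.0, 18.0,  66.0,  8.0, 0.715, 0.015, 33.0, 4.0),
    ("propranolol",  80.0,   92.0, "initial_fluorescence", 163.0, 100.0, 176.0, 60.0, 0.89, 0.05, 88.0, 30.0),
    ("nadolol",     200.0,   33.0, "initial_fluorescence", 340.0, 200.0, 68.0, 24.0, 0.94, 0.05, 34.0, 12.0),
    ("timolol",     260.0,  128.0, "mst",                 120.0, 30.0,  39.0,  6.0, 0.95,  0.03, 19.5, 3.0),
    ("quinidine",   214.0,   29.0, "initial_fluorescence", None, None, None,  None, None,  None,  None, None),
    ("atropine",    912.0, 1318.0, "mst",                  None, None, None,  None, None,  None,  None, None),
    ("methotrexate", 3500.0, 13000.0, "initial_fluorescence", None, None, None, None, None, None, None, None),
    ("diclofenac",   None,   None, "mst",                  None, None, None,  None, None,  None,  None, None),
]

# Reported classification and unbound fractions. fu_vitro is at 1 mg/mL
# melanin; fu_vivo at 34.8 mg/mL. method "sips" = mass-balance prediction
# from Sips parameters at 1 µM total; "dilution" = rescaling of a
# literature unbound fraction (measured near 0.3 µM total).
_CLASSIFICATION = [
    # compound, class_traditional, class_mst, fu_vitro_pct, fu_vivo_pct, method
    ("chloroquine",  "extreme",      "extreme",      0.41, 0.0012, "sips"),
    ("terazosin",    "extreme",      "high",         2.9,  0.012,  "sips"),
    ("levofloxacin", "high",         "high",         28.0, 0.33,   "sips"),
    ("propranolol",  "high",         "intermediate", 32.0, 0.9,    "sips"),
    ("papaverine",   "high",         "high",         15.0, 0.13,   "sips"),
    ("nadolol",      "intermediate", "intermediate", 78.0, 8.0,    "sips"),
    ("timolol",      "intermediate", "intermediate", 71.0, 5.7,    "sips"),
    ("atropine",     "intermediate", "low",          59.0, 3.9,    "dilution"),
    ("methotrexate", "low",          "low",          98.0, 54.0,   "dilution"),
    ("quinidine",    "high",         "intermediate", 16.0, 0.55,   "dilution"),
    ("penicillin_g", "high",         "extreme",      9.2,  0.29,   "dilution"),
]


def binding_parameters() -> pd.DataFrame:
    """Fitted binding parameters for the 13-compound panel (NaN = not determined)."""
    df = pd.DataFrame(
        _BINDING,
        columns=[
            "compound", "kd_mst", "kd_mst_ci68", "mst_mode",
            "kd_sips", "se_kd_sips", "bmax", "se_bmax", "n", "se_n",
            "target_capacity_sips", "se_target_capacity",
        ],
    )
    return df.replace({None: np.nan})


def reported_classification() -> pd.DataFrame:
    """Reported binding classes and unbound fractions for the 11 classified compounds."""
    return pd.DataFrame(
        _CLASSIFICATION,
        columns=["compound", "class_traditional", "class_mst",
                 "fu_vitro_pct", "fu_vivo_pct", "method"],
    )


def sips_parameters(compound: str) -> SipsParameters | None:
    """Sips parameters for one compound, or None where not determined."""
    df = binding_parameters().set_index("compound")
    if compound not in df.index:
        raise KeyError(f"unknown compound: {compound}")
    row = df.loc[compound]
    if pd.isna(row["kd_sips"]):
        return None
    return SipsParameters(
        kd=float(row["kd_sips"]), bmax=float(row["bmax"]), n=float(row["n"]),
        se_kd=float(row["se_kd_sips"]), se_bmax=float(row["se_bmax"]),
        se_n=float(row["se_n"]),
    )
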