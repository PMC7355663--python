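"""Unbound-fraction prediction and binding classification.

Binding parameters measured in vitro are translated to the unbound drug
fraction at any melanin concentration — in particular the human
RPE-choroid, whose melanin content (~34.8 mg/mL) far exceeds the 0.5-5
mg/mL used in vitro, so even weak in vitro binders can be largely bound in
vivo. Two routes exist:

* **Sips mass balance**: with fitted isotherm parameters, solve
  ``total = L + melanin_conc * B(L)`` for the free concentration L.
* **Dilution scaling**: with only a measured unbound fraction at one
  melanin concentration, rescale it by the melanin ratio D:
  ``fu' = 100 / (D * (100/fu - 1) + 1)``,
  which is exact for linear (non-saturable) binding.

Compounds are then binned into four melanin-binder tiers (low /
intermediate / high / extreme) by MST Kd or, equivalently, by predicted in
vivo unbound fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from scipy.optimize import brentq

from .models import SipsParameters, sips_bound

__all__ = [
    "BindingClass",
    "BindingPrediction",
    "KD_CLASS_LIMITS",
    "FU_CLASS_LIMITS",
    "DEFAULT_INVIVO_MELANIN",
    "DEFAULT_CASSETTE_FACTOR",
    "fraction_unbound_sips",
    "dilution_scale",
    "cassette_correction",
    "classify_kd",
    "classify_fu",
]

# Kd (MST, µM) cut-offs between extreme/high/intermediate/low binders;
# equivalent in vivo unbound-fraction cut-offs in percent.
KD_CLASS_LIMITS = (6.5, 65.0, 650.0)
FU_CLASS_LIMITS = (0.1, 1.0, 10.0)

DEFAULT_INVIVO_MELANIN = 34.8  # mg/mL, human RPE-choroid average
DEFAULT_TOTAL_CONC_SIPS = 1.0  # µM, assumed total tissue concentration
DEFAULT_TOTAL_CONC_DILUTION = 0.3  # µM, assay concentration of literature fu data
DEFAULT_CASSETTE_FACTOR = 2.1


class BindingClass(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"
    EXTREME = "extreme"


@dataclass(frozen=True)
class BindingPrediction:
    """Unbound fraction of one compound at stated assay conditions."""

    compound: str
    melanin_conc: float  # mg/mL
    total_conc: float  # µM
    fraction_unbound: float  # percent
    method: str  # "sips_mass_balance" or "dilution_equation"
    binding_class: BindingClass


def fraction_unbound_sips(
    params: SipsParameters, melanin_conc: float, total_conc: float
) -> float:
    """Percent unbound from the Sips isotherm by mass balance.

    Solves ``total = L + melanin_conc * Bmax L^n / (Kd^n + L^n)`` for the
    free concentration L by bracketed root-finding; the left side is
    strictly increasing in L, so the root on (0, total] is unique.

    Parameters
    ----------
    params : SipsParameters
    melanin_conc : float
        Melanin concentration, mg/mL (0 means no binder: returns 100).
    total_conc : float
        Total drug concentration, µM.
    """
    if melanin_conc < 0:
        raise ValueError("melanin_conc must be nonnegative")
    if total_conc <= 0:
        raise ValueError("total_conc must be positive")
    if melanin_conc == 0:
        return 100.0

    def balance(L: float) -> float:
        return L + melanin_conc * sips_bound(L, params) - total_conc

    lo = 1e-12 * total_conc
    if balance(lo) > 0:  # essentially nothing bound even at the bracket floor
        return 100.0 * lo / total_conc
    free = brentq(balance, lo, total_conc, rtol=1e-12, maxiter=500)
    return 100.0 * free / total_conc


def dilution_scale(fu_in_vitro: float, dilution_factor: float) -> float:
    """Rescale an unbound fraction to a D-fold different melanin level.

    ``fu' = 100 / (D (100/fu - 1) + 1)``; exact when binding is linear in
    drug concentration. D > 1 means more melanin, hence a lower unbound
    fraction. D = in vivo / in vitro melanin concentration for in vivo
    extrapolation; a fractional D rescales toward less melanin, and the
    transform is its own inverse under D -> 1/D.
    """
    if not 0 < fu_in_vitro <= 100:
        raise ValueError("fu_in_vitro must be in (0, 100]")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    return 100.0 / (dilution_factor * (100.0 / fu_in_vitro - 1.0) + 1.0)


def cassette_correction(fu_cassette: float, factor: float = DEFAULT_CASSETTE_FACTOR) -> float:
    """Correct a cassette-assay unbound fraction to single-compound conditions.

    Cassette dosing (many compounds competing in one incubation)
    underestimates binding; dividing the observed unbound fraction by an
    empirical factor (2.1, calibrated on high binders measured both ways)
    restores the single-compound estimate.
    """
    if fu_cassette <= 0:
        raise ValueError("fu_cassette must be positive")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return fu_cassette / factor


def _classify(value: float, limits: tuple[float, float, float],
              ascending_strength: bool) -> BindingClass:
    """Interval lookup; the boundary value joins the weaker-binding class."""
    lo, mid, hi = limits
    tiers = [BindingClass.EXTREME, BindingClass.HIGH, BindingClass.INTERMEDIATE,
             BindingClass.LOW]
    if ascending_strength:  # larger value = weaker binding (Kd, fu)
        if value < lo:
            return tiers[0]
        if value < mid:
            return tiers[1]
        if value < hi:
            return tiers[2]
        return tiers[3]
    raise AssertionError("unreachable")


def classify_kd(kd_mst: float) -> BindingClass:
    """Binding tier from an MST dissociation constant (µM).

    Cut-offs 6.5 / 65 / 650 µM; half-open intervals with each boundary
    assigned to the weaker-binding side (Kd = 65 → intermediate).
    """
    if kd_mst <= 0:
        raise ValueError("kd_mst must be positive")
    return _classify(kd_mst, KD_CLASS_LIMITS, ascending_strength=True)


def classify_fu(fu_in_vivo: float) -> BindingClass:
    """Binding tier from a predicted in vivo unbound fraction (percent).

    Cut-offs 0.1 / 1 / 10%; same half-open boundary convention as
    :func:`classify_kd`.
    """
    if not 0 <= fu_in_vivo <= 100:
        raise ValueError("fu_in_vivo must be in [0, 100]")
    return _classify(fu_in_vivo, FU_CLASS_LIMITS, ascending_strength=True)
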