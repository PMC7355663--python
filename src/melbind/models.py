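"""Closed-form binding models shared by every analysis stage.

Two equilibrium models describe drug-melanin binding here:

* the single-site **ligand-depletion** model, in which a fixed molar
  concentration of target (melanin particles) measurably depletes free
  ligand, so occupancy is the root of a quadratic rather than the simple
  hyperbola ``c / (c + Kd)``; and
* the **Sips (Langmuir-Freundlich) isotherm**, a surface-binding model with
  a heterogeneity index ``n`` that interpolates between a broad
  distribution of binding energies (``n < 1``) and the homogeneous
  Langmuir limit (``n = 1``).

All concentrations are micromolar internally; unit conversion happens at
I/O boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DepletionModelParams",
    "SipsParameters",
    "depletion_fraction_bound",
    "sips_bound",
    "melanin_molar_conc",
]


@dataclass(frozen=True)
class DepletionModelParams:
    """Parameters of the single-site ligand-depletion dose-response model.

    Attributes
    ----------
    unbound_signal : float
        Response (normalized fluorescence or raw counts, arbitrary units)
        of target with no ligand bound.
    bound_signal : float
        Response of the fully ligand-saturated target.
    kd : float
        Dissociation constant, µM.
    target_conc : float
        Molar concentration of the binding target in the assay, µM.
    """

    unbound_signal: float
    bound_signal: float
    kd: float
    target_conc: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if self.target_conc <= 0:
            raise ValueError(
                f"target_conc must be positive, got {self.target_conc}"
            )


@dataclass(frozen=True)
class SipsParameters:
    """Sips isotherm parameters with optional standard errors.

    Attributes
    ----------
    kd : float
        Dissociation constant, µM.
    bmax : float
        Maximum binding capacity, nmol per mg melanin.
    n : float
        Heterogeneity index (dimensionless); ``n = 1`` is the Langmuir
        isotherm, ``n < 1`` indicates a spread of binding energies.
    se_kd, se_bmax, se_n : float or None
        Asymptotic standard errors from the fit, same units as the
        corresponding parameter.
    """

    kd: float
    bmax: float
    n: float
    se_kd: float | None = None
    se_bmax: float | None = None
    se_n: float | None = None

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if self.bmax <= 0:
            raise ValueError(f"bmax must be positive, got {self.bmax}")
        if not 0 < self.n <= 1.5:
            raise ValueError(f"n must be in (0, 1.5], got {self.n}")


def depletion_fraction_bound(
    ligand_conc: float | np.ndarray, params: DepletionModelParams
) -> float | np.ndarray:
    """Response of the depletion model at total ligand concentration(s).

    Solves the single-site mass balance exactly: with total ligand ``c``,
    total target ``ct`` and dissociation constant ``Kd``, the occupied
    fraction of target is

    ``f = [(c + ct + Kd) - sqrt((c + ct + Kd)^2 - 4 c ct)] / (2 ct)``

    and the response interpolates linearly between the unbound and bound
    signals with ``f``.

    Parameters
    ----------
    ligand_conc : float or ndarray
        Total ligand concentration(s), µM; must be nonnegative.
    params : DepletionModelParams

    Returns
    -------
    float or ndarray
        Model response, between ``unbound_signal`` and ``bound_signal``.
    """
    c = np.asarray(ligand_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("ligand_conc must be nonnegative")
    ct = params.target_conc
    s = c + ct + params.kd
    disc = s * s - 4.0 * c * ct
    if np.any(disc < 0):  # analytically impossible; numerical guard
        warnings.warn(
            "negative discriminant in depletion model clamped to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        disc = np.clip(disc, 0.0, None)
    frac = (s - np.sqrt(disc)) / (2.0 * ct)
    out = params.unbound_signal + (params.bound_signal - params.unbound_signal) * frac
    return out if out.ndim else float(out)


def sips_bound(
    free_conc: float | np.ndarray, params: SipsParameters
) -> float | np.ndarray:
    """Amount bound per mg melanin at free ligand concentration(s).

    ``B(L) = Bmax * L^n / (Kd^n + L^n)`` with ``B(0) = 0`` special-cased so
    the ``0^n`` indeterminacy never arises.

    Parameters
    ----------
    free_conc : float or ndarray
        Free ligand concentration(s) L, µM; must be nonnegative.
    params : SipsParameters

    Returns
    -------
    float or ndarray
        Bound amount, nmol/mg, in ``[0, Bmax)``.
    """
    L = np.asarray(free_conc, dtype=float)
    if np.any(L < 0):
        raise ValueError("free_conc must be nonnegative")
    Ln = np.zeros_like(L)
    pos = L > 0
    Ln[pos] = np.power(L[pos], params.n)
    out = params.bmax * Ln / (params.kd**params.n + Ln)
    return out if out.ndim else float(out)


def melanin_molar_conc(mass_conc: float, mw_kda: float = 40.0) -> float:
    """Convert a melanin mass concentration to a molar one.

    Parameters
    ----------
    mass_conc : float
        Melanin concentration, mg/mL.
    mw_kda : float
        Particle molecular weight, kDa. Defaults to 40 kDa, the estimate
        for ~4.5 nm synthetic melanin nanoparticles, under which the
        standard 0.5 mg/mL assay concentration is 12.5 µM.

    Returns
    -------
    float
        Molar concentration, µM.
    """
    if mass_conc < 0:
        raise ValueError("mass_conc must be nonnegative")
    if mw_kda <= 0:
        raise ValueError("mw_kda must be positive")
    # mg/mL = g/L; dividing by kg/mol gives mol/m^3 = mM, i.e. 1000 µM
    return mass_conc / mw_kda * 1000.0
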