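"""Cross-method comparison statistics.

MST reports a single-site Kd while the traditional assay reports a Sips
isotherm, so raw dissociation constants are not directly comparable. The
comparable quantity is the ratio of target capacity to affinity:

* MST: (molar melanin concentration in the assay) / Kd,
* Sips: (Bmax x melanin mass concentration) / Kd^n,

both dimensionless measures of how much of the dose the melanin can soak
up. Agreement between methods is summarized by the Spearman rank
correlation of these ratios, and the relation between MST Kd and predicted
in vivo unbound fraction by a through-origin least-squares regression whose
slope converts unbound-fraction class limits into Kd class limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

from .models import SipsParameters

__all__ = [
    "MethodComparison",
    "capacity_ratio_mst",
    "capacity_ratio_sips",
    "spearman_rho",
    "origin_regression",
    "derive_class_limits",
]

DEFAULT_MST_TARGET_CONC = 12.5  # µM molar melanin in the MST assay
DEFAULT_SIPS_MELANIN = 0.5  # mg/mL, matching the MST assay's mass concentration
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class MethodComparison:
    compounds: tuple[str, ...]
    mst_ratio: np.ndarray
    sips_ratio: np.ndarray
    spearman_rho: float
    spearman_p: float


def capacity_ratio_mst(kd: float, melanin_target_conc: float = DEFAULT_MST_TARGET_CONC) -> float:
    """Target-capacity-to-Kd ratio for the MST assay (dimensionless)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    return melanin_target_conc / kd


def capacity_ratio_sips(
    params: SipsParameters, melanin_conc: float = DEFAULT_SIPS_MELANIN
) -> float:
    """Target-capacity-to-Kd^n ratio for the Sips isotherm (dimensionless)."""
    return params.bmax * melanin_conc / params.kd**params.n


def _exact_spearman_p(rho: float, ranks_x: np.ndarray, ranks_y: np.ndarray) -> float:
    """Two-sided permutation p-value over all orderings of one rank vector."""
    n = ranks_x.size
    perms = np.array(list(permutations(range(n))))
    ry = ranks_y[perms]  # (n!, n)
    rx = ranks_x
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, two-sided p). The p-value is an exact permutation
    probability for n <= 9 and the usual t-approximation above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p_t = sps.spearmanr(x, y)
    rho = float(rho)
    if x.size <= EXACT_PERMUTATION_MAX_N:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        return rho, _exact_spearman_p(rho, rx, ry)
    return rho, float(p_t)


def origin_regression(x, y) -> float:
    """Least-squares slope of y on x with the intercept fixed at the origin.

    slope = sum(x*y) / sum(x^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("need two equal-length vectors")
    sxx = float((x**2).sum())
    if sxx == 0:
        raise ValueError("x is degenerate (all zero)")
    return float((x * y).sum() / sxx)


def derive_class_limits(
    slope: float, fu_breaks=(10.0, 1.0, 0.1)
) -> tuple[float, ...]:
    """Convert unbound-fraction class breaks (percent) to Kd breaks (µM).

    A through-origin slope of ~65 µM per percent turns the 10 / 1 / 0.1%
    unbound-fraction tiers into 650 / 65 / 6.5 µM Kd tiers.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    return tuple(slope * float(b) for b in fu_breaks)


def compare_methods(
    compounds, kd_mst, sips_params, melanin_conc: float = DEFAULT_SIPS_MELANIN,
    mst_target_conc: float = DEFAULT_MST_TARGET_CONC,
) -> MethodComparison:
    """Capacity-ratio comparison over compounds measured by both methods."""
    names, xr, yr = [], [], []
    for name, kd, params in zip(compounds, kd_mst, sips_params):
        if kd is None or params is None:
            continue
        names.append(name)
        xr.append(capacity_ratio_mst(kd, mst_target_conc))
        yr.append(capacity_ratio_sips(params, melanin_conc))
    rho, p = spearman_rho(xr, yr)
    return MethodComparison(
        compounds=tuple(names),
        mst_ratio=np.asarray(xr),
        sips_ratio=np.asarray(yr),
        spearman_rho=rho,
        spearman_p=p,
    )
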