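"""Traditional equilibrium melanin-binding assay analysis.

In the traditional assay the drug is incubated with a melanin suspension
(1 mg/mL here), the suspension is centrifuged, and the supernatant — the
unbound drug — is quantified. Paired melanin-free controls give the total
concentration, so the bound amount per mg melanin follows by mass balance:

``B = (total - free) / melanin_conc``  (µM / (mg/mL) = nmol/mg).

(B, L) pairs across the dilution series are then fitted with the Sips
isotherm, giving Kd, Bmax and the heterogeneity index n with standard
errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .models import SipsParameters, sips_bound

__all__ = [
    "EquilibriumDataset",
    "SipsFitResult",
    "bound_amount",
    "fit_sips",
    "sips_target_capacity",
    "read_equilibrium_csv",
]

N_BOUNDS = (1e-6, 1.5)
BMAX_BOUND = 1e6  # nmol/mg; estimates pinned here mean no measurable saturation
KD_BOUND = 1e9  # µM


@dataclass(frozen=True)
class EquilibriumDataset:
    """Paired control/melanin supernatant measurements of one compound.

    ``total_conc`` comes from the melanin-free control supernatant,
    ``free_conc`` from the melanin-incubated supernatant, per sample.
    """

    total_conc: np.ndarray
    free_conc: np.ndarray
    melanin_conc: float
    replicate: np.ndarray | None = None
    nominal_conc: np.ndarray | None = None

    def __post_init__(self) -> None:
        tot = np.asarray(self.total_conc, dtype=float)
        free = np.asarray(self.free_conc, dtype=float)
        object.__setattr__(self, "total_conc", tot)
        object.__setattr__(self, "free_conc", free)
        if tot.shape != free.shape or tot.ndim != 1:
            raise ValueError("total_conc and free_conc must be matching 1-D vectors")
        if self.melanin_conc <= 0:
            raise ValueError("melanin_conc must be positive")
        if np.any(free < 0):
            raise ValueError("free_conc must be nonnegative")
        for name in ("replicate", "nominal_conc"):
            labels = getattr(self, name)
            if labels is not None:
                arr = np.asarray(labels)
                if arr.shape != tot.shape:
                    raise ValueError(f"{name} labels must match sample count")
                object.__setattr__(self, name, arr)

    @property
    def bound(self) -> np.ndarray:
        return bound_amount(self.total_conc, self.free_conc, self.melanin_conc)


@dataclass(frozen=True)
class SipsFitResult:
    """Sips fit outcome. ``params`` is None for a no-binding verdict."""

    params: SipsParameters | None
    converged: bool
    no_binding: bool
    n_negative_bound: int = 0
    message: str = ""


def bound_amount(
    total: float | np.ndarray, free: float | np.ndarray, melanin_conc: float
) -> float | np.ndarray:
    """Bound drug per mg melanin from the supernatant mass balance.

    Negative values (measurement noise at weak binding) are returned as-is;
    the fit handles them by weighting rather than truncation, since
    clipping at zero would bias Bmax upward.
    """
    if melanin_conc <= 0:
        raise ValueError("melanin_conc must be positive")
    out = (np.asarray(total, dtype=float) - np.asarray(free, dtype=float)) / melanin_conc
    return out if out.ndim else float(out)


def _replicate_sigma(data: EquilibriumDataset) -> np.ndarray | None:
    """Per-sample noise from replicate spread of bound amounts, if available."""
    levels = data.nominal_conc if data.nominal_conc is not None else np.round(
        data.total_conc, 6
    )
    df = pd.DataFrame({"level": levels, "bound": data.bound})
    sd = df.groupby("level")["bound"].transform(
        lambda g: g.std(ddof=1) if len(g) > 1 else np.nan
    )
    if sd.isna().all():
        return None
    floor = max(float(np.nanmedian(sd)), 1e-12)
    return np.maximum(sd.fillna(floor).to_numpy(), 0.1 * floor)


def _binding_detectable(B: np.ndarray) -> bool:
    """Bound amounts significantly above zero (one-sample t at ~2 sigma)."""
    if np.all(np.abs(B) < 1e-12):
        return False
    sd = B.std(ddof=1)
    if sd == 0:
        return bool(B.mean() > 0)
    return bool(B.mean() / (sd / np.sqrt(B.size)) > 2.0)


def fit_sips(
    data: EquilibriumDataset, log_domain: bool = False, weighting: str = "cv"
) -> SipsFitResult:
    """Fit the Sips isotherm to (free, bound) pairs.

    Least squares on untransformed bound amounts. ``weighting`` sets the
    error model for the (relative) per-sample noise:

    * ``"cv"`` (default): noise proportional to the control total
      concentration — the constant-CV error model of chromatographic
      quantitation, which the bound-amount difference inherits;
    * ``"replicate"``: empirical replicate standard deviation of bound per
      nominal concentration level;
    * ``"ols"``: unweighted.

    All three keep noisy negative bound amounts in the fit (truncating
    them at zero would bias Bmax upward at weak binding). With
    ``log_domain=True`` the fit minimizes residuals of log(B) instead
    (positive B only).

    A no-binding verdict (rather than parameters) results when bound
    amounts are statistically indistinguishable from zero, when the fit
    does not converge, or when Bmax/Kd escape toward their bounds (no
    measurable saturation).
    """
    L = data.free_conc
    B = data.bound
    if L.size < 4:
        raise ValueError("need at least four (free, bound) pairs")
    if weighting not in ("cv", "replicate", "ols"):
        raise ValueError(f"unknown weighting: {weighting!r}")
    n_neg = int((B < 0).sum())

    def model(l, kd, bmax, n):
        return sips_bound(l, SipsParameters(kd, bmax, n))

    b_pos = B[B > 0]
    if b_pos.size < 3 or not _binding_detectable(B):
        return SipsFitResult(None, converged=False, no_binding=True,
                             n_negative_bound=n_neg,
                             message="bound amounts not distinguishable from zero")
    p0 = [float(np.median(L[L > 0])), float(1.5 * b_pos.max()), 0.8]
    lower = [1e-6, 1e-6, N_BOUNDS[0]]
    upper = [KD_BOUND, BMAX_BOUND, N_BOUNDS[1]]

    if log_domain:
        keep = B > 0
        x, y = L[keep], np.log(B[keep])
        fn = lambda l, kd, bmax, n: np.log(np.maximum(model(l, kd, bmax, n), 1e-300))
        sigma = None
    else:
        x, y = L, B
        fn = model
        if weighting == "cv":
            sigma = np.maximum(data.total_conc, 1e-12)
        elif weighting == "replicate":
            sigma = _replicate_sigma(data)
        else:
            sigma = None

    try:
        popt, pcov = optimize.curve_fit(
            fn, x, y, p0=p0, bounds=(lower, upper), sigma=sigma,
            absolute_sigma=False, maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return SipsFitResult(None, converged=False, no_binding=True,
                             n_negative_bound=n_neg, message=str(exc))

    kd, bmax, n = (float(v) for v in popt)
    if bmax >= 0.5 * BMAX_BOUND or kd >= 0.5 * KD_BOUND:
        return SipsFitResult(None, converged=True, no_binding=True,
                             n_negative_bound=n_neg,
                             message="no saturation within tested range")
    se = np.sqrt(np.diag(pcov))
    params = SipsParameters(
        kd=kd, bmax=bmax, n=min(n, N_BOUNDS[1]),
        se_kd=float(se[0]), se_bmax=float(se[1]), se_n=float(se[2]),
    )
    return SipsFitResult(params, converged=True, no_binding=False,
                         n_negative_bound=n_neg)


def sips_target_capacity(params: SipsParameters, melanin_conc: float) -> float:
    """Total binding capacity as a molar concentration in the assay.

    Bmax (nmol/mg) times melanin concentration (mg/mL) is µM.
    """
    if melanin_conc < 0:
        raise ValueError("melanin_conc must be nonnegative")
    return params.bmax * melanin_conc


def read_equilibrium_csv(path: str | Path, melanin_conc: float) -> EquilibriumDataset:
    """Read paired supernatant measurements.

    Expected columns: ``nominal_conc_uM``, ``control_supernatant_uM``,
    ``melanin_supernatant_uM``; optional ``replicate``.
    """
    df = pd.read_csv(path)
    required = {"control_supernatant_uM", "melanin_supernatant_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"equilibrium CSV missing columns: {sorted(missing)}")
    return EquilibriumDataset(
        total_conc=df["control_supernatant_uM"].to_numpy(),
        free_conc=df["melanin_supernatant_uM"].to_numpy(),
        melanin_conc=melanin_conc,
        replicate=df["replicate"].to_numpy() if "replicate" in df.columns else None,
        nominal_conc=(
            df["nominal_conc_uM"].to_numpy() if "nominal_conc_uM" in df.columns else None
        ),
    )
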