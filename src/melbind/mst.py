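"""Microscale-thermophoresis (MST) trace processing and Kd fitting.

An MST experiment records, per capillary, the fluorescence of the target
(melanin nanoparticles) over ~30 s while an infrared laser heats a spot in
the capillary. The dose-response signal is either

* ``mst`` mode: the normalized fluorescence Fnorm — the ratio of the mean
  fluorescence in a post-heating ("hot") window to the mean in a
  pre-heating ("cold") window — which shifts as ligand binding changes the
  thermophoretic mobility of the particles; or
* ``initial_fluorescence`` mode: the raw pre-heating counts, used when the
  ligand itself quenches or enhances target fluorescence in a
  concentration-dependent way.

Either response is fitted against total ligand concentration with the
ligand-depletion model (the target is at 12.5 µM, far from trace-dilute),
yielding Kd with a 68% confidence half-width from the asymptotic
least-squares covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import DepletionModelParams, depletion_fraction_bound

__all__ = [
    "MstTrace",
    "MstSeries",
    "MstMode",
    "HotRegionResult",
    "MstFitResult",
    "compute_fnorm",
    "cold_region_counts",
    "select_hot_region",
    "detect_mode",
    "fit_kd",
    "fit_kd_points",
    "read_traces_csv",
    "read_dose_response_csv",
]

KD_BOUNDS = (1e-3, 1e6)  # µM; fits pinned at either end are unreliable
DEFAULT_MIN_SNR = 5.0
HOT_WINDOW_WIDTH_S = 1.0
HOT_WINDOW_STEP_S = 0.5
MODE_TREND_RHO = 0.7  # Spearman |rho| cold counts vs log-conc
MODE_TREND_SPAN = 0.10  # relative span of cold counts


class MstMode(str, Enum):
    MST = "mst"
    INITIAL_FLUORESCENCE = "initial_fluorescence"


@dataclass(frozen=True)
class MstTrace:
    """Time-resolved fluorescence of one capillary.

    ``times`` must be strictly increasing and span the laser-on instant;
    ``ligand_conc`` is the total ligand concentration in the capillary (µM,
    0 for the reference capillary).
    """

    times: np.ndarray
    fluorescence: np.ndarray
    ligand_conc: float
    laser_on_time: float
    capillary_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or t.size < 2 or f.shape != t.shape:
            raise ValueError("times and fluorescence must be matching 1-D vectors")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f < 0):
            raise ValueError("fluorescence must be nonnegative")
        if not t[0] <= self.laser_on_time <= t[-1]:
            raise ValueError("laser_on_time must lie within the trace")
        if self.ligand_conc < 0:
            raise ValueError("ligand_conc must be nonnegative")


@dataclass(frozen=True)
class MstSeries:
    """A dilution series of traces sharing one target concentration.

    Replicate capillaries at the same ligand concentration are allowed and
    are pooled in the fit. ``reference_trace``, if present, is the
    ligand-free capillary defining the unbound state.
    """

    traces: tuple[MstTrace, ...]
    target_conc: float
    reference_trace: MstTrace | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "traces", tuple(self.traces))
        if self.target_conc <= 0:
            raise ValueError("target_conc must be positive")
        if not self.traces:
            raise ValueError("series needs at least one trace")
        if any(tr.ligand_conc <= 0 for tr in self.traces):
            raise ValueError("non-reference traces need positive ligand_conc")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([tr.ligand_conc for tr in self.traces])

    @property
    def laser_on_time(self) -> float:
        return self.traces[0].laser_on_time


@dataclass(frozen=True)
class HotRegionResult:
    region: tuple[float, float]
    snr: float
    passed: bool


@dataclass(frozen=True)
class MstFitResult:
    """Outcome of a dose-response Kd fit.

    ``kd`` is None when the fit did not converge. ``flags`` may contain
    ``no_binding`` (flat response), ``kd_at_bound`` (estimate pinned at a
    fit bound), ``wide_ci`` (confidence half-width exceeds the estimate,
    typical when the true Kd lies far above the tested range) and
    ``low_snr`` (no hot window reached the signal-to-noise threshold).
    """

    kd: float | None
    kd_ci68_halfwidth: float | None
    mode: MstMode
    hot_region: tuple[float, float] | None
    cold_region: tuple[float, float] | None
    snr: float | None
    response: pd.DataFrame = field(repr=False, default=None)
    unbound_signal: float | None = None
    bound_signal: float | None = None
    converged: bool = True
    flags: tuple[str, ...] = ()
    message: str = ""

    @property
    def reliable(self) -> bool:
        return self.converged and not self.flags


def _region_mask(times: np.ndarray, region: tuple[float, float]) -> np.ndarray:
    lo, hi = region
    if hi <= lo:
        raise ValueError(f"empty region {region}")
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"region {region} contains no samples")
    return mask


def compute_fnorm(
    trace: MstTrace, cold: tuple[float, float], hot: tuple[float, float]
) -> float:
    """Normalized fluorescence: mean(hot window) / mean(cold window).

    The cold window must lie entirely before the laser-on time and the hot
    window entirely after it.
    """
    if cold[1] > trace.laser_on_time:
        raise ValueError("cold region must end before laser_on_time")
    if hot[0] < trace.laser_on_time:
        raise ValueError("hot region must start after laser_on_time")
    cold_mean = float(trace.fluorescence[_region_mask(trace.times, cold)].mean())
    hot_mean = float(trace.fluorescence[_region_mask(trace.times, hot)].mean())
    if cold_mean <= 0:
        raise ValueError("degenerate trace: nonpositive cold-region mean")
    return hot_mean / cold_mean


def cold_region_counts(trace: MstTrace, cold: tuple[float, float] | None = None) -> float:
    """Mean raw fluorescence counts in the pre-heating window."""
    if cold is None:
        cold = default_cold_region(trace)
    if cold[1] > trace.laser_on_time:
        raise ValueError("cold region must end before laser_on_time")
    return float(trace.fluorescence[_region_mask(trace.times, cold)].mean())


def default_cold_region(trace: MstTrace) -> tuple[float, float]:
    """The full pre-laser span of the trace."""
    return (float(trace.times[0]), float(trace.laser_on_time))


def _detrended_sd(t: np.ndarray, f: np.ndarray) -> float:
    if t.size < 3:
        return float(np.std(f, ddof=1)) if t.size == 2 else 0.0
    resid = f - np.polyval(np.polyfit(t, f, 1), t)
    return float(np.std(resid, ddof=2))


def _window_noise(trace: MstTrace, cold: tuple[float, float], hot: tuple[float, float]) -> float:
    """Noise of one Fnorm estimate from detrended residuals in both windows."""
    hot_mask = _region_mask(trace.times, hot)
    cold_mask = _region_mask(trace.times, cold)
    cold_mean = float(trace.fluorescence[cold_mask].mean())
    fn_hot = trace.fluorescence[hot_mask] / cold_mean
    sd_hot = _detrended_sd(trace.times[hot_mask], fn_hot)
    sd_cold = _detrended_sd(trace.times[cold_mask],
                            trace.fluorescence[cold_mask] / cold_mean)
    fnorm = float(fn_hot.mean())
    # variance of the hot/cold mean ratio, both window means being noisy
    var = sd_hot**2 / hot_mask.sum() + (fnorm * sd_cold) ** 2 / cold_mask.sum()
    return float(np.sqrt(var))


def select_hot_region(
    series: MstSeries,
    min_snr: float = DEFAULT_MIN_SNR,
    window_width: float = HOT_WINDOW_WIDTH_S,
    window_step: float = HOT_WINDOW_STEP_S,
) -> HotRegionResult:
    """Scan post-laser windows and pick one with adequate signal-to-noise.

    Candidate hot windows of fixed width slide over the post-laser span in
    fixed steps. For each, the signal is the span of per-concentration mean
    Fnorm across the dilution series and the noise is the pooled
    within-replicate standard deviation of Fnorm (residual-based when a
    concentration has a single capillary). The highest-SNR window wins —
    the thermophoretic amplitude keeps developing after laser-on, and
    windows that merely clear the threshold early yield systematically
    biased Kd fits. ``passed`` records whether the winner reached
    ``min_snr``.
    """
    concs = np.unique(series.concentrations)
    if concs.size < 2:
        raise ValueError("need at least two distinct ligand concentrations")
    t_on = series.laser_on_time
    t_end = min(float(tr.times[-1]) for tr in series.traces)
    if t_end <= t_on:
        raise ValueError("no post-laser samples in series")

    starts = np.arange(t_on, t_end - window_width + 1e-9, window_step)
    if starts.size == 0:
        starts = np.array([t_on])
    best: HotRegionResult | None = None
    for s in starts:
        hot = (float(s), float(min(s + window_width, t_end)))
        means, noises = [], []
        for c in concs:
            reps = [tr for tr in series.traces if tr.ligand_conc == c]
            vals = [compute_fnorm(tr, default_cold_region(tr), hot) for tr in reps]
            means.append(np.mean(vals))
            if len(vals) > 1:
                noises.append(np.std(vals, ddof=1))
            else:
                noises.append(_window_noise(reps[0], default_cold_region(reps[0]), hot))
        span = float(np.max(means) - np.min(means))
        noise = float(np.mean(noises))
        snr = span / noise if noise > 0 else (np.inf if span > 0 else 0.0)
        if best is None or snr > best.snr:
            best = HotRegionResult(hot, snr, passed=snr >= min_snr)
    return best


def detect_mode(series: MstSeries) -> MstMode:
    """Choose between thermophoresis and initial-fluorescence readout.

    Initial-fluorescence mode applies when the pre-heating raw counts show
    a systematic ligand-concentration dependence: Spearman |rho| above 0.7
    against log concentration together with a relative span above 10%.
    Both gates must fire so that drift or jitter alone never switches mode.
    """
    concs = np.unique(series.concentrations)
    counts = []
    for c in concs:
        reps = [tr for tr in series.traces if tr.ligand_conc == c]
        counts.append(np.mean([cold_region_counts(tr) for tr in reps]))
    counts = np.asarray(counts)
    if concs.size < 3 or np.all(counts == counts[0]):
        return MstMode.MST
    rho, _ = stats.spearmanr(np.log(concs), counts)
    rel_span = (counts.max() - counts.min()) / counts.mean()
    if abs(rho) > MODE_TREND_RHO and rel_span > MODE_TREND_SPAN:
        return MstMode.INITIAL_FLUORESCENCE
    return MstMode.MST


def _series_response(
    series: MstSeries, mode: MstMode, hot: tuple[float, float] | None
) -> pd.DataFrame:
    rows = []
    for tr in series.traces:
        cold = default_cold_region(tr)
        if mode is MstMode.MST:
            resp = compute_fnorm(tr, cold, hot)
        else:
            resp = cold_region_counts(tr, cold)
        rows.append(
            {"ligand_conc": tr.ligand_conc, "response": resp, "capillary_id": tr.capillary_id}
        )
    return pd.DataFrame(rows)


def fit_kd_points(
    ligand_conc: np.ndarray,
    response: np.ndarray,
    target_conc: float,
) -> tuple[dict | None, str]:
    """Nonlinear least squares of the depletion model on dose-response points.

    Free parameters are the unbound signal, the bound signal and Kd; the
    target concentration is fixed. Kd is initialized at the geometric mean
    of the tested concentrations and constrained to ``KD_BOUNDS``.
    Returns (result dict, message); result is None on non-convergence.
    """
    c = np.asarray(ligand_conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if c.size < 3:
        raise ValueError("need at least three dose-response points")

    order = np.argsort(c)
    y_lo = float(np.mean(y[order[: max(1, c.size // 8)]]))
    y_hi = float(np.mean(y[order[-max(1, c.size // 8):]]))
    kd0 = float(np.exp(np.mean(np.log(c[c > 0]))))
    scale = max(abs(y).max(), 1.0)

    def model(cc, unbound, bound, kd):
        return depletion_fraction_bound(
            cc, DepletionModelParams(unbound, bound, kd, target_conc)
        )

    try:
        popt, pcov = optimize.curve_fit(
            model,
            c,
            y,
            p0=[y_lo, y_hi if y_hi != y_lo else y_lo + 1e-6 * scale, kd0],
            bounds=([-np.inf, -np.inf, KD_BOUNDS[0]], [np.inf, np.inf, KD_BOUNDS[1]]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return None, f"fit did not converge: {exc}"

    unbound, bound, kd = (float(v) for v in popt)
    se_kd = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    resid = y - model(c, *popt)
    dof = max(c.size - 3, 1)
    noise = float(np.sqrt((resid**2).sum() / dof))
    return (
        {
            "unbound": unbound,
            "bound": bound,
            "kd": kd,
            "se_kd": se_kd,
            "residual_sd": noise,
        },
        "",
    )


def fit_kd(
    series: MstSeries,
    mode: MstMode | None = None,
    min_snr: float = DEFAULT_MIN_SNR,
) -> MstFitResult:
    """Full series-to-Kd pipeline: region selection, mode choice, fit, flags.

    Replicate capillaries are pooled into one residual vector rather than
    averaged first, so the 68% confidence half-width reflects the full
    error structure. Non-convergence and pathological responses come back
    as flagged results, never exceptions.
    """
    if mode is None:
        mode = detect_mode(series)
    cold = default_cold_region(series.traces[0])

    hot_result = None
    if mode is MstMode.MST:
        hot_result = select_hot_region(series, min_snr=min_snr)
        hot = hot_result.region
    else:
        hot = None

    resp = _series_response(series, mode, hot)
    fitted, msg = fit_kd_points(
        resp["ligand_conc"].to_numpy(), resp["response"].to_numpy(), series.target_conc
    )
    base = {
        "mode": mode,
        "hot_region": hot,
        "cold_region": cold,
        "snr": hot_result.snr if hot_result else None,
        "response": resp,
    }
    if fitted is None:
        return MstFitResult(
            kd=None, kd_ci68_halfwidth=None, converged=False, message=msg, **base
        )

    flags = []
    if hot_result is not None and not hot_result.passed:
        flags.append("low_snr")
    amplitude = abs(fitted["bound"] - fitted["unbound"])
    resp_scale = max(abs(fitted["unbound"]), abs(fitted["bound"]), 1e-12)
    if amplitude <= max(3.0 * fitted["residual_sd"], 1e-9 * resp_scale):
        flags.append("no_binding")
    kd, se_kd = fitted["kd"], fitted["se_kd"]
    if kd <= KD_BOUNDS[0] * 1.01 or kd >= KD_BOUNDS[1] * 0.99:
        flags.append("kd_at_bound")
    if not np.isfinite(se_kd) or se_kd > kd:
        flags.append("wide_ci")
    return MstFitResult(
        kd=kd,
        kd_ci68_halfwidth=se_kd,
        unbound_signal=fitted["unbound"],
        bound_signal=fitted["bound"],
        flags=tuple(flags),
        **base,
    )


# ---------------------------------------------------------------- CSV I/O

def read_traces_csv(
    path: str | Path,
    target_conc: float,
    laser_on_time: float,
) -> MstSeries:
    """Read a long-format trace table into an MstSeries.

    Expected columns: ``capillary_id``, ``ligand_conc_uM``, ``time_s``,
    ``fluorescence``. The capillary with ligand_conc_uM == 0 (if any)
    becomes the reference trace.
    """
    df = pd.read_csv(path)
    required = {"capillary_id", "ligand_conc_uM", "time_s", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces, reference = [], None
    for cap_id, grp in df.groupby("capillary_id", sort=False):
        grp = grp.sort_values("time_s")
        tr = MstTrace(
            times=grp["time_s"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(),
            ligand_conc=float(grp["ligand_conc_uM"].iloc[0]),
            laser_on_time=laser_on_time,
            capillary_id=str(cap_id),
        )
        if tr.ligand_conc == 0:
            reference = tr
        else:
            traces.append(tr)
    return MstSeries(tuple(traces), target_conc=target_conc, reference_trace=reference)


def read_dose_response_csv(path: str | Path) -> pd.DataFrame:
    """Read pre-extracted dose-response points.

    Expected columns: ``ligand_conc_uM``, ``response``; optional
    ``replicate``.
    """
    df = pd.read_csv(path)
    required = {"ligand_conc_uM", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose-response CSV missing columns: {sorted(missing)}")
    return df
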