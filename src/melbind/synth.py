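"""Synthetic assay-data generator.

Emulates both assays from known ground-truth binding parameters so every
pipeline stage can be exercised end to end without instrument data:

* MST capillary traces: a flat pre-laser baseline followed by a
  single-exponential thermophoretic depletion whose amplitude scales with
  the fraction of target occupied (from the ligand-depletion model at the
  true Kd). Optionally the baseline itself depends on occupancy, which
  reproduces ligand-induced initial-fluorescence changes.
* Equilibrium supernatants: free concentrations solved exactly from the
  Sips mass balance at the true (Kd, Bmax, n), emitted alongside paired
  melanin-free controls.

Noise is multiplicative log-normal by default (fluorescence counts and
LC-quantified concentrations are positive and CV-dominated), parametrized
by its coefficient of variation and mean-preserving, so zero noise gives
exact round trips. All randomness flows from the single seed in the
config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .equilibrium import EquilibriumDataset
from .models import DepletionModelParams, SipsParameters, depletion_fraction_bound
from .mst import MstSeries, MstTrace
from .prediction import fraction_unbound_sips

__all__ = ["SynthConfig", "generate_mst_series", "generate_equilibrium_dataset",
           "write_mst_csv", "write_equilibrium_csv"]


def _dilution_series(top: float = 500.0, steps: int = 16, factor: float = 2.0) -> tuple:
    """Descending 2x dilution series, the standard screening design."""
    return tuple(top / factor**i for i in range(steps))


@dataclass(frozen=True)
class SynthConfig:
    """Ground truth and design of a simulated compound.

    Defaults mirror the screening conditions: melanin nanoparticles at
    12.5 µM (0.5 mg/mL at 40 kDa), a 16-step twofold dilution series from
    500 µM, 30 s traces with the heating laser on at 5 s, and 3%
    multiplicative noise.
    """

    true_kd: float  # µM
    true_bmax: float = 100.0  # nmol/mg
    true_n: float = 0.8
    target_conc: float = 12.5  # µM
    conc_series: tuple = field(default_factory=_dilution_series)
    noise_cv: float = 0.03
    baseline_counts: float = 1000.0
    depletion_amplitude: float = 0.3  # fractional Fnorm drop at full occupancy
    tau_s: float = 3.0  # thermophoresis time constant
    laser_on_s: float = 5.0
    duration_s: float = 30.0
    dt_s: float = 0.25
    cold_trend_amplitude: float = 0.0  # fractional initial-counts drop at full occupancy
    additive_noise: bool = False
    n_replicates: int = 3  # biological replicates per dilution series
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_kd <= 0 or self.target_conc <= 0:
            raise ValueError("true_kd and target_conc must be positive")
        if any(c <= 0 for c in self.conc_series):
            raise ValueError("conc_series must be positive")
        if list(self.conc_series) != sorted(self.conc_series, reverse=True):
            raise ValueError("conc_series must be sorted descending")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")


def _noisy(values: np.ndarray, cv: float, rng: np.random.Generator,
           additive: bool) -> np.ndarray:
    if cv == 0:
        return values
    if additive:
        return values + rng.normal(0.0, cv * np.abs(values))
    sigma = np.sqrt(np.log1p(cv**2))
    return values * rng.lognormal(-0.5 * sigma**2, sigma, size=values.shape)


def _fraction_bound(conc: float, cfg: SynthConfig) -> float:
    return depletion_fraction_bound(
        conc, DepletionModelParams(0.0, 1.0, cfg.true_kd, cfg.target_conc)
    )


def generate_mst_series(cfg: SynthConfig) -> tuple[MstSeries, dict]:
    """Simulate one MST dilution series plus its ground-truth record.

    Per capillary: occupancy fb from the depletion model at the true Kd;
    baseline ``B (1 - cold_trend_amplitude * fb)``; after laser-on the
    signal relaxes as ``1 - depletion_amplitude * fb * (1 - exp(-t/tau))``;
    multiplicative noise on every sample.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(0.0, cfg.duration_s + 1e-9, cfg.dt_s)
    post = np.clip(times - cfg.laser_on_s, 0.0, None)

    def make_trace(conc: float, cap_id: str) -> MstTrace:
        fb = _fraction_bound(conc, cfg) if conc > 0 else 0.0
        baseline = cfg.baseline_counts * (1.0 - cfg.cold_trend_amplitude * fb)
        decay = 1.0 - cfg.depletion_amplitude * fb * (1.0 - np.exp(-post / cfg.tau_s))
        clean = baseline * np.where(times >= cfg.laser_on_s, decay, 1.0)
        noisy = np.clip(_noisy(clean, cfg.noise_cv, rng, cfg.additive_noise), 0.0, None)
        return MstTrace(times, noisy, conc, cfg.laser_on_s, capillary_id=cap_id)

    traces = [
        make_trace(c, f"c{i:02d}r{r}")
        for r in range(cfg.n_replicates)
        for i, c in enumerate(cfg.conc_series)
    ]
    reference = make_trace(0.0, "ref")
    series = MstSeries(tuple(traces), target_conc=cfg.target_conc,
                       reference_trace=reference)
    truth = {
        "true_kd": cfg.true_kd,
        "target_conc": cfg.target_conc,
        "fnorm_at_full_occupancy": 1.0 - cfg.depletion_amplitude,
        "fraction_bound": {c: _fraction_bound(c, cfg) for c in cfg.conc_series},
        "seed": cfg.seed,
    }
    return series, truth


def generate_equilibrium_dataset(
    cfg: SynthConfig,
    melanin_conc: float = 1.0,
    totals: tuple | None = None,
    n_replicates: int = 3,
) -> tuple[EquilibriumDataset, dict]:
    """Simulate paired control/melanin supernatant measurements.

    Free concentrations are the exact Sips mass-balance roots at the
    ground-truth parameters; controls are the totals. Both are then
    measured with multiplicative noise. ``melanin_conc = 0`` yields
    free = total (no binder).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    totals = tuple(totals) if totals is not None else cfg.conc_series
    params = SipsParameters(cfg.true_kd, cfg.true_bmax, cfg.true_n)
    free_true = np.array([
        total * fraction_unbound_sips(params, melanin_conc, total) / 100.0
        if melanin_conc > 0 else total
        for total in totals
    ])
    tot = np.repeat(np.asarray(totals, dtype=float), n_replicates)
    free = np.repeat(free_true, n_replicates)
    rep = np.tile(np.arange(n_replicates), len(totals))
    measured_tot = _noisy(tot, cfg.noise_cv, rng, cfg.additive_noise)
    measured_free = np.clip(_noisy(free, cfg.noise_cv, rng, cfg.additive_noise), 0.0, None)
    data = EquilibriumDataset(
        total_conc=measured_tot,
        free_conc=measured_free,
        melanin_conc=melanin_conc if melanin_conc > 0 else 1.0,
        replicate=rep,
        nominal_conc=tot,
    )
    truth = {
        "true_kd": cfg.true_kd, "true_bmax": cfg.true_bmax, "true_n": cfg.true_n,
        "melanin_conc": melanin_conc,
        "free_conc_true": dict(zip((float(t) for t in totals), free_true.tolist())),
        "seed": cfg.seed,
    }
    return data, truth


# ------------------------------------------------------------- CSV export

def write_mst_csv(series: MstSeries, path: str | Path, truth: dict | None = None) -> None:
    """Write the long-format trace CSV the MST reader consumes."""
    rows = []
    all_traces = list(series.traces)
    if series.reference_trace is not None:
        all_traces.append(series.reference_trace)
    for tr in all_traces:
        for t, f in zip(tr.times, tr.fluorescence):
            rows.append((tr.capillary_id, tr.ligand_conc, t, f))
    pd.DataFrame(
        rows, columns=["capillary_id", "ligand_conc_uM", "time_s", "fluorescence"]
    ).to_csv(path, index=False)
    if truth is not None:
        Path(path).with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))


def write_equilibrium_csv(
    data: EquilibriumDataset, path: str | Path, truth: dict | None = None
) -> None:
    """Write the paired-supernatant CSV the equilibrium reader consumes."""
    pd.DataFrame({
        "nominal_conc_uM": (
            data.nominal_conc if data.nominal_conc is not None else data.total_conc
        ),
        "control_supernatant_uM": data.total_conc,
        "melanin_supernatant_uM": data.free_conc,
        "replicate": data.replicate if data.replicate is not None else 0,
    }).to_csv(path, index=False)
    if truth is not None:
        Path(path).with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))
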