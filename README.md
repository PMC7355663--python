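# melbind

Melanin-binding screening analysis for ocular drug discovery.

Many drugs bind melanin, and in the densely pigmented retinal pigment
epithelium and choroid (RPE-choroid) this binding dominates tissue drug
disposition: melanin there reaches ~35 mg/mL, one to two orders of
magnitude above the concentrations used in vitro, so even compounds that
look like weak binders on the bench can be >90% melanin-bound in vivo.
`melbind` implements the complete analysis chain that turns raw binding
assays into in vivo predictions and a four-tier melanin-binder
classification:

1. **MST Kd fitting** — microscale-thermophoresis dilution series
   (fluorescent melanin nanoparticles, 12.5 µM ≙ 0.5 mg/mL at 40 kDa) are
   processed from raw capillary traces: hot/cold-window normalized
   fluorescence (Fnorm), signal-to-noise-driven hot-region selection,
   automatic fall-back to the initial-fluorescence readout when the ligand
   itself changes the target's fluorescence, and a nonlinear
   least-squares fit of the **ligand-depletion** single-site model

   f(c) = U + (B − U) · [(c + cₜ + K_d) − √((c + cₜ + K_d)² − 4 c cₜ)] / (2 cₜ)

   which accounts for the non-trace target concentration cₜ. 68%
   confidence half-widths come from the fit covariance.

2. **Sips isotherm fitting** — the traditional assay (drug + melanin
   suspension, supernatant quantified against melanin-free controls) gives
   bound amounts B = (total − free)/c_mel that are fitted with the
   Sips (Langmuir–Freundlich) isotherm

   B(L) = B_max · Lⁿ / (K_dⁿ + Lⁿ),

   whose heterogeneity index n ≤ 1 captures the spread of binding
   energies on the melanin surface (n = 1 is the Langmuir limit).

3. **In vivo extrapolation** — the fraction unbound at any melanin
   concentration follows from the mass balance
   total = L + c_mel·B(L) (unique root, solved by bracketed
   root-finding), or, when only a measured unbound fraction is available,
   from the dilution-scaling relation
   fu' = 100 / (D·(100/fu − 1) + 1) with D the melanin concentration
   ratio. Cassette-assay data can be corrected to single-compound
   conditions (÷2.1).

4. **Classification and cross-method statistics** — compounds are binned
   into extreme / high / intermediate / low melanin binders by MST Kd
   (cut-offs 6.5 / 65 / 650 µM) or equivalently by predicted in vivo
   unbound fraction (0.1 / 1 / 10%); the two assays are compared through
   target-capacity/affinity ratios (Spearman rank correlation) and a
   through-origin regression K_d(MST) ≈ 65 × fu_in-vivo(%), which is where
   the Kd cut-offs come from.

A synthetic-data generator simulates both assays from known ground truth
(trace-level thermophoresis kinetics with multiplicative noise; exact
mass-balance supernatants), so every stage is validated by parameter
recovery without instrument data. A reference panel of 13 ophthalmic
model compounds (chloroquine, atropine, timolol, …) with published
binding parameters ships with the package and drives the end-to-end
reproduction.

## Worked example

Fit a simulated MST dilution series (true Kd = 30 µM, 3% trace noise,
three replicate series) and predict chloroquine's in vivo binding from
its Sips parameters:

```python
from melbind import (SynthConfig, generate_mst_series, fit_kd,
                     SipsParameters, fraction_unbound_sips,
                     classify_fu, classify_kd)

series, _ = generate_mst_series(SynthConfig(true_kd=30.0, noise_cv=0.03, seed=7))
res = fit_kd(series)
print(f"Kd = {res.kd:.1f} ± {res.kd_ci68_halfwidth:.1f} µM "
      f"mode={res.mode.value} hot={res.hot_region} snr={res.snr:.1f}")

chloroquine = SipsParameters(kd=76.0, bmax=380.0, n=0.605)
fu_vitro = fraction_unbound_sips(chloroquine, melanin_conc=1.0, total_conc=1.0)
fu_vivo = fraction_unbound_sips(chloroquine, melanin_conc=34.8, total_conc=1.0)
print(f"fu in vitro = {fu_vitro:.2f}%  fu in vivo = {fu_vivo:.4f}%  "
      f"class = {classify_fu(fu_vivo).value}")
```

prints

```
Kd = 30.2 ± 2.8 µM mode=mst hot=(17.0, 18.0) snr=31.8
fu in vitro = 0.41%  fu in vivo = 0.0012%  class = extreme
```

The fitted Kd recovers the programmed 30 µM within its 68% confidence
interval; the selected hot window (17–18 s after trace start) is where the
thermophoretic signal-to-noise peaks. Chloroquine, 0.41% unbound at the
1 mg/mL assay concentration, is predicted 99.999% melanin-bound in the
human RPE-choroid — an extreme binder by both routes.

The same steps are available from the shell:

```sh
melbind simulate --kd 30 --seed 7 --out-dir scratch/demo
melbind fit-mst scratch/demo/mst_traces.csv
melbind predict --kd 76 --bmax 380 --n 0.605 --melanin-conc 34.8 --total-conc 1
melbind reproduce --out-dir scratch/report   # full reference-panel analysis
```

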