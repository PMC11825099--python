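# bimodalkit

Stochastic two-state promoter models and bimodality analysis of single-cell
gene-expression distributions.

Some bacterial genes express at two distinct levels in a clonal population:
the single-cell distribution of protein numbers (or reporter fluorescence)
has a low and a high mode, and cells switch between them.  This package is
for researchers who want to study when such bimodality appears, how robust
it is to perturbations of transcription, translation and turnover, and how
to detect and quantify it in data — simulated or measured by flow
cytometry.

## What's inside

* **Reduced two-state expression model.** A promoter switches between a
  low (L) and a high (H) transcription state at slow rates `k_H` (L→H) and
  `k_L` (H→L).  Initiation in each state is a two-step process — RNAP
  holoenzyme binding at `k_bind_X·n_holo`, then promoter escape at
  `k_esc_X` releasing one RNA — with the promoter unavailable in between.
  Translation (`k_tr`) and first-order decays (`kd_rna`, `kd_prot`,
  degradation + dilution) complete the scheme.  The effective transcription
  rate per state is `r_X = 1/(1/(k_bind_X·n_holo) + 1/k_esc_X)` and the
  locked-state mean protein number is `r_X·k_tr/(kd_rna·kd_prot)`.
  Single-state collapse variants (low / average / high rate) and a
  positive-feedback variant are included, as are named perturbation
  scenarios (rifampicin → escape rates; streptomycin → translation;
  novobiocin → switching; growth-phase transition → interpolated
  condition sets).
* **Exact stochastic simulation** (direct-method SSA, numba-accelerated
  ensembles, counter-based per-cell seeding) with two independent oracles:
  closed-form stationary means and a truncated chemical-master-equation
  stationary solver.
* **Bimodality classification**: BIC comparison of 1- vs 2-component
  Gaussian mixtures (with separation and mixture-shape guards) OR kernel
  density peak detection; shape statistics of bimodal distributions —
  relative peak distance `d = (pk₂−pk₁)/range`, relative height difference
  `h = (PDF₁−PDF₂)/max PDF`, between-peak fraction `o = n_overlap/n_total`.
* **In-silico experiments**: single-parameter 0.1×–10× sweeps, extended
  L-rate sweeps, the gradual exponential→stationary transition,
  bimodal→unimodal transients, and forward/backward ramp cycles with a
  loop-gap statistic for hysteresis.
* **Synthetic flow cytometry**: log-normal mixture intensities over an
  autofluorescence floor, extrinsic noise, three merged biological
  replicates, and correlated but unimodal size-proxy channels
  (SSC-H/FSC-H/Width); plus a bridge from simulated counts to
  intensity-like data.
* **Cross-fluorophore calibration**: the 4-anchor piecewise-linear map
  (min, weak-mode mean, high-mode mean, max) with OLS fit statistics.

See `docs/methods.md` for the model, defaults, and numerical choices.

## Worked example

```python
from bimodalkit import (
    reference_rates, build_reduced_model, sample_snapshot,
    classify_modality, shape_params, stationary_moments_closed_form,
)

rates = reference_rates()
system = build_reduced_model(rates)            # 6 species, 9 reactions
snap = sample_snapshot(system, n_cells=10000, seed=1)

call = classify_modality(snap.values)
sp = shape_params(call, snap.values)
m_L = stationary_moments_closed_form(rates, "L").mean["Protein"]
m_H = stationary_moments_closed_form(rates, "H").mean["Protein"]

print(f"verdict: {call.verdict} (BIC={call.bic_criterion}, peaks={call.peaks_criterion})")
print(f"modes at {call.pk1:.1f} and {call.pk2:.1f} proteins "
      f"(closed-form state means {m_L:.1f} / {m_H:.1f})")
print(f"shape: d={sp.d:.2f}  h={sp.h:.2f}  o={sp.o:.2f}")
```

prints

```
verdict: bimodal (BIC=True, peaks=True)
modes at 2.7 and 31.4 proteins (closed-form state means 3.3 / 33.3)
shape: d=0.42  h=0.57  o=0.52
```

Ten thousand cells simulated to stationarity land in two modes near the
closed-form means of the locked L and H states; the first mode is taller
(`h > 0`), the modes sit 42% of the data range apart, and half the cells
lie between the peaks.  `run_sweep` then shows how this distribution
deforms as any one rate constant moves through 0.1×–10×: cutting H-state
initiation or translation ten-fold, or boosting either decay rate
ten-fold, collapses it onto a single low mode, while tuning the switching
rates only shifts the mode weights and overlap.

## Command line

```bash
bimodalkit simulate --cells 5000 --seed 1 --out ref.csv
bimodalkit classify ref.csv
bimodalkit sweep --param k_esc_H --grid 0.1:10:7 --cells 5000 --seed 1 --out sweep.json
bimodalkit synth --fixture synthetic_distant_even --seed 1 --out cells.csv
bimodalkit calibrate --src gfp.csv --dst yfp.csv --out map.json
bimodalkit hysteresis --param k_bind_H --seed 1
bimodalkit pipeline --config run.yaml --out report/
```

All commands take explicit seeds; identical configuration and seed give
identical output.

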