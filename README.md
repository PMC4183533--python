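# dcevox

Finite-element simulation of intra-voxel contrast-agent diffusion for
quantitative DCE-MRI.

## The problem

Dynamic contrast-enhanced MRI estimates tissue physiology — the volume
transfer constant K<sup>trans</sup>, the extravascular extracellular volume
fraction v<sub>e</sub>, and the plasma fraction v<sub>p</sub> — by fitting
tracer-kinetic models to signal-intensity time courses.  The extended Tofts
model,

```
C_t(t) = Ktrans ∫₀ᵗ C_p(τ) e^(−(Ktrans/ve)(t−τ)) dτ + vp C_p(t),
```

assumes the extracellular space is instantaneously well mixed.  Real
contrast agents diffuse with a finite coefficient D (≈1–4×10⁻⁴ mm²/s for
gadolinium chelates in tissue), so the agent piles up around vessels before
spreading through the interstitium.  `dcevox` quantifies the bias this
produces: it simulates delivery and diffusion inside a realistic 2-D tissue
voxel, synthesizes the MR signal the scanner would see, fits the extended
model the way a standard analysis would, and reports the percent
parameterization error as a function of D and scan temporal resolution.

It is aimed at researchers in quantitative MR physics and tracer-kinetic
modelling who want a transparent, testable sandbox for diffusion effects at
the voxel scale.

## What is inside

* `geometry` — seeded packing of a (250 µm)² voxel with elliptical cells
  (impermeable), circular vessels (8 µm, spaced by farthest-point sampling)
  and the extracellular space between them, hitting prescribed area
  fractions (v<sub>e</sub>, v<sub>p</sub>) exactly; 3×3 tiling to embed the
  voxel of interest in identical neighbours.
* `meshing` — graded triangulation of the extracellular space only (cells
  and vessels stay unmeshed voids) with every boundary edge tagged
  vessel / cell / outer.
* `fem_solver` — P1 Galerkin discretization of ∂C/∂t = D∇²C with a Robin
  influx D ∂C/∂n = P (C_p(t) − C) on vessel walls (P = (Ktrans/60)·V/S) and
  zero flux elsewhere; Crank–Nicolson stepping with a reused sparse LU.
* `aif` — parametric population-style arterial input function
  (gamma-variate bolus peaking at 0.88 min + biexponential washout), or any
  measured curve from CSV.
* `mr_signal` — fast-exchange-limit compartment R1 bookkeeping and the SPGR
  signal equation (TR 5 ms, flip 25°, r1 4.7 mM⁻¹s⁻¹, R10 0.5 s⁻¹).
* `pk_models` — standard/extended Tofts forward models, SPGR inversion, and
  bounded nonlinear least-squares fitting.
* `experiment` — the full grid (domains × Ktrans × D × temporal
  resolution) behind the error tables.
* `oracle` — an independent masked-grid finite-difference solver and the
  closed-form well-mixed limit, used to validate the FEM.

## Worked example

```python
import numpy as np
from dcevox import (AIFModel, ExperimentConfig, generate_domain,
                    tile_extended_domain, mesh_ees, summarize_errors)
from dcevox.experiment import run_cell, _fit_rows

# a voxel with ve = 0.39, vp = 0.03, embedded in 8 identical neighbours
dom = generate_domain(seed=1)
ext = tile_extended_domain(dom)
mesh = mesh_ees(ext, target_edge=6e-3)

cfg = ExperimentConfig(seed=1)
ctc, r1 = run_cell(ext, mesh, Ktrans=0.4, D=1e-4, config=cfg)
rows = _fit_rows(r1, ctc.times, ext, 0.4, 1e-4, cfg)
for r in rows:
    print(f"dt={r['dt_sample_s']:5.1f} s  "
          f"errK={r['err_Ktrans_pct']:+6.2f}%  "
          f"err_ve={r['err_ve_pct']:+6.3f}%  err_vp={r['err_vp_pct']:+6.2f}%")
```

prints (seed 1, D = 1×10⁻⁴ mm²/s):

```
dt=  1.6 s  errK= -5.63%  err_ve=-0.167%  err_vp= +2.15%
dt=  3.2 s  errK= -5.63%  err_ve=-0.166%  err_vp= +2.14%
dt=  6.4 s  errK= -5.63%  err_ve=-0.166%  err_vp= +2.13%
dt= 12.8 s  errK= -5.62%  err_ve=-0.163%  err_vp= +2.10%
dt= 25.6 s  errK= -5.58%  err_ve=-0.150%  err_vp= +1.91%
```

At a physiological diffusion coefficient the fitted K<sup>trans</sup> is
biased low by ~6 % for this well-vascularized voxel because the agent
cannot leave the vessel periphery fast enough; at D = 3×10⁻³ mm²/s (40×
faster than physiological) the same pipeline recovers all three parameters
to better than 0.2 %, confirming that the bias is a diffusion effect, not a
pipeline artifact.  Sparser vasculature and higher K<sup>trans</sup>
amplify the bias.

The same grid is available from the shell:

```
dcevox grid --out results/            # results.csv + summary.json
dcevox domain --ve 0.39 --vp 0.03 --seed 1 --out domain.json
dcevox mesh --domain-json domain.json --target-edge-um 2 --out mesh
```

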