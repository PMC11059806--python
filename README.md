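# retinapop

Virtual populations of the human retinal vasculature, with network
hemodynamics and OCTA-style morphometrics.

## What it does, and for whom

Microvascular metrics measured on OCT angiography (vessel area density,
fractal dimension, …) are widely used biomarkers of retinal disease, but how
they relate to actual retinal perfusion is hard to probe experimentally.
`retinapop` is a research tool for modelers and image-analysis researchers
that closes this loop in silico: it generates anatomically plausible
vasculatures of the temporal retina and macula — CRA/CRV roots, PCA-sampled
temporal arcades, arteriolar/venular trees grown by constrained constructive
optimization (CCO), and the three macular capillary plexuses (SVP/ICP/DCP)
built from Voronoi diagrams — solves blood flow on the resulting network,
and measures both function (retinal blood flow, macular flow fraction) and
structure (VAD, VSD, VDI, VCI, FD, IVD, Horton–Strahler diameter tables) on
cohorts of such virtual eyes.

The core models:

* **Growth** — staged CCO: terminals are placed with a fovea-biased radial
  law r = r₀ + e^(µ+σZ), separated by l_min = √(νA/(π(N+1))), and connected
  at volume-minimizing bifurcations subject to Murray's law
  r_p^γ = r₁^γ + r₂^γ, a radius-symmetry floor δ, and a branching-angle
  floor θ_min, in three regions (full disk, perifoveal annulus, parafoveal
  disk).
* **Capillaries** — Delaunay-centroid Voronoi meshes per plexus, pruned
  around arterioles, wired to the trees (all macular terminals plus a
  fraction α of arterioles/venules; 30% descend to the ICP and on to the
  DCP), with graph-Laplacian flow orientation that keeps the capillary
  graph acyclic.
* **Hemodynamics** — Poiseuille resistances R = 8µl/(πr⁴) with the in-vivo
  diameter-dependent effective-viscosity law (Fåhræus–Lindqvist effect,
  hematocrit 0.45), boundary pressures p_CRA = ⅔·MAP and p_CRV = IOP,
  extramacular terminals closed through a compartment of fixed resistance;
  one sparse linear solve per eye.
* **Statistics** — cohorts over the four clinical parameters
  (r_CRA, v_CRA, MAP, IOP), Spearman structure–function correlations with
  bootstrap CIs, Sobol sensitivity analysis (Saltelli design, first/total
  order), and an uncertainty-quantification grid over R, OPP and α.

## Worked example

```bash
python examples/01_generate_one_eye.py
```

prints (seed 1; capillary beds at half seed count):

```
individual: r_CRA=83.8 um, v_CRA=7.29 cm/s, MAP=86.0 mmHg, IOP=8.4 mmHg, OPP=49.0 mmHg
network: 53246 nodes, 79541 segments
retinal blood flow:     22.20 uL/min
macular flow fraction:  16.26 %
CRA velocity:            1.68 cm/s
```

The individual's ocular perfusion pressure (OPP = ⅔·MAP − IOP = 49 mmHg)
drives ~22 µL/min of blood through the CRA, of which ~16% perfuses the
3 mm-radius perifoveal disk — both inside the physiological range reported
for healthy eyes. The other examples cover morphometrics
(`02_octa_morphometrics.py`), cohort correlations
(`03_cohort_correlations.py`), Sobol sensitivity
(`04_sobol_sensitivity.py`) and the UQ grid (`05_uncertainty_grid.py`).

A thin CLI wraps the same entry points:

```bash
retinapop generate --seed 1 --out out/          # one eye + VTK/CSV export
retinapop cohort --n 20 --seed 1 --out out/     # cohort + correlations
retinapop sobol --n-base 16 --seed 1 --out out/
retinapop uq --n 5 --seed 1 --out out/
```

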