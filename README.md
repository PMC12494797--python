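# saxsfit

Small-angle X-ray scattering (SAXS) analysis and modelling for flexible
multi-domain proteins — built around the kind of system exemplified by
O-GlcNAcase (OGA): a symmetric homodimeric catalytic core carrying
pseudo-HAT domains on flexible linkers, which in solution forms asymmetric
conformers and transient dimers-of-dimers.

The package provides, as one importable library:

* **Primary curve analysis** — Guinier fit (`I(q) ≈ I(0)·e^{−q²Rg²/3}`,
  self-consistent `qmax·Rg` window), dimensionless Kratky transform
  (`(qRg)²I/I(0)` vs `qRg`) with a flexibility plateau diagnostic, Porod
  invariant/volume (`Vp = 2π²I(0)/∫q²I dq`) and correlation volume
  (`Vc = I(0)/∫qI dq`) with the standard protein mass calibrations.
* **Indirect Fourier transform** — `p(r)` by regularised least squares with
  a second-difference smoothness prior, α and Dmax selected by Bayesian
  evidence (or a classic χ²-plateau mode).
* **A Debye-equation forward calculator** — per-residue (or per-atom)
  Gaussian beads with excluded-volume contrast, optional hydration layer,
  exact `I(q) = Σᵢⱼ fᵢfⱼ sinc(qrᵢⱼ)` or a fast pair-distance-histogram
  variant, and scale/background fitting with reduced χ².
* **Rigid-body refinement** — multi-body decompositions with soft
  connectivity springs and excluded-volume restraints, simulated-annealing
  refinement against a measured curve over multiple independent runs, and a
  co-fitted unspecific-oligomer structure factor
  `I(q) → I(q)·(1 + f·sin(qd)/(qd))` for transient dimers-of-dimers.
* **Cryo-EM map vs SAXS** — threshold scanning of a density map into
  dummy-atom models scored by reduced χ² against the solution curve.
* **Structure geometry** — Shrake–Rupley SASA, PISA-convention buried
  interface areas, inter-Cα distances, sequence masses, two-fold (C2) axis
  detection from chain superposition, and hybrid-model assembly by aligning
  two-fold axes.
* **Synthetic data** — seeded generators for bead and Cα-trace models
  (spheres, dumbbells, globules, C2 multidomain dimers), noisy curves with
  laboratory-source error growth, oligomer mixtures, and toy voxel maps, so
  every stage is testable without downloads.

File formats: three-column SAXS `.dat` (SASBDB dialect), PDB/mmCIF (via
gemmi), MRC/CCP4-2014 maps (via gemmi). Units: Å, Å⁻¹ throughout.

## Worked example

```python
import saxsfit as sf

spec = sf.SyntheticSpec(shape="multidomain_chain", n_domains=2,
                        n_res_domain=80, n_linker=10, seed=5,
                        oligomer=(0.65, 65.0))
model = sf.make_model(spec)              # CA-trace, two domains + linker
data = sf.simulate_curve(model, spec)    # Debye + oligomer + noise

decomp = sf.decompose(model, sf.multidomain_dimer_segments(spec))
cfg = sf.RBConfig(n_runs=4, n_steps=1500, seed=11, fit_oligomer=True,
                  fit_background=False, fixed_bodies=(1,))
result = sf.rb_refine(decomp, data, cfg)
best = result.best
print(best.chi2_red, best.oligo.f, best.oligo.d)
```

prints (run 1 of 4 winning):

```
0.9427... 0.6533... 64.68...
```

i.e. the refined two-body model explains the simulated curve within its
errors (reduced χ² ≈ 1), and the co-fitted oligomer structure factor
recovers the simulated mixture — 65% of units engaged in dimers-of-dimers
at a 65 Å centre-of-mass separation. The `examples/` directory has one
short script per capability (primary analysis, Debye + hydration,
rigid-body + oligomer, map-vs-SAXS, geometry/hybrid assembly), each printing
the numbers it computes and what they mean. A thin `saxsfit` command-line
interface exposes the same stages (`saxsfit invariants|pr|calc|rbfit|mapfit|
geom|simulate|run`); `saxsfit run config.yaml` executes the whole pipeline
from one YAML config with a fixed seed and writes a machine-readable
summary.

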