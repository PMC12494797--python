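# Methods

`saxsfit` models small-angle X-ray scattering (SAXS) of proteins in
solution, with an emphasis on flexible multi-domain homodimers such as
O-GlcNAcase (OGA): a symmetric catalytic core carrying loosely tethered
accessory (pHAT) domains on flexible linkers. This note describes the
models, their assumptions, the defaults, and what the synthetic validation
does and does not establish.

## Primary curve analysis

**Guinier fit.** I(q) ≈ I(0)·exp(−q²Rg²/3) is fitted as a weighted straight
line of ln I vs q² (weights (I/σ)²). The window is the largest low-q range
with qmax·Rg ≤ 1.3 (configurable), found by self-consistent iteration: fit,
shrink to the predicted window, repeat. A non-negative slope (Rg² < 0) is
reported as an aggregation/repulsion signature rather than silently clipped.
For an ideal homogeneous sphere the next term of ln I is −(qR)⁴/350, which
biases the fitted Rg high by ≈1.2% at qmax·Rg = 1.3 and ≈0.9% at 1.0; the
sphere-recovery validations therefore use the tighter 1.0 window. Real
protein data carry larger systematic effects, so the conventional 1.3
default is kept.

**Dimensionless Kratky.** (qRg)²·I/I(0) vs qRg. Globular particles peak near
(√3, 3/e ≈ 1.10) and decay; flexible chains level off. The "plateau"
diagnostic is the mean transformed intensity over the top decile of q.

**Porod volume.** Q = ∫q²I dq is assembled from (i) the closed-form Guinier
extension below the first measured point, (ii) the trapezoid over the data,
and (iii) a K·q⁻⁴ tail beyond the last point. K and a non-negative constant
c are fitted jointly (non-negative least squares on the top 20% of the
window) and c is subtracted before integration — the standard treatment of
the flat high-q term contributed by internal structure, incoherent
background, or (in simulations) the discrete-scatterer plateau of a bead
model. Vp = 2π²I(0)/Q; mass = Vp / 1.6·10³ Å³·kDa⁻¹. The divisor is the
conventional protein Porod calibration and is configurable.

**Correlation volume.** Vc = I(0)/∫₀^0.3 q·I dq (same constant subtraction
and Guinier extension), and mass[Da] = (Vc²/Rg)/0.1231 — the standard
protein power-law calibration. That calibration is empirical for real
proteins; a smooth homogeneous sphere lacks the internal-structure intensity
at high q and reads ~20–30% low, which the test suite freezes as a known
property rather than "fixing" by a bespoke constant.

**Mass-recovery scale.** The mass-recovery validation uses random globules
of ≈1,400 residues (≈160 kDa), the mass regime of the flexible OGA-like
homodimers this package targets. For much smaller bead models (≲50 kDa) the
discrete-scatterer plateau is large relative to the envelope scattering and
its separation from the q⁻⁴ tail becomes unstable, biasing the Porod mass by
up to ~20% — a limitation of bead-model fixtures more than of the estimator.

## Indirect Fourier transform

The forward model is I(q) = 4π∫₀^Dmax p(r)·sinc(qr) dr on a uniform grid
(101 points by default) with p(0) = p(Dmax) = 0 clamped. The inverse problem
is weighted least squares with a second-difference smoothness penalty α·pᵀBp.
α is selected on a 30-point log grid by maximising the Gaussian evidence
(marginal likelihood), ties broken toward smoother solutions; a "classic"
mode instead takes the largest α whose χ² stays within 10% of the minimum.
Dmax, when not supplied, is scanned on [2Rg, 5Rg] in 25 steps and selected
by evidence. If the unconstrained solution dips below −1% of its peak, a
non-negative least-squares polish on the regularised augmented system
restores near-nonnegativity. Moments: Rg² = ∫r²p dr / 2∫p dr,
I(0) = 4π∫p dr. Point scatterers at zero separation (self terms) appear as
mass piled against the r = 0 boundary; the pair-distance features themselves
are unaffected.

## Debye forward model

Scattering is computed from Gaussian beads:
I(q) = Σᵢⱼ fᵢfⱼ·sin(qrᵢⱼ)/(qrᵢⱼ), fᵢ(q) = bᵢ·exp(−q²σᵢ²/2).

* **Coarse-graining.** One bead per residue at the heavy-atom centroid with
  b = electrons − ρs·V (ρs = 0.334 e/Å³, tabulated residue volumes), or one
  bead per heavy atom with atomic displaced volumes. The Gaussian width
  σ = (1/√5)(3V/4π)^{1/3} matches the bead's second moment to a uniform
  sphere of the same volume.
* **Hydration layer.** Shell beads on the solvent-exposed surface at
  distance (bead radius + 3 Å), one per 15 Å² of surface, with
  b = 0.10·ρwater·V_shell by default. All three constants are configurable;
  they represent the usual ~10% excess-density hydration shell.
* **Evaluation.** The exact O(N²) double sum (numba) for models up to a few
  thousand beads; a pair-distance-histogram variant (0.5 Å bins,
  per-scatterer-type pair histograms) for larger models, accurate to ≲0.5%
  at 0.25 Å bins and converging monotonically as the bin shrinks.
* **Fitting.** Scale and (optionally) a constant background by weighted
  linear least squares; χ²_red = Σ((c·Im + b − Id)/σ)²/(N − p). For
  simulated, background-free data the scale-only fit is the appropriate
  choice and is used throughout the validation experiments.

## Rigid-body refinement

A model is partitioned into K rigid bodies by residue-range segments;
springs are placed at every sequence-adjacent residue pair split across
bodies with rest length 3.8 Å × gap. Slack is 1.5 Å × gap (so a contiguous
cut gets 1.5 Å of slack — a "soft" restraint needs a non-zero dead zone
even with no missing residues). The objective is

    total = χ²_red + w_conn·Σ max(0, d − rest − slack)² + w_ev·Σ (r_clash − d)²,

with w_conn = 10, w_ev = 1, r_clash = 3.8 Å between beads of different
bodies. Optimisation is Metropolis simulated annealing (default 3,000 steps,
T geometric 2.0 → 0.01): each step moves one random body, either a rotation
about its centroid plus a translation (σ = 8°, 3 Å, both annealed with √T)
or, with probability ½, a pure rotation about one of its spring anchors —
the move that explores the connectivity-preserving manifold directly.
Intensities are maintained as per-body-pair Debye blocks so a single-body
move recomputes only its K−1 cross blocks. Ten independent runs are
performed (seeded from one master seed); every run except the first starts
from random ±45° per-body hinge kicks (multistart diversification); the best
run minimises the penalised objective, ties broken toward the lowest run
index. A reference body can be held fixed (`fixed_bodies`), the conventional
choice since only relative placement is observable in I(q).

**Identifiability.** SAXS constrains body placement weakly. At
laboratory-source statistics (≈1% relative error at low q, growing as
1 + (q/0.1)² toward high q) alternative placements of a two-lobed domain
15–17 Å apart fit a 100-point curve within Δχ²_red ≈ 0.02 of each other —
statistically indistinguishable. The placement-recovery validation therefore
simulates synchrotron-grade statistics (0.2%), at which the true placement
is decisively preferred (Δχ²_red ≈ 0.5 per competing basin) and the χ²-best
of ten runs lands within ~2–3 Å of the ground truth. At laboratory
statistics the package still converges to χ²_red ≈ 1 but the run-to-run
placement spread is the honest result — consistent with flexible-protein
practice, where multiple refinement runs are inspected for structural
variation rather than read as one unique structure.

## Unspecific-oligomer structure factor

A fraction f of scattering units transiently associated as dimers-of-dimers
at centre-of-mass distance d modulates the intensity as

    I(q) = I_unit(q) · (1 + f·sin(qd)/(qd)),

the decoupling approximation with a unit cross-term. f is a mass fraction:
forward scattering scales as 1 + f (doubling at f = 1), and the modulation
decays at high q. During refinement (f, d) are re-fitted every 250 steps by
a grid search (f in 0.05 steps, d in 5 Å steps over 30–120 Å) polished with
Nelder–Mead. On simulated mixtures at the 65%/65 Å regime the recovered
parameters are within a few percent / a few Å of truth.

## Map-to-SAXS check

A density map is converted into uniform-contrast dummy atoms (one bead per
voxel ≥ threshold, width matched to the voxel volume; optionally
density-weighted). Thresholds are scanned on a 50-level grid between the
50th and 99.9th percentiles of the positive map values; each model's Debye
curve is fitted to the data and the χ²_red profile returned. Above the bead
budget the grid is decimated by 2×2×2 merging with b-weighted centroids;
the reported voxel count (pre-decimation) is non-increasing in threshold by
construction, while the bead count after decimation need not be.

## Structure geometry

* **SASA**: Shrake–Rupley with 960 Fibonacci sphere points per atom, probe
  1.4 Å, standard van der Waals radii, hydrogens ignored.
* **Interface area**: (SASA(A) + SASA(B) − SASA(AB))/2, the PISA headline
  convention; the unhalved buried area and its fraction of the free-chain
  surface are reported alongside, since both conventions occur in the
  literature.
* **Sequence mass**: Σ average residue masses + one water per chain.
* **C2 axis**: Kabsch superposition of matched Cα sets A→B; angle from the
  rotation trace, axis from the unit-eigenvalue eigenvector, and the axis
  point as the perpendicular-plane (minimum-norm) solution of the screw
  decomposition — a canonical point, which makes axis alignment idempotent.
  Deviations of more than 10° from 180° are flagged non-two-fold.
* **Axis alignment**: rigid transform making two axes colinear and
  co-located (canonical points matched), with the residual spin about the
  shared axis set explicitly — the operation used to assemble hybrid models
  of a symmetric core and a separately solved symmetric domain dimer.

## Synthetic data

The generator emulates the study conditions: q from 0.005–0.35 Å⁻¹ (150
points), Gaussian noise with σ(q) = σ₀·I(q)·(1 + (q/q₀)^a), defaults
σ₀ = 0.01, q₀ = 0.1 Å⁻¹, a = 2 — the error growth of a laboratory-source
instrument. Models:

* `sphere` / `dumbbell`: uniform random bead fillings (plus a deterministic
  antialiased `grid_sphere_beads` for closed-form comparisons);
* `globule` / `multidomain_chain` / `multidomain_dimer`: Cα-trace chains
  with residue types drawn from the twenty standard amino acids, packed at
  1.6·10³ Å³/kDa (the Porod protein density). Domains are two fused unequal
  lobes (70/30% of residues, the major one prolate at axis ratio 1.6) so
  that domain orientation is observable in I(q); linkers run between
  surface-attachment residues at ≈3.3 Å rise per residue, and each domain's
  first/last residues sit at the linker attachment points so the chain
  topology matches the geometry. The dimer is exactly C2-symmetric about z.
* `make_toy_map`: Gaussian rasterisation of any bead model onto a padded
  voxel grid.

What the synthetic fixtures do **not** emulate: real side-chain level
internal structure (bead clouds have a flat discrete-scatterer term
instead), inter-particle interference at finite concentration, beam
smearing, and buffer-subtraction artefacts. Passing the validation
establishes the correctness of the estimators and the refinement machinery
under the stated noise model, not instrument-specific accuracy on measured
data.

## Numerical choices and degenerate inputs

Curves must have strictly increasing q and positive σ (noise-free model
curves are flagged and refused as weighting sources). The Debye sinc is
evaluated as 1 at qr < 10⁻¹². The IFT normal equations use a Cholesky solve;
a non-positive-definite system falls back to the next α. Porod/Vc constant
subtraction clamps the constant to [0, min I]. Thresholds above the map
maximum, empty selections, and all-fixed body sets raise immediately with a
descriptive message.
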