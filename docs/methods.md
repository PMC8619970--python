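# Methods

## Model

Each lattice site is one cell of a microtumor surface, with NOTCH1 level
`N_i ≥ 0` and DLL4 level `D_i ≥ 0` in arbitrary concentration units.  The
2-D periodic lattice stands in for the (3-D) microtumor surface; there is
no cell division, movement, stochastic chemistry or explicit NICD cascade.
Cells are coupled juxtacrinely: the DLL4 input to cell *i* is the weighted
mean over its first Moore ring (8 touching cells, weight `w1`) and second
Moore ring (16 cells reachable by filopodia, weight `w2`):

    D̄_i = (w1 Σ_ring1 D_j + w2 Σ_ring2 D_j) / (8 w1 + 16 w2).

The second-ring contact is modelled as a constant reduced weight rather
than intermittent filopodial contact, which keeps the dynamics
deterministic.  The per-cell ODEs combine Hill activation of NOTCH1
production by neighbour DLL4, Hill repression of DLL4 production by own
NOTCH1, first-order turnover, and a bilinear cis-inhibition sink acting on
both species:

    dN_i/dt = R_N,i · D̄_i^h_act / (K_act^h_act + D̄_i^h_act) − γ_N N_i − k_cis N_i D_i
    dD_i/dt = R_D · K_rep^h_rep / (K_rep^h_rep + N_i^h_rep) − γ_D D_i − k_cis N_i D_i

This is the classic lateral-inhibition feedback loop written with explicit
receptor/ligand species: a DLL4-high cell drives its neighbours NOTCH1-high,
which silences their DLL4.  The homogeneous steady state is unstable in the
default regime, so spatial noise in the initial conditions grows into a
mosaic of isolated DLL4-high cells.  Per-cell variation of the maximum
NOTCH1 production rate `R_N,i` is the heterogeneity variable: cells whose
`R_N` is too small to raise `N` past the repression scale `K_rep` keep
producing DLL4 no matter what their neighbours present, and contiguous
groups of such cells appear as DLL4 clusters.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `rows × cols` | lattice size | 16 × 16 | cells |
| `w1`, `w2` | first/second-ring contact weights | 1.0, 0.25 | – |
| `R_D` | max DLL4 production rate | 1.0 | conc/time |
| `γ_N`, `γ_D` | degradation rates (set the time unit) | 1.0 | 1/time |
| `K_act`, `h_act` | NOTCH1-activation half-saturation / Hill exponent | 0.1, 4 | conc, – |
| `K_rep`, `h_rep` | DLL4-repression half-saturation / Hill exponent | 0.3, 4 | conc, – |
| `k_cis` | cis-inhibition rate constant | 0.1 | 1/(conc·time) |
| `R_N` mean | mean max NOTCH1 production rate (sweep axis) | 2.0, swept 1–3 | conc/time |
| `sigma` | CV of `R_N` across cells (sweep axis) | 0, swept 0–0.8 | – |
| `dt`, `tol`, `max_steps` | RK4 step, convergence tolerance, step cap | 0.05, 1e-6, 2·10⁵ | – |

The kinetic constants are calibration choices, not measurements: they were
fixed, once, so that the model sits in the biologically expected regime —
a uniform-`R_N` lattice reliably forms a defect-free checkerboard
(DLL4-high cells mutually non-adjacent, ~10–15 % of cells), while CV ≈ 0.8
at mean `R_N = 2` reliably fuses DLL4-high cells into clusters.  The two
requirements pull in opposite directions through `K_rep`: raising it
widens the pool of cells that cannot self-repress (bigger clusters under
heterogeneity) but also raises the equilibrium density of DLL4-high cells
until mosaic packing defects appear.  `K_rep = 0.3` with the reduced
second-ring weight `w2 = 0.25` satisfies both with margin; the choice was
verified over independent seed families.  Sharp (quartic) Hill functions
are required — with exponent 2 the homogeneous state is stable and no
pattern forms at any swept mean rate.

## Heterogeneity generator

`R_N` values are drawn per cell and held fixed for the simulation
(heterogeneity is static).  Two modes:

* **iid** — draws from a gamma distribution with the requested mean and
  CV (`shape = 1/sigma²`), then multiplied by `mean/sample_mean`.  The
  multiplicative recentering pins the sample mean *exactly* (the mean is
  the experiment's controlled variable), preserves nonnegativity and
  leaves the CV unchanged.  The gamma family is used instead of a
  truncated normal because a normal truncated at zero cannot realize CVs
  approaching 1 — truncation compresses the spread, which would silently
  shrink the variation axis of the phase diagram.  The phase-diagram
  "variation" axis is identified with this CV.
* **two_population** — a co-culture abstraction: a fraction of cells at
  `mean·(1+c)` and the rest at `mean·(1−c′)`, with `c′` computed from the
  realized label counts so the mean is exact.  Default contrast `c = 0.8`
  mimics mixing a NOTCH1-high with a NOTCH1-low line.  Labels are placed
  either by seeded permutation or by seeded multi-source region growing
  (`aggregated=True`), reproducing the tendency of mixed cell types to
  self-sort into same-type patches.

Initial conditions are iid uniform on [0, 0.1] for `N` and `D`; the
symmetric dynamics fix the homogeneous state exactly, so this noise is
what seeds patterning.

## Numerics

Fixed-step classical RK4, no adaptivity, for bit-reproducibility across
runs and platforms; identical seeds give identical results.  Integration
stops when the max-norm of the right-hand side falls below `tol` (an
equilibrium pattern) or at `max_steps` (recorded as non-converged, never
fatal inside a sweep).  At the default `dt = 0.05` the scheme is far
inside the stability region of the dynamics (turnover rate 1); states stay
nonnegative without clipping.  Typical convergence at defaults is a few
thousand steps (seconds per 16×16 lattice).  Non-finite states raise a
divergence error naming the step.  Sweep replicate seeds are derived
deterministically from the base seed via `SeedSequence((base, i, j, rep))`.

## Pattern readouts

Equilibrium DLL4 fields are binarized by optimal 1-D two-means (every
sorted split evaluated; deterministic, no initialization sensitivity);
fields with spread below 1e-9 are flagged degenerate with zero high cells.
The *checkerboard score* is the fraction of first-ring adjacent pairs with
both cells DLL4-high — exactly 0 when the high set is an independent set,
i.e. a perfect mosaic.  *Clusters* are connected components of the high
mask under periodic 8-connectivity (first-ring adjacency only; second-ring
contact does not join clusters), computed with `scipy.ndimage.label` plus
a union-find merge across the periodic seams.  The transition readout is
the median over ≥ 5 replicates of the largest cluster, with the
checkerboard→clusters transition called at median ≥ 3; both the mean DLL4
over all cells and over high cells are emitted for gray-scale maps.

## Invasion statistics

* Invasive fraction uses a *strict* inequality at the threshold ("over
  50 µm"): a depth of exactly 50 µm is non-invasive.
* The data-derived threshold is the midpoint between the two centroids of
  the optimal 1-D two-means split of the depths; at least two distinct
  depths are required.
* Group depth comparisons: Kruskal–Wallis (scipy, mid-rank tie
  correction, chi-square approximation), followed by Tukey–Kramer on the
  pooled mid-ranks (statsmodels `pairwise_tukeyhsd`; the Kramer form
  handles unequal group sizes).  The co-culture-vs-component comparison is
  a one-tailed Wilcoxon rank-sum test with alternative "co-culture median
  greater": exact null distribution when both groups have ≤ 20
  observations and no ties, normal approximation with tie correction
  otherwise.
* Region distributions: Pearson chi-square (no continuity correction) on
  the conditions × regions count table.  Region columns empty in every
  group are dropped with a warning and the degrees of freedom adjusted;
  an all-zero group row is an error; expected counts below 5 set a
  warning flag.  Both the 4-region table and any 2-category collapse can
  be tested through the same interface.

## Synthetic cohorts

The generator emulates the statistical structure of the invasion assays:
invasion depths are a two-component mixture — a truncated-normal
deformation mode (mean 25 µm, sd 10 µm, support [0, 50) µm; non-invading
microtumors still dimple the gel) and a shifted-lognormal invasive mode
`50 + LogNormal(log 30, 0.6)` µm, i.e. typically 65–110 µm — and each
record draws a region from a per-condition four-probability vector.
Preset conditions encode the qualitative levels of the multilayer assay:
homogeneous lines place < 5 % of mass at-or-past the collagen interface,
co-culture ~20 % at the interface and ~20 % inside collagen, DLL4
knockdown exactly 0 in both, single-line NOTCH1 knockdown ~30 % in
collagen with none trapped at the interface, double knockdown no collagen
enhancement, and wild-type/FOXA1-KO co-culture ~25 % in collagen.

What the generator does *not* emulate: depths and regions are drawn
independently per microtumor (no depth–region coupling), composition
labels are independent of depth, there is no imaging noise, no
microtumor-size covariate and no within-well correlation.  Tests passing
on these cohorts therefore validate the pipeline's arithmetic and
calibration, not any biological claim about real imaging data.

## Problem sizes

The test suite and analysis scripts use 16×16 lattices (the full model
size) for pattern and sweep claims, 8×8 or 5×5 lattices for integrator
oracles, sweeps of 4 × 6 grid points × 5 replicates, cohorts of 200–500
records for worked analyses and 10⁴ for recovery checks, and 1000
simulated null datasets for the type-I-error calibration of the
Kruskal–Wallis and chi-square tests.

## Known limitations

* The ODE system is a reconstruction of the standard lateral-inhibition
  architecture with cis-inhibition; rate constants are calibrated, not
  fitted to measurements, so equilibrium levels are in arbitrary units
  and only pattern-class statements (mosaic vs clusters, transition
  ordering) are meaningful.
* The checkerboard→cluster transition is read from a small lattice with
  five replicates; near the critical variation the median largest cluster
  is noisy, and the critical-sigma curve is resolved only to the sweep
  grid (0.1–0.2 CV steps).
* The two-population co-culture mode changes only `R_N`; it does not model
  differences in DLL4 production, adhesion or motility between lines.
* `JAG1` and other NOTCH ligands are out of scope; DLL4 is the only
  ligand species.
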