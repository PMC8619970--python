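# microtumor

Agent-based modelling of NOTCH1–DLL4 lateral inhibition in heterogeneous
bladder-cancer microtumors, together with the statistical pipeline used to
quantify microtumor invasion assays.

## The scientific problem

Bladder tumors commonly mix molecular subtypes (e.g. luminal-papillary and
basal/squamous), and mixed microtumors invade extracellular-matrix gels far
more aggressively than microtumors built from either line alone.  One
candidate mechanism is juxtacrine NOTCH1–DLL4 signalling: DLL4 presented by
a cell activates NOTCH1 in its contacting neighbours, and NOTCH1 activity
represses the cell's own DLL4 production.  This *lateral inhibition*
normally produces a checkerboard — isolated DLL4-high cells, each ringed by
NOTCH1-high cells.  When the maximum NOTCH1 production rate R_N varies from
cell to cell (as it does when a NOTCH1-high and a NOTCH1-low line are
mixed), the checkerboard can collapse into *clusters* of DLL4-high cells,
and DLL4 supports collective invasion.

This package provides both halves of that argument as tested, reusable
code:

1. **The lattice model.**  Cells on a periodic square lattice (16×16 by
   default) carry NOTCH1 level `N_i` and DLL4 level `D_i`, coupled through
   the DLL4 seen over the first and second Moore rings (8 + 16 contacts,
   the second ring down-weighted for filopodial reach):

   ```
   D̄_i    = (w₁ Σ_ring1 D_j + w₂ Σ_ring2 D_j) / (8 w₁ + 16 w₂)

   dN_i/dt = R_N,i · D̄_i^h / (K_act^h + D̄_i^h) − γ_N N_i − k_cis N_i D_i
   dD_i/dt = R_D · K_rep^h / (K_rep^h + N_i^h)  − γ_D D_i − k_cis N_i D_i
   ```

   Hill-type activation of NOTCH1 production by neighbour DLL4, Hill-type
   repression of DLL4 production by own NOTCH1, linear turnover, and a
   bilinear cis-inhibition sink.  Integration is fixed-step RK4 run to an
   equilibrium pattern.  Per-cell `R_N` heterogeneity with an exactly
   controlled mean is the experiment's variable.

2. **The invasion statistics.**  Per-microtumor records (condition,
   composition, invasion depth in µm, region of a multilayer gel) are
   summarized into invasive fractions (depth strictly over 50 µm), a
   clustering-derived depth threshold (optimal 1-D two-means, centroid
   midpoint), four-region occupancy, Kruskal–Wallis + Tukey–Kramer on
   ranks, one-tailed Wilcoxon rank-sum, and chi-square region comparisons.
   A synthetic-cohort generator with named per-condition presets stands in
   for imaging data so the whole pipeline is testable end to end.

## Worked example

The numbered scripts under `analysis/` reproduce the main computational
results and write tables under `results/`:

```sh
python analysis/01_simulate_checkerboard.py   # mosaic at uniform R_N
python analysis/02_phase_sweep.py             # transition map (~1 min)
python analysis/03_synthesize_cohorts.py      # preset cohorts
python analysis/04_invasion_analysis.py       # invasion statistics
```

`02_phase_sweep.py` prints the replicate-median largest DLL4 cluster over
the (mean R_N × variation CV) grid:

```
          0.0  0.1  0.2  0.4  0.6  0.8
r_n_mean
1.0       1.0  1.0  1.0  2.0  3.0  8.0
1.5       1.0  1.0  1.0  1.0  2.0  6.0
2.0       1.0  1.0  1.0  1.0  1.0  4.0
3.0       1.0  1.0  1.0  1.0  1.0  3.0
```

Reading: with no variation (first column) every mean rate yields a perfect
checkerboard (largest cluster 1).  Moving right along a row, variation in
R_N at a *fixed mean* eventually fuses DLL4-high cells into clusters, and
the variation needed for that transition (median cluster ≥ 3) grows with
the mean production rate — 0.6 at R_N = 1 versus 0.8 at R_N ≥ 1.5.

`04_invasion_analysis.py` prints, among other things:

```
clustering-derived invasion threshold: 56.1 um (definition: depth over 50 um)
Kruskal-Wallis across conditions: H=73.0, p=9.93e-14
chi-square on region occupancy: X2=331.2, dof=18, p=1.74e-59
```

i.e. the unsupervised two-cluster split of the bimodal depth distribution
recovers the 50 µm invasive/non-invasive boundary, and both depth and
region distributions differ strongly across conditions.

A `microtumor` console script exposes the same stages
(`simulate`, `sweep`, `synth`, `analyze-invasion`) with YAML configs and
run manifests; see `microtumor --help`.

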