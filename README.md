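# dvpattern

Quantitative analysis of how cells interpret the BMP signaling gradient
along the zebrafish dorsoventral (DV) axis during gastrulation.

Nuclear phosphorylated Smad5 (pSmad5) forms a ventral-to-dorsal gradient
that patterns BMP target genes into nested expression domains. Three
readout models could explain how a cell decides to express a target gene:

- **threshold** — the local pSmad5 *level* exceeds a gene-specific
  concentration threshold;
- **slope** — the local spatial *derivative* of the gradient exceeds a
  gene-specific criterion;
- **duration** — BMP signaling has lasted longer than a gene-specific time.

`dvpattern` implements the full measurement pipeline that discriminates
these models — from 3-D nuclei point clouds to expression-boundary calls —
together with a synthetic-embryo generator with known ground truth, so
every stage is testable without imaging data.

## What the pipeline does

1. **Synthesize** (`dvpattern.synthetic`, `dvpattern.gradients`): nuclei
   uniform on a spherical cap (radius 350 μm, cap 120°, n = 4,000), pSmad5
   from a canonical monotone gradient G(θ) (wild-type, laterally expanded
   *chordin*-mutant, or flat *bmp7*-mutant), FISH channels from a chosen
   readout model, plus clipped Gaussian measurement noise (σ = 5 A.U.).
   Dissociated-cell assays (uniform 5 / 20 ng/ml BMP2/7 doses) and
   ligand-pulse experiments are simulated with the same models.
2. **Orient and profile** (`dvpattern.geometry`, `dvpattern.profiles`):
   least-squares sphere fit, ventral-pole estimation from the pSmad5 high
   point, DV/AV angle assignment, per-channel mean-intensity profiles in a
   40-μm band of cells, robust lowess smoothing and slope estimation, 8×8
   AV×DV expression heat maps, 4,800-triangle surface averages.
3. **Call boundaries** (`dvpattern.boundaries`): a gene's expression
   boundary is where its profile falls to 10% of maximum; at that angle the
   pSmad5 level (A.U. and % of profile max) and slope magnitude
   (A.U./degree) are read out.
4. **Cluster and discriminate** (`dvpattern.clustering`,
   `dvpattern.discrimination`): genes are grouped by DV expression reach;
   Welch t-tests and relative-deviation statistics compare boundary
   readouts between wild-type and *chordin*-mutant cohorts (a threshold
   readout predicts level invariance under gradient reshaping), pulse
   experiments test the duration model, and uniform-dose assays test
   concentration dependence.

## Worked example

```python
from dvpattern import simulate_cohort, quantify_cohort

embryos = simulate_cohort("wild_type", 5, seeds=[1, 2, 3, 4, 5])
calls, quants = quantify_cohort(embryos, genes=["sizzled", "foxi1", "bambia"])
summary = calls.groupby("gene")[
    ["boundary_angle_deg", "level_pct_max", "slope_au_per_deg"]
].mean()
print(summary.round(2))
```

prints

```
         boundary_angle_deg  level_pct_max  slope_au_per_deg
gene
bambia               140.55           7.57              0.38
foxi1                108.34          24.39              0.79
sizzled               75.79          59.44              1.34
```

Each row is a cohort mean over five synthetic wild-type embryos: the
*sizzled* boundary sits near 75° DV where pSmad5 is ~60% of its ventral
maximum with slope ~1.4 A.U./degree, *foxi1* near 108° at ~25%, and
*bambia* near 140° at ~7% — the pipeline reads back the levels and slopes
the generator encoded, through sphere fitting, orientation, banding,
smoothing and boundary detection.

A command-line interface wraps the same stages:

```sh
dvpattern simulate --genotype wild_type --n-embryos 20 --seed 1 --out wt/
dvpattern quantify wt/*.csv --out quant_wt/
dvpattern discriminate --calls-wt quant_wt/boundary_calls.csv \
    --calls-mut quant_chd/boundary_calls.csv --out verdict.json
```

## Layout

```
src/dvpattern/
  gradients.py        # monotone Hermite gradient models + canonical profiles
  synthetic.py        # embryo / dissociated-assay / pulse generators
  geometry.py         # sphere fit, angles, registration, surface patches
  profiles.py         # normalization, band profiles, lowess, heat maps
  boundaries.py       # boundary detection and pSmad5 readouts
  clustering.py       # DV expression-cluster assignment
  discrimination.py   # threshold / slope / duration model comparison
  pipeline.py         # cohort-level orchestration
  io.py, cli.py       # delimited-text I/O and the dvpattern CLI
docs/methods.md       # model, parameters, numerical choices, limitations
```
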