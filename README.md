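# mdspectra

Replica-averaged post-processing and visualization of GROMACS
molecular-dynamics outputs.

MD studies increasingly run several independent replicas of each
simulation condition, but most plotting workflows handle one run at a
time.  `mdspectra` takes the text files GROMACS already produces —
grace-annotated `.xvg` time series, `.xpm` matrices (DSSP secondary
structure, `gmx mdmat` distance matrices) and plain `.dat` tables —
aggregates any number of replicas per group, and emits
publication-style figures with numeric CSV sidecars.  It never reads
trajectories or topologies: the per-frame computation stays in GROMACS
(`gmx rms`, `gmx sasa`, `do_dssp`, `gmx mindist`, `gmx anaeig`, ...),
and this package does the statistics and the plots.  It is aimed at
people analysing protein, ligand and complex simulations who want
replica statistics without writing scripts.

## What it computes

- **Time-dependent profiles** (RMSD, RMSF, Rg, SASA, H-bonds, salt
  bridges, temperature, pressure, density): per timepoint the
  arithmetic mean across replicas, x̄(t) = (1/n) Σₖ xₖ(t), with the
  sample standard deviation s(t) (n−1 denominator) drawn as a shaded
  band.  Every time-dependent analysis also gets a kernel-density
  companion plot.
- **Gaussian KDE** in 1D and 2D:
  f̂(x) = (1/(n·h·√(2π))) Σᵢ exp(−(x−xᵢ)²/(2h²)), with Silverman's
  rule-of-thumb bandwidth h = 0.9·min(σ̂, IQR/1.349)·n^(−1/5) by
  default and a product kernel in 2D.
- **Secondary structure** from DSSP `.xpm` grids: per-frame class
  probability P₍ᵢ,ₛ₎ = N₍ᵢ,ₛ₎/N_total × 100 and fraction
  F₍ᵢ,ₛ₎ = N₍ᵢ,ₛ₎/N_total over the six classes α-helix, β-sheet,
  coil/loop, turn, bend, 3-helix; boxplot summaries and an `.xlsx`
  export with a CSV twin.
- **Circular dihedral statistics**: mean direction
  atan2(mean sin θ, mean cos θ) for ligand dihedrals and χ1/χ2
  rotamers, pooled (not averaged) φ/ψ Ramachandran densities,
  histograms and dot plots.
- **Interactions**: protein–ligand contact counts, hydrophobic-residue
  subsets, minimum-distance traces with advisory dissociation flags.
- **Spatial views**: ligand occupancy maps on the box XY plane,
  inter-residue distance-matrix heatmaps, PCA projection scatter plots
  colored by simulation progression.

## Worked example

Generate a seeded synthetic example-data tree (two simulation groups,
three replicas each, in the exact GROMACS dialects), then run the RMSD
analysis:

```bash
mdspectra fixtures --kind all --seed 7 --out exampledata
mdspectra rmsd --config rmsd.yaml --out results
```

with `rmsd.yaml`:

```yaml
groups:
  - label: simulation1
    replicas:
      - exampledata/simulation1/rmsd/replica1.xvg
      - exampledata/simulation1/rmsd/replica2.xvg
      - exampledata/simulation1/rmsd/replica3.xvg
  - label: simulation2
    replicas:
      - exampledata/simulation2/rmsd/replica1.xvg
      - exampledata/simulation2/rmsd/replica2.xvg
      - exampledata/simulation2/rmsd/replica3.xvg
```

The command prints the artifacts it wrote:

```
figure: results/rmsd.png
kde_figure: results/rmsd_kde.png
kde_sidecar: results/rmsd_kde.csv
log: results/rmsd.log
sidecar: results/rmsd_summary.csv
```

`rmsd_summary.csv` holds one row per timepoint and group:

```
group,axis,mean,sd
simulation1,0,0.794017995542,0.187943260649
simulation1,0.01,0.81671218501,0.0970760990252
simulation1,0.02,0.792409903043,0.149467448782
...
```

`axis` is simulation time in ns, `mean` the across-replica mean RMSD
in nm at that time, and `sd` the sample standard deviation of the
three replicas — the line and the width of the shaded band in
`rmsd.png`.  The KDE sidecar holds the density curve of the pooled
RMSD values per group.

The same pattern covers all twenty analyses
(`mdspectra --help` lists them); secondary-structure runs additionally
write `ss_fraction_table.xlsx`, and the angular analyses write circular
means and pooled angle tables.

Library use mirrors the CLI:

```python
from mdspectra import read_xvg, to_nanoseconds, ReplicaSet, summarize

series = [to_nanoseconds(read_xvg(p).to_timeseries()) for p in paths]
trace = summarize(ReplicaSet("simulation1", series))
trace.mean, trace.sd  # per-timepoint statistics
```

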