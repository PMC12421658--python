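# Methods

## Scope and data model

`mdspectra` post-processes GROMACS-generated text outputs only:
grace-annotated `.xvg` tables, `.xpm` pixel matrices and plain `.dat`
tables.  Trajectory and topology formats are deliberately out of
scope — GROMACS computes the per-frame quantities; this package owns
the replica statistics and the visualisation.  All numeric columns are
parsed as double-precision floats, including frame indices, so every
downstream contract is uniform.

Of the grace directive grammar only `title`, `xaxis label`,
`yaxis label` and `s<N> legend` are interpreted; all other `@` lines
are preserved verbatim so a write/read cycle is the identity on the
file's metadata and on values to at least 12 significant digits
(values are written with 17 significant digits, which round-trips IEEE
doubles exactly).

## Replica statistics

A *group* is one simulation condition; its *replicas* are independent
repetitions.  Summaries are purely descriptive: per timepoint the
arithmetic mean across replicas and the sample standard deviation
(n−1 denominator).  With one replica the band is defined as zero.
The sample estimator was chosen because replicas are a small
independent sample from the distribution of trajectories; no
inferential statistics (CIs, tests) are attempted.

Replicas whose time axes disagree are first truncated to the
overlapping time range and resampled onto the coarsest replica's grid
by nearest-neighbour lookup.  Nearest-neighbour (rather than linear
interpolation) keeps every summarised value an actual simulation
sample; the choice matters only when grids are offset by a fraction of
a step, where either convention is defensible.  Time axes are
converted to ns for plotting; the unit is read from the `.xvg` x-axis
label and defaults to ps (the GROMACS convention) when absent.  RMSF
profiles keep their residue/atom index axis unconverted.

## Kernel density estimation

The 1D estimator is the standard Gaussian KDE

    f̂(x) = 1/(n h √(2π)) Σᵢ exp(−(x−xᵢ)²/(2h²))

evaluated on 512 evenly spaced points spanning the observations ± 4h,
so the trapezoidal integral is 1 to within a few percent.  The default
bandwidth is Silverman's rule of thumb,
h = 0.9·min(σ̂, IQR/1.349)·n^(−1/5) — a standard, unopinionated
default — and is user-overridable for exact matching against other
tools.  A constant sample has no data-driven bandwidth; the estimator
falls back to h = 1 with a logged warning rather than failing.
The 2D form is the product Gaussian kernel with per-axis Silverman
bandwidths on a 128×128 grid.

The kernels are non-periodic.  Dihedral data is pre-wrapped to
[−180°, 180°) before estimation; an optional ±360° augmentation flag
duplicates the sample at shifted copies for edge correction near the
wrap point (off by default, and the normalisation keeps the original
n).  Von Mises (periodic) kernels are a known limitation, not
implemented.

## Secondary structure

DSSP codes map onto six classes: H→α-helix, G→3-helix, E→β-sheet,
B→β-sheet, T→turn, S→bend, C/`~`/blank→coil/loop, I→coil/loop.
Folding the isolated β-bridge (B) into β-sheet and the rare π-helix
(I) into coil/loop keeps the six-class partition exhaustive, which is
what guarantees the per-frame percentages sum to exactly 100; the
mapping is user-overridable.  `do_dssp` grids put residues on y and
frames on x; orientation is auto-detected from axis tick counts when
present and assumed frames-on-x otherwise, with an explicit override
parameter.

Per-frame probability and fraction are plain counting:
P₍ᵢ,ₛ₎ = N₍ᵢ,ₛ₎/N_total×100 and F₍ᵢ,ₛ₎ = P₍ᵢ,ₛ₎/100.  For boxplots,
frames from all replicas of a group are pooled (each frame is one
observation of the per-frame probability); quartiles use linear
interpolation (type 7, the numpy default) and whiskers are Tukey's
1.5·IQR fences.  Fraction-over-time curves average the per-frame
fractions across replicas.  The export writes `.xlsx` plus a CSV twin
with all six class columns always present.

## Circular statistics

Angles live on [−180°, 180°), matching `gmx angle`/`gmx rama` output.
The mean direction is atan2(mean sin, mean cos); the resultant length
R measures concentration.  When R < 1e−9 (e.g. {0°, 180°}) the mean
direction is genuinely undefined, and the package returns NaN with a
RuntimeWarning instead of an arbitrary angle — silent garbage would
corrupt averaged rotamer traces.  φ/ψ observations from multiple
replicas are pooled by concatenation, never averaged: the pooled cloud
represents the full conformational space sampled, and averaging angles
across replicas frame-by-frame would invent conformations no replica
visited.  Per-replica Ramachandran maps are emitted alongside the
combined one.

## Interactions and spatial analyses

Contact and minimum-distance traces reuse the replica summary.
Hydrophobic contacts are selection + summation: one contact-count
`.xvg` per residue per replica, summed over the user's residue
selection per timepoint, then averaged across replicas — the only
residue-resolved signal available without topology access.  Frames
whose mean minimum distance exceeds 0.6 nm (configurable) are flagged
in the run log as potential dissociation events; the flag is advisory
only and never alters data or plots.

Occupancy maps pool ligand positions from all frames, discard z
(projection onto the box XY plane — per-atom z averaging would not
produce a 2D density) and bin on a regular grid spanning the **box**
dimensions, not the data range, so the axes are physical coordinates.
Counts are normalised by their maximum, giving a relative density with
peak 1.  Out-of-box coordinates are wrapped modulo the box length with
a warning, treating them as periodic images.  PCA is consumed, not
computed: the package reads 2D projections as written by
`gmx anaeig -2d` and never touches the covariance matrix.

Distance matrices come from `gmx mdmat` `.xpm` files whose legend bins
distances into colour levels labelled "lo–hi"; each cell maps to its
bin midpoint, the unbiased representative of a uniform bin.
Single-number legends map to that number.

## Synthetic data generator

The `fixtures` module emulates the statistical shape of each input
dialect with known ground truth: time series are deterministic trends
plus Gaussian noise; DSSP grids are categorical draws with recorded
exact per-frame counts; dihedrals are von Mises draws around a known
location; distance matrices have chosen legend levels; ligand
coordinates are Gaussian clouds at chosen hot spots inside the box;
projections are drifting point clouds.  Default conditions mirror a
typical small-peptide study: 50 ns sampled every 10 ps (5001 frames),
3 replicas per group, ~40 residues, a ~5.14 nm box, thermostat-scale
noise (e.g. 2.5 K around 300 K).  Each fixture uses its own PRNG
stream derived from (seed, kind, replica), so any single replica file
is independently reproducible.  Headers deliberately vary (ps/ns
labels, legends present or absent) to exercise the parsers.

What the fixtures do **not** emulate: autocorrelation along the
trajectory, physically consistent cross-property correlations,
force-field semantics, or rare-event kinetics.  Passing tests
therefore demonstrate correctness of the statistics and parsing, not
realism of any simulated system.

## Numerical choices and degenerate inputs

- Quartiles: linear interpolation (type 7), exposed as an option.
- Alignment tolerance: axes count as "identical" when they agree
  pointwise within 1% of the sampling interval.
- Wrap convention: +180° maps to −180° (half-open interval).
- Empty KDE input, empty replica sets, non-square distance matrices,
  negative counts/distances and unknown units all raise typed errors;
  empty time windows warn and return an empty series.
- Sidecar CSVs are written with 12 significant digits; identical
  inputs and configuration give byte-identical sidecars.

## Problem sizes in the checks

The test suite and the acceptance script run on generated data sized
to exercise each property cleanly: 200–500 observations for the KDE
oracles, 100 frames × 30 residues for secondary structure,
5 replicas × 10,000 points for replica statistics, 10,000 draws for
circular-mean recovery, 10,000 points × 100 bins for occupancy, and a
2-group × 2-replica tree of 41–61-frame inputs for the end-to-end
command sweep.

## Known limitations

- No periodic (von Mises) kernels; edge correction is by data
  augmentation only.
- Only GROMACS conventions are guaranteed; CPPTRAJ-style `.dat`
  time-value tables parse, but other tools' headers are not handled.
- DSSP analysis is per-frame only; per-residue timelines are not
  produced.
- The hydrophobic-contact contract requires per-residue input files;
  a combined multi-residue file cannot be decomposed without topology
  information.
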