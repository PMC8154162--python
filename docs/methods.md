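# Methods

This note records the models, conventions and numerical choices behind
nanoagg, what the synthetic generator does and does not emulate, and the
package's known limitations.

## Coordinates, boxes, units

All coordinates are nanometres internally (PDB Å are converted at the
I/O boundary), masses are atomic mass units, times nanoseconds for
trajectories and hours for release curves, densities g/cm³ (conversion
constant 1 amu = 1.66053907×10⁻²⁴ g). Only orthorhombic periodic boxes
are supported; triclinic GRO box lines are rejected rather than
approximated, since none of the implemented analyses require them.
Minimum-image displacements use the floor convention, mapping each
component into [−L/2, L/2).

## Probe-series volume and density

The aggregate volume is measured indirectly. For probe radius r, a cell
of a regular grid (default spacing 0.05 nm; cells exactly tile the box)
is probe-open when no solute atom centre lies within (vdW radius + r) of
the cell centre. Open cells are computed from a single signed clearance
field F = minᵢ(dᵢ − Rᵢ), evaluated once per frame and thresholded per
probe radius, with a cell-list-style local update per atom for
near-linear scaling. The external region is the subset of open cells
reachable from the box faces by 6-connected flood fill; interior voids
are thereby excluded *deterministically* for every probe radius, a
strengthening of the common heuristic of relying on probes too large to
enter the voids. V_ext(r) is evaluated at the default radii
{0.3, 0.4, 0.5, 0.6, 0.8} nm, fit by least squares with a straight line
(a quadratic is available behind `fit_degree=2`; the fit form and R² are
reported), and extrapolated to r = 0. The aggregate volume is the box
volume minus that intercept.

Two systematic effects partially cancel and are worth knowing about.
For a ball-like body, V_box − V_ext(r) grows like (R_eff + r)³, so the
linear extrapolation of a convex series *undershoots* the r = 0 volume
by a few percent at aggregate sizes of ~3 nm; conversely the raw union
of atom spheres *overshoots* the visually sensible aggregate boundary
through surface bumps and misses smoothed-over crevices. The Monte-Carlo
union estimator (`mc_volume_oracle`, uniform samples against the sphere
union, bucket-sorted for speed) therefore brackets the probe-series
value from the other side; the two measures on a packed aggregate differ
by ~6%, and the packer centres their geometric mean on the target so
that each individual measure stays within its tolerance.

Degenerate inputs: an empty atom group returns the box volume; fewer
than 10 grid cells along any box edge is an error; a non-monotone
V_ext(r) series beyond one cell volume warns; a negative extrapolated
aggregate volume is an error.

## Synthetic systems

The generator emulates the *statistical structure* of
polystyrene–curcumin aggregate configurations, not their physics: no
force field, no dynamics, no energetics.

- **Chains.** A styrene unit is two beads (backbone "CB" + phenyl-like
  side bead "CG") of 52.075 amu each, so one unit totals 104.15 amu.
  Free chains (`build_atactic_chain`) are self-avoiding random walks
  with 0.25 nm bonds and an excluded-volume distance of 0.30 nm between
  non-bonded beads. Stereo labels (A/B, residue names STYA/STYB) are
  i.i.d. Bernoulli draws at ratio 0.5, emulating atactic random joining;
  the label sequences pass a runs test for randomness.
- **Bead radius.** The bead vdW radius defaults to 0.38 nm. This is the
  covering radius of the packing lattice: with 2 beads per unit, 1120
  beads must tile ≈92 nm³ to reach 1.05 g/cm³, which requires per-bead
  spheres of at least ≈0.38 nm; smaller beads cannot reach melt-like
  density with any arrangement of their union.
- **Aggregates.** `pack_aggregate` lays beads on a jittered cubic
  lattice (spacing set by the target volume per bead, jitter σ=0.04 nm)
  inside a ball, orders the sites serpentine-fashion so each chain's 80
  beads form a compact sub-coil stuck to its neighbours, then rescales
  the configuration radially until the measured density matches the
  target (coarse-grid passes first, then refinement at the 0.05 nm
  analysis grid; convergence on the geometric mean of the probe-series
  and Monte-Carlo densities, tolerance 5%). Within-chain bond length in
  packed aggregates is therefore the lattice spacing (≈0.43 nm) rather
  than the free-chain 0.25 nm — the packer trades bond-length fidelity
  for density fidelity, which is what the volume analyses consume.
- **Guests.** A guest molecule is 13 beads of 368.38/13 amu (two
  hexagonal rings C1–C6 and C7–C12 of radius 0.14 nm bridged by a linker
  bead CD; vdW radius 0.21 nm). `dispersed` places guests at random
  interior points, `shell` just outside the host surface. After
  placement, host beads within 0.55 nm of a guest bead are pushed out to
  that distance (three relaxation sweeps), so guests sit in
  vdW-like contact with the chains instead of interpenetrating them;
  0.55 nm ≈ the bead contact distance 0.38 + 0.21 nm. This gives the
  contact-shell structure (g(r) first peak at ≈0.55 nm) that the rdf and
  coordination analyses measure.
- **Hydration shell.** Water points (18.015 amu, single site "MW") are
  placed so their nearest host-atom distance lies in (0.40, 0.50] nm —
  inside the 0.5 nm hydration shell, outside every bead. No bulk phase
  and no interior water is generated, mirroring a dry hydrophobic core.
- **Release curves.** Linear at `rate` %/h up to the changepoint, then a
  continuous saturating exponential toward `plateau` (default 100%) with
  an explicit time constant `tau` (default 12 h). Sampling is t = 0 plus
  39 geometrically spaced points from 0.25 h to 96 h, emulating frequent
  early sampling out to four days. `tau=None` selects the
  slope-continuous exponential instead; note that for small
  rate×changepoint relative to the plateau that variant degenerates into
  a single near-exponential with no identifiable changepoint, which is
  why an explicit time constant is the default for a generator whose
  purpose is curves with a known changepoint.

What passing tests on these systems show: the analysis chain recovers
construction parameters (density, changepoints, labels, counts) from
configurations with realistic sizes, densities and contact structure.
What they do not show: correctness of any claim that depends on
equilibrium physics — real aggregates have chain-conformational
statistics, guest orientations (e.g. genuinely π-stacked dimers), and
interfacial water structure that no geometric generator reproduces.

## Geometry analyses

R_g is mass-weighted by default and computed after making each molecule
whole across the periodic boundary and greedily shifting molecules to
the image nearest the group's running centre of mass (valid while each
molecule spans less than half the box). The plateau detector fits a
least-squares slope in every sliding window (default 20 ns, slope
tolerance 0.002 nm/ns, both exposed) and reports the earliest time from
which *all* subsequent windows are flat; it is invariant to time shifts.
Molecular clustering is single-linkage over inter-atomic contacts
(default cutoff 0.45 nm, the heavy-atom contact convention) via a
periodic KD-tree and union-find.

Density slice maps rotate the group into its gyration-tensor principal
frame (eigenvalues descending; each eigenvector's largest-magnitude
component made positive for a reproducible orientation). The "thickest
point" is operationalised as the maximum of the 1D mass profile along
the slab normal, binned at 0.1 nm. Atom masses are point-binned into 2D
cells (default 0.1 nm, slab thickness 0.8 nm), so Σ(cell value × cell
volume) equals the slab mass exactly; maps of coarse bead systems are
correspondingly grainy at sub-bead cell sizes.

Water classification: shell = within 0.5 nm of any host atom centre
(checked first), interior = inside the flood-fill-excluded void region,
bulk otherwise.

## Contact analyses

g(r) uses periodic KD-tree pair counting in 0.01 nm bins with the
partner density taken over the whole box — the common MD-tool
convention, stated explicitly because local-density normalisations give
different absolute values. n(r) comes from the same cumulative counts,
so at a cutoff on a bin edge it equals the direct coordination count
exactly; the direct counter is inclusive at the cutoff (an atom at
0.71 nm is outside a 0.7 nm cutoff). Ring planes are best-fit planes
(smallest principal component of the ring atoms, rings made whole
first); collinear rings are rejected by name. Stacking thresholds
default to d_max = 0.5 nm and 30°, reported with every record. Guest
burial thresholds are 0.1/0.9 with a default contact cutoff of 0.7 nm
(bead contact distance plus slack; for atomistic systems a tighter
cutoff such as 0.45 nm is appropriate and exposed in the config).

## Loading and release

DLC divides by polymer mass, EE by the drug mass offered in the feed;
the "wt % load" convention is drug relative to polymer weight. The two
come from independent measurements, so a (DLC, EE) pair for one sample
need not be mutually consistent with any single set of masses.
Calibration inversion flags concentrations outside the calibrated range
(default 0.8–6 µg/mL) and rejects readings below the blank. Cumulative
release applies no depletion correction (aliquots are returned to the
vessel) and rejects curves exceeding 110%.

The kinetic fit scans every candidate changepoint with at least three
points on each side: the early segment gets a through-origin line
(cumulative release starts at zero), the late segment a saturating
exponential with asymptote capped at 100% and *continuity enforced at
the changepoint* — cumulative release is continuous, and the constraint
is also what makes the changepoint statistically identifiable. Total
RSS selects the changepoint, with near-ties resolved toward the latest
candidate (maximal extent of the zero-order phase). A burst flag is
raised when an unconstrained early fit has intercept above 5%.

## Known limitations and open points

- The probe-series extrapolation is linear by convention; its small
  convexity bias on ball-like bodies is documented above and bracketed
  by the Monte-Carlo cross-check rather than corrected.
- A printed reference density of ~1.12 g/cm³ for a 14×40-unit styrene
  aggregate of ~94 nm³ is internally inconsistent with the standard
  104.15 amu monomer mass (which yields ≈1.03 g/cm³ at that volume);
  end-group masses could account for part of the gap. The package
  computes densities from its own masses and volumes and does not
  attempt to reconcile externally reported pairs.
- File round-trips preserve coordinates to format precision (GRO:
  3 decimals in nm) and group tags via residue names, but masses of
  non-synthetic residues are resolved from the element table, so exotic
  masses do not survive a GRO/PDB round-trip.
- The rdf "first peak" is the global maximum of g(r); for very sparse
  selections single-pair bins can dominate below the contact distance.
- Whether a combined-group R_g or a per-chain statistic is wanted is
  analysis-dependent; the combined group is the default and per-molecule
  selections can be passed explicitly.
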