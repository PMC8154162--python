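# nanoagg

Structural analysis of polymer-nanoparticle aggregates and their drug
cargo: probe-extrapolated aggregate volume and mass density, gyration
analysis with aggregation-plateau detection, 2D density slice maps,
radial distribution functions and coordination numbers, π-stacking and
guest-localization detection, and drug-loading (DLC/EE) plus
zero-order release-kinetics analytics. A deterministic synthetic-systems
generator produces configurations with the statistical structure of
polystyrene–curcumin aggregate simulations (atactic 40-unit oligomer
chains, coiled-chain aggregates near 1.05 g/cm³, dispersed or
shell-placed guest molecules, explicit hydration-shell waters), both for
method development and as oracle fixtures with known answers.

## Who this is for

Researchers analysing molecular configurations of amorphous polymer
aggregates — especially hydrophobic nanoparticle cores hosting small-drug
guests — who need the structural observables above without re-running
molecular dynamics, plus the wet-lab side arithmetic (loading capacity,
encapsulation efficiency, release kinetics) in the same toolbox.

## The core methods

**Indirect volume/density.** An irregular aggregate has no usable radial
density profile. Instead, for a series of probe radii *r*, the external
volume V_ext(*r*) is measured on a regular grid: a grid cell is probe-open
if no solute atom lies within (vdW radius + *r*) of it, and the external
region is the probe-open set reachable from the box faces (a 6-connected
flood fill, which excludes interior voids deterministically). A straight
line fit to V_ext(*r*) extrapolated to *r* = 0 gives the true external
volume; then

    V_aggregate = V_box − V_ext(0),   ρ = m_host / V_aggregate.

A Monte-Carlo union-of-spheres estimator serves as an independent
cross-check throughout.

**Gyration and aggregation time.** R_g = √(Σᵢ mᵢ|rᵢ − r_cm|²/Σᵢ mᵢ) of
the combined chains (molecules made whole across periodic boundaries),
per frame; the aggregation plateau onset is the earliest time from which
every sliding window has least-squares slope |k| ≤ tolerance.

**Contacts.** g(r) from minimum-image pair histograms normalised by the
4πr²Δr shell volume and the whole-box partner density, with the
cumulative coordination n(r); π-stacking-like dimers are ring pairs with
centroid distance ≤ d_max and best-fit-plane angle ≤ angle_max; guest
localization is classified interior/surface/aqueous by the fraction of
guest atoms in host contact.

**Loading and release.** DLC = 100·m_drug/m_polymer,
EE = 100·m_entrapped/m_feed; release curves are built from calibrated
absorbances and fit with a zero-order phase (release = k·t) followed by a
continuous saturating exponential, the changepoint chosen by residual
minimisation.

## Worked example

```python
import nanoagg as na

system = na.pack_aggregate(na.AggregateSpec(seed=7, guest_mode="none", n_guests=0))
host = na.select(system, tag="host")
res = na.probe_series_volume(system, host, radii=(0.3, 0.4, 0.5, 0.6),
                             grid_spacing=0.05)
print(f"aggregate volume: {res.aggregate_volume:.1f} nm^3")
print(f"mass density:     {res.density:.3f} g/cm^3")
print(f"R_g:              {na.radius_of_gyration(system, host):.2f} nm")
```

prints

```
aggregate volume: 89.6 nm^3
mass density:     1.081 g/cm^3
R_g:              2.06 nm
```

— the 14-chain aggregate packed at a 1.05 g/cm³ target is measured back
at 1.081 g/cm³ by the probe-series procedure (within its ~5% band; the
Monte-Carlo union cross-check gives ≈1.02), its volume is ≈90 nm³, and
the compact blob has a gyration radius just above the uniform-ball value
√(3/5)·R. The `examples/` directory holds one short narrative script per
capability (building aggregates, volume/density, gyration plateau,
rdf/coordination, stacking/localization, loading/release); each prints
its numbers with a line on what they mean. A thin CLI mirrors the
library: `nanoagg synth|volume|gyration|densmap|cluster|rdf|stacking|
localize|loading|release|pipeline`.

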