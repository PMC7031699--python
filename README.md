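# lipidkinetics

Analysis of protein–lipid interactions in coarse-grained membrane
simulations: contact kinetics with dissociation-rate estimation, lipid
binding-site mapping and pose scoring, spatial lipid statistics, lipid
interplay, and one-dimensional umbrella-sampling free-energy analysis —
together with a synthetic membrane-trajectory generator with *known*
binding kinetics, so that every stage of the pipeline can be validated
against ground truth without microsecond-scale MD data.

The package is aimed at people studying how specific lipids (PIP2, GM3,
cholesterol, …) bind membrane receptors such as GPCRs in complex,
asymmetric, in vivo-mimetic bilayers.

## The statistics at the core

**Dual-cutoff contact kinetics.** A continuous contact between a lipid and
a residue starts when the lipid's centre of mass comes closer than 0.55 nm
to the residue's centre of mass and ends only when it moves beyond 1.4 nm.
The hysteresis suppresses boundary rattling, so contact durations reflect
genuine unbinding. For Markovian unbinding the durations are exponential
and their histogram decays as

&nbsp;&nbsp;&nbsp;&nbsp; N(t) = A·e<sup>−k_off·t</sup>,

fitted here by weighted nonlinear least squares with a case-resampling
bootstrap CI and the closed-form rate 1/⟨t⟩ as an independent cross-check.

**Binding-site mapping.** Residues whose mean contact duration clears a
scale-free threshold (3× the median positive residue duration) are
clustered by spatial adjacency; connected patches of two or more residues
are binding sites. Bound poses at a site are ranked by the sum over beads
of a 3D bead-density score, mirroring how a most-representative bound
conformation is chosen for umbrella sampling.

**Spatial statistics.** Surface RDFs measure lipid COM distances to the
nearest receptor bead, normalized by a Monte-Carlo estimate of each
distance shell's accessible in-plane area so g(r) → 1 in bulk; 2D density
maps are per-leaflet time averages; area per lipid comes from a periodic 2D
Voronoi tessellation of representative beads (glycerol midpoint GL1/GL2,
sphingosine midpoint AM1/AM2, sterol ROH) plus receptor beads.

**Lipid interplay.** The Pearson correlation of per-repeat mean interaction
durations of two co-habiting species classifies their coupling as
synergistic (P.C.C > 0) or competing (P.C.C < 0).

**Umbrella-sampling PMFs.** Harmonic windows (default spacing 0.05 nm,
force constant 1000 kJ/mol/nm²) are recombined with the weighted histogram
analysis method (WHAM); statistical errors come from a Bayesian bootstrap
(Dirichlet-weighted samples per window), and K_d follows from the
bound-region configurational integral referenced to the 1 M standard state
with an explicit, recorded convention.

**Synthetic ground truth.** The generator renders a static multi-helix
receptor in an asymmetric ten-species bilayer (upper leaflet
POPC/DOPC/POPE/DOPE/Sph/GM3/Chol, lower leaflet
POPC/DOPC/POPE/DOPE/POPS/DOPS/PIP2/Chol), lipids diffusing laterally, and
designed binding sites with exactly exponential residence times; every
binding and unbinding transition is recorded in a ledger that downstream
estimators are tested against.

## Worked example

`examples/03_fit_koff.py` designs one PIP2 site with a true dissociation
rate of 6 μs⁻¹, simulates 40 μs, detects contacts with the dual-cutoff
scheme and fits the rate from the strongest residue's durations:

```
true k_off        : 6.00 /us
fitted k_off      : 6.44 /us (95% CI 5.28 - 7.97)
1/mean cross-check: 6.05 /us
events in the fit : 218
```

The fitted rate and the closed-form cross-check both agree with the truth
within the sampling error of ~200 events; the bootstrap CI quantifies that
error. The other scripts under `examples/` walk through membrane
construction, contact detection, site mapping and pose scoring, spatial
statistics, PMF analysis and the full configuration-driven pipeline; each
prints what it computes and what the numbers mean.

A thin command-line interface wraps the same stages:

```bash
lipidkinetics simulate --out run --total-time-us 1 --seed 2
lipidkinetics contacts --topology run/system.gro --trajectory run/system.xtc \
    --species PIP2 --out run/events.csv
lipidkinetics kinetics --events run/events.csv
lipidkinetics run --config pipeline.yaml     # full pipeline
```

## Layout

```
src/lipidkinetics/
  composition.py   membrane recipe, validation, count realization, YAML IO
  trajectory.py    array-backed trajectory container, GRO/XTC round-trip
  synthetic.py     receptor/site builders, kinetic trajectory generator
  contacts.py      COM machinery, dual-cutoff detection, occupancy
  kinetics.py      mono-exponential k_off fitting
  sites.py         site identification, pose scoring, interplay PCC
  spatial.py       leaflet assignment, surface RDF, 2D maps, Voronoi APL
  pmf.py           umbrella windows, WHAM, Bayesian bootstrap, K_d
  benchmarks.py    canonical ground-truth validation studies
  pipeline.py      configuration-driven orchestration and reporting
  cli.py           thin click CLI over the library
```
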