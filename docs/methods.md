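# Methods

This note documents the models and numerical choices behind
`lipidkinetics`: what each stage computes, the assumptions it makes, the
parameters that matter, and what the synthetic validation does and does not
demonstrate about real data.

## Contact model and dissociation kinetics

A lipid–residue contact is defined on centre-of-mass (COM) distances
between whole molecules: it opens at the first frame with d < 0.55 nm and
closes at the first frame with d > 1.4 nm. Both cutoffs are exposed
(`lower`, `upper`); the defaults are the values used for coarse-grained
bead models, where 0.55 nm is roughly the first-minimum of bead pair
correlations and 1.4 nm is far enough that re-crossings are genuine
returns. The duration convention is t_close − t_open, where t_close is the
first frame *beyond* the upper cutoff; an event still open at the end of
the trajectory closes at the final frame time and is flagged censored.
COMs are equal-weight bead averages (the coarse-grained convention),
unwrapped about each molecule's first bead under the minimum-image
convention before averaging.

For Markovian unbinding the uncensored durations are exponential.
`fit_koff` histograms them (default bin width max(t)/30, configurable; raw
counts by default, normalized density optional) and fits
N(t) = A·exp(−k_off·t) by weighted nonlinear least squares with Poisson
(√count) weights. Censored events are excluded from the fit — uncensored
exponential fitting is unbiased, whereas mixing in censored spells is not —
but are counted separately in the profiles. The confidence interval is a
200-resample case bootstrap (percentile), and the closed-form
maximum-likelihood rate 1/mean(durations) is always reported as a
cross-check; the two agree within sampling error whenever the exponential
model holds. A floor of 50 uncensored events (configurable) guards against
meaningless fits, and all-equal durations are rejected as degenerate.

`site_koff` implements site-level rates: within a site, the residue with
the largest mean duration (top-1 by default) is selected and its pooled
durations fitted. Pooling across independent repeats is used for the means;
per-repeat means are also emitted because the interplay statistic needs
them.

### Equilibration

First-shell occupancy (molecules whose COM is within 1 nm of the nearest
receptor bead) is block-averaged (default 20 blocks); the equilibration
time is the start of the earliest block from which every later block mean
stays within `tolerance` × SD of the final-half mean, with the plateau
required to cover at least the final quarter. Monotone drifts therefore
raise a no-plateau error rather than returning a spurious time. The default
analysis window is (equilibration time, end of trajectory).

## Binding-site identification

The per-residue duration profile is thresholded at 3× the median positive
residue duration — a scale-free default that separates long-lived designed
or physical hotspots from the background of short diffusive "rattling"
contacts, provided hot residues are a minority of the contactable surface
(they are, on any realistic receptor). Residues above threshold become
graph nodes; edges connect residues whose COMs lie within the adjacency
radius (default 0.8 nm, i.e. a couple of residues along a helix); connected
components with ≥ 2 members are sites, ranked by their hottest member.
The threshold and radius are explicit parameters: the delineation rule is
this package's formalization, stated so it can be criticized.

### Pose scoring

Bound frames of a species at a site are those whose lipid COM lies within
1.0 nm of the site's basic residues — of *every* basic residue by default
(the literal "within 1.0 nm radius of all the basic residues"), with a
union mode for wide sites where the intersection is empty. For each lipid
bead index a 3D voxel density (0.1 nm voxels, commensurate with
coarse-grained bead size; bounding box + 1 nm margin) is accumulated over
bound frames; a pose's score is the sum over its beads of the density at
each bead's voxel, and ties rank by lower frame index. The trajectory is
assumed receptor-fixed (true for the generator; external trajectories
should be aligned to the receptor first).

### Interplay

The coupling of two co-habiting species is the sample Pearson correlation
of their per-repeat mean interaction durations, computed directly from the
definitional sums (no library call, so the statistic is exactly the printed
formula). Zero-variance inputs are undefined and signalled. |P.C.C| ≥ 0.5
is annotated synergistic/competing; the threshold is an annotation aid, not
part of the statistic.

## Spatial statistics

**Leaflet assignment.** The instantaneous midplane is the median z of all
lipid representative beads; a molecule is labelled by the sign of its
head-group bead relative to it. Cholesterol — the only species expected to
flip-flop — is re-evaluated every frame; all other species keep their
frame-0 label.

**Surface RDF.** The distance of a molecule to the receptor is the
minimum-image distance from its COM to the nearest receptor bead (a
surface-referenced, not centre-referenced, distance). Because the
accessible in-plane area of a distance shell around an irregular protein
cross-section has no closed form, each shell is normalized by a Monte-Carlo
estimate: 10⁵ (configurable, seeded) uniform points in the leaflet plane
are mapped through the same distance function, giving the shell's
accessible area; the bulk density uses only molecules within the histogram
range, so corner regions beyond r_max enter neither numerator nor
denominator. On a homogeneous system this construction gives g ≡ 1 with
mean |g−1| ≈ 0.02 beyond 2 nm at 1.2×10⁵ molecule-frames.

**2D density maps.** COM xy positions per species and leaflet accumulated
on a regular grid, normalized per frame and bin area, so that
∑ density × bin area × frames equals the counted molecule-frames exactly.

**Voronoi area per lipid.** Per leaflet, the generators are the lipids'
representative beads (GL1/GL2 midpoint for glycerophospholipids and
phosphoinositides, AM1/AM2 midpoint for sphingo- and glycolipids, ROH for
sterols) plus the xy projections of receptor beads lying between the
bilayer midplane and the leaflet midplane; vertically stacked receptor
beads that project to the same point are deduplicated. Periodicity is
handled by 3×3 image tiling, exact whenever no cell spans half the box
(always true at membrane densities); cell areas are computed by the
shoelace formula on angularly sorted vertices of scipy's Voronoi regions.
Lipid plus receptor cell areas tile the box to ~1e-15 relative.

## Umbrella-sampling analysis

`extract_windows` lays successive targets one spacing (default 0.05 nm)
apart from the initial coordinate in the pulling direction and selects the
first frame crossing each target, so transient backtracks never move a
window. `wham_1d` iterates the standard self-consistent equations for the
per-window free-energy shifts on a common grid (default 100 bins over the
sampled range) until the largest shift change is below 1e-6 kJ/mol
(default), then anchors the profile minimum at zero. Neighbouring windows
must share at least one occupied bin, otherwise the problem is
disconnected and rejected. Per-sample weights are supported so the Bayesian
bootstrap — Dirichlet(1,…,1) weights over each window's samples, WHAM
re-solved per replicate, per-bin SD over re-anchored replicates — reuses
the same solver. Validation compares profiles after removing the free
additive constant, and assesses the well depth as a gauge-free contrast
(barrier minus mean of the minima) whose bootstrap SD comes from the
replicate profiles; anchoring both estimate and truth at their noisy minima
would otherwise inject a systematic, SD-invisible offset.

`estimate_kd` converts a profile into a dissociation constant via
K_a = A·∫_bound exp(−(W−W_bulk)/k_B T) dξ with A a stated cross-sectional
area (default 1 nm²) mapping the 1D coordinate to a volume, W_bulk the
plateau value (mean over the outermost 10% of the grid), the bound region
defaulting to [ξ_min, first ξ with W ≥ W_bulk − 1 kJ/mol], and
K_d = 1.661 nm³ / K_a (1 M standard state). The convention string is
recorded in every estimate because K_d values from PMFs are meaningless
without it. Temperature defaults to 323 K throughout the coarse-grained
analyses.

## The synthetic generator

The generator is a statistical emulator, not a physical simulator: no
forces, no thermostat, no lipid internal dynamics. It exists to give every
estimator a ground truth.

* Geometry: leaflet midplanes at ±2 nm about the bilayer midplane;
  three-bead lipids (head bead 0.3 nm above the COM, two backbone beads
  below) for non-sterols, a single ROH bead for cholesterol; a static
  helix-bundle receptor (one bead per residue, 0.35 nm spacing, helices on
  a ring).
* Dynamics: unbound lipids take 2D Gaussian steps (default lateral
  D = 0.02 nm²/ns, the coarse-grained regime; per-species configurable)
  with periodic wrapping and a hard cylindrical exclusion around the
  receptor core. Unbound cholesterol flips leaflet with a small hazard
  (default 0.1 μs⁻¹).
* Binding: an unbound lipid of the right species and leaflet inside a free
  site's capture radius binds with hazard k_on; residence times are drawn
  *exactly* exponential with the site's k_off, so the ledger is exact; the
  lipid is tethered at the anchor centroid (Gaussian jitter σ = 0.10 nm
  truncated at 0.25 nm, keeping it within 0.45 nm of every anchor — safely
  under the 0.55 nm detection cutoff) and on unbinding is displaced 1.6 nm
  from the anchor (beyond the 1.4 nm upper cutoff) within one frame, with
  the landing direction resampled until it is outside the receptor core
  and every site's keep-out pocket.
* Keep-out: unbound lipids may not diffuse within 0.85 nm
  (= lower cutoff + tether radius + margin) of a site anchor, so *any*
  sub-cutoff approach to an anchor corresponds to a ledger binding; this is
  what makes detected events and ledger events match one-to-one within one
  frame stride. Diffusive rattling contacts still occur everywhere else on
  the contactable surface, which is what the site-identification threshold
  is calibrated against.
* Determinism: one `numpy` generator seeded from the system config; the
  same seed and config give a bit-identical trajectory and ledger.

What the generator does not emulate: membrane undulations and thickness
fluctuations, lipid tilt and internal conformations, multi-bead chemistry
(GM3 head groups are not modelled beyond a representative-bead rule),
receptor conformational dynamics (state dependence is emulated by supplying
different site rate tables, not by moving the receptor), crowding-induced
subdiffusion, and correlated binding between sites. Passing the validation
studies therefore demonstrates the correctness of the estimators under the
model assumptions (Markovian unbinding, planar leaflets, static receptor),
not the physical fidelity of any particular simulation.

## Validation studies and problem sizes

The studies in `benchmarks.py` (shared by the tests and the reproduction
script) use sizes chosen for single-core, few-minute runs:

* k_off recovery: four PIP2 sites with k_off ∈ {2, 5, 9, 14} μs⁻¹ on a
  four-helix bundle, 270 μs at 2 ns stride, ≥ 500 events at the slowest
  site (the regime of hundreds to thousands of events per site in
  production data). Median relative error is ~2–4%. Truths 2 and 14 sit on
  the regime boundary, so point estimates match the regime to within the
  estimator's ~10% tolerance rather than strictly inside it.
* nine-site recovery: nine hotspots (GM3, cholesterol, PIP2; k_off
  0.6–2.5 μs⁻¹) on a twelve-helix bundle, 40 μs, lateral D = 0.04 nm²/ns;
  designed residences (0.4–1.7 μs) then stand well clear of rattling
  contacts (~40 ns), and all nine sites are recovered with member-residue
  Jaccard 1.0.
* WHAM: 50 windows, 0.05 nm spacing, 1000 kJ/mol/nm², 5000 samples/window
  from the double well 10(ξ−1)²(ξ−2)² kJ/mol; RMS deviation ~0.1 kJ/mol
  (bound 0.5). The 2-SD bootstrap interval on the well depth has nominal
  coverage ≈ 95%, so over 20 replicates 18–20 covered is typical and 17
  occurs within ordinary binomial fluctuation (~8% of study seeds).
* Voronoi conservation: 1000 random periodic point sets, relative area
  error ~1e-15; a 4-point square lattice gives exactly box area / 4.
* RDF flatness: 200 ideal-gas molecules × 600 frames (1.2×10⁵
  molecule-frames), mean |g−1| ≈ 0.02 beyond 2 nm.

## Known limitations

* The periodic Voronoi uses 3×3 tiling, exact only while no cell spans half
  the box — fine for membranes, wrong for near-empty leaflets (a minimum of
  3 generators per leaflet is enforced).
* The surface RDF's Monte-Carlo normalization assumes a static receptor
  (frame-0 beads) and samples each leaflet at its mean COM plane; strongly
  undulating membranes would need per-frame receptor trees and z-resolved
  sampling.
* WHAM convergence is plain self-consistent iteration; profiles spanning
  very high barriers (≫ 40 kJ/mol between neighbouring windows) may need
  smaller tolerances or more iterations than the defaults.
* `estimate_kd` is only as meaningful as its recorded standard-state
  convention; comparing values across conventions is a category error.
* The mono-exponential fit assumes a single bound state per site;
  multi-exponential residence distributions (multiple poses with distinct
  lifetimes) will bias k_off toward the fast component, and the 1/mean
  cross-check diverging from the histogram fit is the diagnostic for it.
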