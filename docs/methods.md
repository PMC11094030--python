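# Methods

This package re-implements, as a tested pipeline over synthetic data, the
computational analyses of activity-dependent recruitment of a membrane
protein (dynamin-1) into endocytic nanoclusters: mobility metrics from
single-particle tracking, spatiotemporal nanocluster detection,
certification of lateral-trapping events, recruitment kinetics, and a
reaction–diffusion model of cluster growth with parameter fitting.

## Synthetic sptPALM generator (`nanotrap.synthetic`)

The generator emulates the statistical structure of an sptPALM
acquisition rather than its optics: no camera frames or point-spread
functions are rendered; trajectories are produced directly.

Mechanism: molecules appear on the membrane as a Poisson process whose
area-rate steps from `recruitment_rate_pre` to `recruitment_rate_post`
at `stim_time` (the recruitment phase of the bi-phasic response).  Free
molecules take 2D Brownian steps of per-axis variance `2·d_free·Δt`,
reflected at the ROI boundary.  Nanoclusters are disks with birth times
and exponential lifetimes (or a static regular grid).  When a molecule's
detection crosses from outside into a live disk it is captured with
probability `trap_probability`; captured molecules diffuse at
`d_confined` with reflection at the disk edge until escape
(`escape_rate`), cluster death, or photobleaching.  Bleaching and
blinking are collapsed into one geometric detection-count distribution
(`bleach_rate`), justified because all downstream analyses use
≥8-detection tracks only.  Detections are true positions plus isotropic
Gaussian noise (`localization_sigma`).  All randomness derives from one
seed through per-molecule `SeedSequence` substreams, so outputs are
bit-identical given a seed.

Default conditions (the acquisition regime being emulated): 50 Hz frames
(20 ms), membrane diffusion 0.045 µm²/s free vs 0.005 µm²/s confined,
clusters of radius ~0.09 µm at 0.54/µm² with ~8 s mean lifetimes,
localization noise 20 nm, and appearance rates chosen so that the track
density stays below the 50 trajectories/µm² rejection limit above which
real acquisitions are discarded for mistracking.

What the generator does *not* emulate: mistracking and track splitting,
detection dropout inside dense clusters, drift, dye photophysics beyond
a single off-rate, and active recruitment of molecules *to* cluster
sites (capture happens only by lateral crossing).  Consequences of the
last point are discussed under "cluster recovery" below.

## Mobility metrics (`nanotrap.tracks`)

MSD(τ_k) is the time-origin average of squared displacements at lag k.
The diffusion coefficient is an OLS fit of `MSD = 4Dτ + c` over the
first 4 lags with a free intercept; the intercept absorbs the static
localization-noise offset (4σ²).  D is floored at 1e-5 µm²/s before
log10.  The mobile/immobile split uses Log10D > −1.45 by default; the
threshold is configurable since different prior calibrations are in
use.  The AUC of the MSD is a trapezoidal integral over the first 8 lags
(0.16 s at 50 Hz).  Tracks shorter than 8 or longer than 100 detections
are excluded; sets denser than 50 trajectories/µm² are flagged and can
be rejected.

## Spatiotemporal clustering (`nanotrap.clustering`)

Each detection maps to `(x, y, t·ε/T)` with neighborhood radius ε and
time window T, so two co-located detections separated by exactly T map
exactly ε apart: one radius serves space and transformed time.  The
temporal scalar ε/T is the defining property; no other scaling satisfies
it linearly.  DBSCAN then runs in this 3D metric with standard
semantics; the implementation indexes neighborhoods with a KD-tree but
expands clusters by BFS over points in canonical (t, id) order, so
border-point ties always resolve to the first-discovered cluster and the
labeling is reproducible.

Cluster radius is the RMS member distance from the centroid; a
`radius_factor` multiplier (default 1.0; 1.2 in the legacy-compatible
preset) scales the footprint used for membership queries.  Screens:
radius ≤ `cluster_size_screen`, member trajectories ≥
`cluster_threshold`.  Hotspots: a cluster belongs to a hotspot when
another cluster with a strictly disjoint lifetime has its centroid
within the sum of the two radii.  Trajectory rates count distinct
trajectories with ≥1 detection in the xy footprint during the cluster's
lifetime, and in the equal-length window immediately before (clipped at
the acquisition start and renormalized).

Presets carry the published parameter sets: ε = 0.05 µm, T = 10 s, 8
minimum points for neuron-like acquisitions (60 s) and 3 for
PC12-like (320 s); the NASTIC-like preset uses T = 20 s, radius factor
1.2, cluster threshold 3.

## Lateral trapping (`nanotrap.trapping`)

A trajectory certifies as a trapping event for a cluster when (1) its
first detection is not within the cluster, (2) its last detection is
within it, and (3) it does not intercept the cluster boundary before its
entry step, where "within" means inside the xy footprint during the
cluster's temporal window.  Rule 3 is evaluated at detection resolution
(it is then implied by the definition of the entry step); a stricter
optional mode also rejects trajectories whose pre-entry segments cross
the footprint circle between detections.  By default a fourth condition
is enforced — every detection from entry to the end of the cluster
lifetime stays inside the footprint — reflecting the stronger
"confined for the duration of its lifetime" reading; the pure
three-rule variant is available via `require_confinement=False`.

Displacements are indexed by step number relative to entry (step 0 = the
first in-cluster detection) and pooled across events; the percentage of
clustered trajectories entering after ≥ n prior detections is reported
for n = 1..10, with the denominator being all trajectories having ≥1
detection within any surviving cluster (the most inclusive reading of
"clustered trajectories").

## Kinetics (`nanotrap.kinetics`)

Traces are smoothed with a centered moving average (default 5 s) for
peak localization only; baseline is the mean raw FI over the 30 s before
stimulation; fold change is smoothed peak over baseline; the decay slope
is an OLS fit over a 100 s post-peak window (configurable — the original
window is not published).  A peak is flagged unresolved when the
smoothed trace never falls below it afterwards.  Decay is compared to a
photobleaching control on log-FI when both traces are positive (slopes
are then exponential rate constants); the verdict is one-sided.
Cumulative track counts per µm² are sampled at 30 s block edges to avoid
under-sampling and differentiated with `numpy.gradient`.

## Reaction–diffusion model (`nanotrap.model`)

Species and reactions are listed in the module docstring.  Design
choices:

- **Geometry.**  Clusters at measured density ρ are assumed evenly
  distributed, so the model tracks one cluster in a periodic patch of
  side 1/√ρ with a solution column of height V/A = 1.9 µm.  With
  ρ = 0.54 µm⁻² the patch is 1.36 × 1.36 µm (1.85 µm²); with 3.1 µm⁻²
  it is 0.568 µm.  The length scale h = 10 nm converts 3D rate constants
  to 2D (k/h); in volume-concentration units all 2D reactions carry the
  dimensionality factor DF = V/(Ah).
- **Equilibrium initialization.**  k_b = k_frev·[D]_sol·[R]_mem/[D]_mem
  holds the solution/recruiter/membrane pool stationary, so all cluster
  growth is driven by the activator density; with the optimal
  concentrations (10 µM, 4.85 and 30 copies/µm², k_frev = 0.09) this
  gives k_b = 0.1455 ≈ 0.15 s⁻¹.
- **Units.**  The ODE state is volume concentration (µM); surface
  densities convert through explicit areas (membrane species over the
  patch area, cluster species over the cluster disk area) so totals are
  never double-counted.  `convert_units` performs the conversions with
  602.214 copies·µm⁻³ per µM.
- **Stimulation transform.**  Three changes: the post-stimulation
  cluster density (new geometry, radius 0.096 µm), the membrane density
  scaled by the measured factor with the solution pool reduced so total
  copies per unit membrane area are conserved, and k_mem switching to
  its post value.  The Dyn1bb scale factor is not printed in the
  available text; the preset uses 2.0, which keeps the initial membrane
  pool (60 copies/µm²) inside the stated physical range of 10–80
  copies/µm².  The headline bound (peak cluster copies ≤ 80 over the
  4 s formation window) is insensitive to the factor anywhere in that
  range.
- **Deterministic solver.**  LSODA at rtol 1e-7 / atol 1e-9 (matching
  the tolerances used by the original finite-volume solver), with
  negative-state detection.  The growth is open-ended irreversible
  autocatalysis, so the simulation horizon (default: the 4 s formation
  window) is part of the experiment definition, not a solver property.
- **Stochastic variant.**  An exact Gillespie simulation in copy
  numbers.  Dynamin–dynamin reactions are dispatched over 4 independent
  binding sites at k_dyn/4 each — a well-mixed bookkeeping of the 4-site
  oligomerization whose summed propensity equals the mass-action rate.
  An optional 0th-order titration (100 µM/s) plus 1st-order degradation
  (10 s⁻¹) pins the solution pool near its initial concentration,
  mimicking an open cytosol; with titration off, total dynamin is
  conserved exactly.  Ensemble comparisons use 48 trajectories.
- **Reduced spatial variant.**  The membrane species diffuse on a
  periodic 2D grid (0.015 µm cells) while the solution is a single
  well-mixed bath coupled to every surface cell.  Rationale: solution
  diffusion (7 µm²/s) equilibrates the 1.9 µm column roughly two orders
  of magnitude faster than membrane transport spans the patch, so the
  3D solution gradient carries no information at these time scales.
  Time stepping is operator splitting: Heun (second-order) reactions
  plus exact spectral diffusion, with dt bounded by 0.1 s and by the
  fastest local linear reaction rate; in the fast-membrane-diffusion
  limit the domain totals agree with the ODE to better than 1%.
- **Observables.**  Rel Density(t) = (ρ_Dmem + ρ_Dclus + ρ_D2dclus)(t)
  / ρ_Dmem(0) with all densities per-area; Dyn copies = that sum times
  the cluster disk area; the 2D fraction ρ_D2dclus/(ρ_Dclus+ρ_D2dclus)
  quantifies dimensional reduction.  The recruiter is treated as
  permanently sequestered once dynamin enters cluster species (it never
  reappears in the reaction list), so free R + membrane dynamin is
  non-increasing once a cluster exists.

## Fitting (`nanotrap.fitting`)

Relative intensity (I − Δ)/(I(0) − Δ) uses an offset Δ chosen so the
peak matches an independently measured fold change (from
single-particle track counts); the matching condition is monotone in Δ
and solved in closed form.  The objective is χ² = Σ(model−data)²/SEM²
on a common grid, with zero SEMs rejected.  The genetic algorithm is
real-coded on the unit box with log10 decoding for rate-like
parameters: tournament selection (size 3), two-point crossover (p=0.6),
per-individual Gaussian mutation (p=0.2, σ=0.1 of the range), one
elite, fixed seed.  Defaults: population 50, 100 generations.  Search
boxes default to 1e-4–1 µM⁻¹s⁻¹ for bimolecular rates (an assumption;
the original ranges beyond those printed are not available), 0.1–10 µM
for solution dynamin and 10–80 copies/µm² for membrane dynamin.

In the parameter-recovery experiment (planted k_mem and k_dyn, 1%
relative errors on a 41-point growth curve) the GA recovers k_dyn to
~10–15% and k_mem to ~20–25%; the residual k_mem uncertainty reflects
partial compensation between the two recruitment channels over a 4 s
window, not optimizer failure.

## Validation experiments: what they do and do not show

Test problem sizes are chosen to keep the default suite in a few
minutes on one CPU: acquisitions of 100–700 trajectories on 16–100 µm²
ROIs and 25–40 s durations, 48-run stochastic ensembles, a 41-point
fitting grid.

- The DBSCAN and trapping implementations are verified against
  brute-force oracles (O(n²) DBSCAN from the definition; literal
  re-evaluation of the trapping rules over all pairs), including a
  property-based sweep, so the production implementations are exact.
- Estimator consistency: the MSD fit recovers the generator's D within
  10% on 500 pure-Brownian tracks; mobility, trajectory-rate and
  displacement-drop checks reproduce the *directions* of the measured
  effects (mobility drop under trapping, higher trajectory rates during
  cluster lifetimes, smaller in-cluster displacements).  Passing these
  shows the pipeline is self-consistent on data matching its
  assumptions; it does not certify the biological magnitudes.
- Cluster recovery uses a dedicated synthetic field designed so every
  occupied planted cluster is one cohesive detection cloud: footprints
  on the ε scale, lifetimes inside the time window, fast free diffusion
  (0.5 µm²/s) so untrapped tracks do not linger, and `min_points`
  matched to the per-visitor detection yield (captured tracks leave
  25–60 detections in their host; coincidental crossings far fewer).
  Two generator-specific caveats follow from the capture-by-crossing
  mechanism.  First, a planted binding site that no molecule visits
  produces no detections, so recovery and density are judged against
  *occupied* planted clusters.  Second, slow free walkers (0.02–0.1
  µm²/s) transiently linger within ε at 50 Hz and can mimic small
  clusters in short acquisitions; real analyses operate on much longer
  acquisitions where the pseudo-time slab is proportionally thicker.
  Recovery (≥80% at Jaccard ≥0.5) and density agreement (within 20%)
  were verified across independent seeds before freezing the fixture.

## Known limitations

- The single-cluster periodic geometry ignores inter-cluster
  competition beyond the density-derived patch size.
- The stochastic simulator is well-mixed; it carries the 4-site
  bookkeeping but not structure-resolved excluded volume, so it cannot
  resolve oligomer geometry (rings vs helices).
- The spatial model diffuses only the membrane species; the well-mixed
  bath assumption breaks if solution diffusion were within an order of
  magnitude of membrane diffusion.
- HFA/LFA ROI selection and image-to-trace extraction are out of scope;
  traces and ROI geometries are inputs.
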