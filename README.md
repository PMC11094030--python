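# nanotrap

Analysis pipeline for activity-dependent recruitment of membrane
proteins into endocytic nanoclusters, built around single-particle
tracking (sptPALM) data and a reaction–diffusion model of cluster
growth.  The motivating system is dynamin-1 at the plasma membrane:
molecules are recruited from the cytosol, diffuse laterally in 2D, and
are trapped into nanoscale clusters at endocytic sites — a
dimensional-reduction search strategy.  Everything runs on synthetic
acquisitions with exact ground truth, so every stage is testable
without any experimental download.

## What it does

- **`nanotrap.synthetic`** — generates sptPALM-like trajectory sets
  (50 Hz, Brownian motion, Bernoulli capture into nanocluster disks,
  photobleaching-limited track lengths, localization noise) and
  fluorescence-intensity traces, with JSON ground truth.
- **`nanotrap.tracks`** — TRXYT/CSV trajectory I/O, length and density
  filters, MSD curves (MSD = 4Dτ + c over the first lags), Log10D
  distributions, mobile/immobile ratio, AUC of the MSD.
- **`nanotrap.clustering`** — spatiotemporal nanocluster detection:
  detections embedded as (x, y, t·ε/T) so one DBSCAN radius ε applies
  in space and time; cluster radius/lifetime/density, hotspot fraction,
  and per-cluster trajectory rates before vs during the lifetime.
- **`nanotrap.trapping`** — certifies lateral-trapping events (first
  detection outside, last inside, no boundary interception before
  entry, confined afterwards) and aligns displacements on the entry
  step.
- **`nanotrap.kinetics`** — time-to-peak, fold change and post-peak
  decay of FI traces (vs a photobleaching control); blocked cumulative
  track-appearance rates.
- **`nanotrap.model`** — a 6-species / 7-reaction model of dynamin
  recruitment to one cluster: reversible membrane binding
  (D_sol + R_mem ⇌ D_mem), activator capture from solution and from the
  membrane, and autocatalytic dynamin–dynamin recruitment; 2D reactions
  carry rate k/h and, in the well-mixed ODE, the dimensionality factor
  DF = V/(Ah).  Deterministic (LSODA), exact stochastic (Gillespie,
  4-site oligomer bookkeeping, optional solution titration) and reduced
  spatial (2D membrane grid + well-mixed bath) variants.
- **`nanotrap.fitting`** — χ² objective weighted by experimental SEM,
  background-offset normalization of intensity curves, and a seeded
  real-coded genetic algorithm for parameter estimation.

The numbered scripts under `analysis/` drive the full study over the
synthetic data and write tables to `results/`.  A thin CLI (`nanotrap
simulate-tracks|mobility|cluster|trap|kinetics|model-run|model-fit`)
wraps the same functions.

## Worked example

Run the cluster-growth model with the optimal short-tail (Dyn1bb)
parameter set after the stimulation transform — cluster density
3.1 µm⁻² (patch side 0.568 µm), cluster radius 0.096 µm, membrane pool
scaled with copy conservation, k_mem at its post-stimulation value —
over the 4 s cluster-formation window:

```sh
nanotrap model-run --preset dyn1bb-post --t-end 4
```

prints

```json
{
  "peak_dyn_copies": 6.625938776300422,
  "final_rel_density": 3.8142032294288066,
  "final_fraction_2d": 0.46726771674439604
}
```

Reading: starting from ~0.9 dynamin copies within the cluster footprint
(the pre-cluster membrane pool), recruitment driven by the
cluster-restricted activator raises the local density ~3.8-fold within
4 s, peaking at ~6.6 copies localized to the cluster — inside the
physical envelope of ≤80 copies needed for a constriction filament —
with nearly half of the clustered dynamin arriving laterally from the
membrane (2D) rather than directly from solution, the signature of
dimensional reduction.

The full synthetic study:

```sh
python analysis/01_simulate_acquisitions.py   # rest + stimulated sptPALM
python analysis/02_mobility.py                # Log10D, M/IMM, MSD, AUC
python analysis/03_nanoclusters.py            # 3D DBSCAN cluster metrics
python analysis/04_trapping.py                # entry rules, displacements
python analysis/05_kinetics.py                # FI traces, cumulative rates
python analysis/06_cluster_growth_model.py    # ODE vs SSA vs spatial model
python analysis/07_fit_growth_curve.py        # GA parameter recovery
```

For example, `02` reports a mobile-to-immobile ratio dropping ~65%
between the rest and trapping conditions, `04` reports in-cluster
displacements roughly half the pre-entry displacements (≈40 nm vs
≈80 nm per frame), and `06` shows the 48-run stochastic ensemble
tracking the deterministic growth curve and the membrane-diffusion
model forming a depletion halo around the cluster.

## Layout

```
analysis/            numbered study drivers (write to results/)
src/nanotrap/        library modules (all computation lives here)
tests/               pytest suite incl. acceptance checks
scripts/acceptance.py
docs/methods.md      model, estimators, parameters, limitations
```
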