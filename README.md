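# trackdose

Desk-scale simulator and reconstruction library for MLC-tracked
step-and-shoot radiotherapy. It builds a digital pelvic phantom and a
step-and-shoot IMRT plan with pre-calculated dose influence matrices,
simulates deliveries as asynchronous MLC-aperture (40 ms) and machine-state
(20 ms) streams in three modes (*static*, *conventional*, *tracked* with a
latency-delayed translational MLC tracking controller), and reconstructs the
actually-delivered dose per aperture: weighting every beamlet by its
geometric overlap with the MLC, scaling by the incremental monitor units,
and accumulating both onto the static anatomy and into the moving target
VOIs. DVH analytics (Dx points, V95 overlap, non-tumour integral dose) and
batch sweeps over interfractional offset grids and pitch/roll rotation
grids complete the pipeline.

No external data is required: phantom, plan, trajectories and delivery logs
are all generated by the package.

## Layout

| module                 | contents |
|------------------------|----------|
| `trackdose.phantom`    | voxel grid, VOIs, phantom builder, anisotropic margin expansion |
| `trackdose.plan`       | BEV geometry, beamlet grids, apertures, heuristic conformal plan generator |
| `trackdose.influence`  | synthetic pencil-beam kernel and sparse dose influence matrices |
| `trackdose.motion`     | trajectory archetypes, latency model, offset/rotation grids, rigid displacement |
| `trackdose.delivery`   | delivery simulation, BEV projection, aperture tracking |
| `trackdose.recon`      | per-aperture reconstruction loop (MLC+VOI and MLC-only methods), sweeps |
| `trackdose.analysis`   | DVH curves, Dx/Vx metrics, NTID, delta-vs-static reports |
| `trackdose.io` / `cli` | CSV/HDF5 round-tripping, config schema, command line |

Conventions: x = LR (+left), y = AP (+anterior), z = SI (+superior);
lengths mm, doses cGy, angles degrees, times seconds. In the beam's-eye-view
u is the leaf-travel axis and v the leaf-width axis (always SI).

## CLI

```bash
# end-to-end static/conventional/tracked triptych with metrics CSV
trackdose demo --seed 0 --out out/

# staged pipeline
trackdose dij --config cfg.yaml --out scene.h5
trackdose trajectory --config cfg.yaml --duration 300 --out traj.csv
trackdose deliver --config cfg.yaml --scene scene.h5 --out-prefix out/run
trackdose reconstruct --config cfg.yaml --scene scene.h5 --out out/result.h5
trackdose sweep-offsets --config cfg.yaml --scene scene.h5 --out offsets.csv
trackdose sweep-rotations --config cfg.yaml --scene scene.h5 --out rotations.csv
trackdose metrics --result out/result.h5 --scene scene.h5 --out metrics.json
```

Example config (YAML):

```yaml
phantom_size: small          # or "default"
margin_mm: {isotropic: 3.0}  # or per-direction: {left: 5, right: 5, ant: 5, post: 3, sup: 5, inf: 5}
n_beams: 7
segments_per_beam: 3
total_mu: 340
beamlet: {u_res: 5}          # 5, 2.5 or 1.25 mm along leaf travel
mode: tracked                # static | conventional | tracked
method: mlc_voi              # mlc_voi | mlc_only
trajectory: {archetype: continuous_drift}   # or {file: traj.csv}
latency: {mean_ms: 100, sd_ms: 15}
dose_rate_mu_min: 600
hold_s: 2.0
seed: 0
```

A single config + seed reproduces every artifact byte-for-byte.

## File formats

* Trajectory CSV: header `t_s,d_lr_mm,d_ap_mm,d_si_mm`, one row per 25 Hz sample.
* Delivery logs: machine states `t_s,cum_mu,dose_rate,gantry_deg,beam_on`;
  apertures `t_s,beam,segment,applied_u_mm,applied_v_mm,v0_mm,leaf_width_mm,
  row<i>_left_mm,row<i>_right_mm,...,vmin_mm,vmax_mm`.
* Scene/result containers: HDF5 (`/grid`, `/density`, `/vois/<name>`,
  `/plan/beam<i>`, `/dij/beam<i>` with CSC arrays; results hold
  `/static_dose`, `/target_dose/<voi>`, `/voi_doses/<voi>` plus provenance
  attributes).

## Notes on the dose model

The dose engine is a documented synthetic kernel (not a TPS):
`D = C * exp(-mu*depth) * exp(-r^2 / 2 sigma^2)` with `mu = 0.005/mm`,
`sigma = 3 mm`, calibrated to a configurable cGy/MU on the central axis at
10 cm depth. On the homogeneous, water-equivalent phantom this kernel is
exactly shift-invariant, which the test suite uses to verify
perfect-tracking recovery and static identity to machine precision.
MLC leakage, tongue-and-groove and output-factor effects are ignored;
leaf dynamics are idealized (infinite leaf speed).
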