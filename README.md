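# mcmuv — Monte Carlo monitor-unit verification for VMAT plans

An independent secondary dose check for VMAT arc plans: DICOM-RT ingestion,
a CT-derived four-material voxel phantom, a deterministic photon Monte Carlo
dose engine with job splitting and partial-dose merging, per-energy
calibration to reference conditions, DICOM RT Dose export, and
reference-point evaluation against a configurable action limit (default 5%).
A modified-Clarkson sector-integration comparator with radiological depth
represents the simple single-point algorithm class, so its heterogeneity
blindness can be demonstrated against the transport engine.

## What's inside

| module | role |
| --- | --- |
| `muv.dicom_io` | CT / RT Plan / RT Structure Set / RT Dose read & write, de-identification, HDF5 case container (self-contained Explicit-VR-LE codec) |
| `muv.phantom` | HU → material/density mapping (air, lung, tissue, bone) and phantom resampling |
| `muv.beam` | phase-space files (own binary layout), parametric source, per-control-point apertures, differential MU |
| `muv.transport` | Woodcock-tracking kerma-approximation photon engine, job split/merge, uncertainty, `pardose`/`3ddose` files |
| `muv.cross_sections` | packaged analytic attenuation / energy-transfer tables, Klein–Nishina sampling |
| `muv.calibration` | reference condition (10×10 cm, 100 cm SSD, 40 cm water cube, d = 10 cm), F_cal = D_tps/D_mc per energy |
| `muv.clarkson` | sector integration + Siddon radiological depth, commissioning tables |
| `muv.evaluation` | reference-point selection (PTV centroid + 4 offsets), percent differences, action limits, study pooling |
| `muv.fixtures` | deterministic synthetic CT series, plans, structures, TPS-like dose, phase space, commissioning tables |

The engine is photon-only with kerma approximation (no electron transport):
Compton via exact Klein–Nishina sampling, photoelectric absorption, pair
production with annihilation photons, 10 keV cutoff. Runs are deterministic
per `(seed, segment, history-batch)` so splitting a run into jobs and
merging the partial doses reproduces the unsplit result.

## CLI

```bash
muv fixtures make-case --preset lung --out case_dir   # synthetic DICOM case
muv ingest case_dir --out case.h5                     # bundle into a container
muv simulate case.h5 --arc 0 --histories 100000 --jobs 4 --seed 1 --out-dir pd
muv merge pd/*.pardose --out arc0.3ddose
muv calibrate --energy 6FFF --histories 200000
muv check-clarkson case.h5 --point 0 0 0
muv phsp concat a.phsp b.phsp --out merged.phsp
```

## Conventions

Patient coordinates in mm, voxel values at voxel centers, arrays indexed
`[z, y, x]`; axis-aligned geometry only. Gantry angles in degrees, vendor
convention, wrapped to [0, 360). Dose in Gy (engine output in Gy/particle
until calibrated). Percent difference is `100·(secondary − TPS)/TPS`, and
the action limit uses strict inequality.
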