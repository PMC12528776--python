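# airtree

Geometric airway-branch decomposition and volume biomarkers from binary
airway/lung masks, with skeleton-based morphometry and a survival
(prognostic-evaluation) toolkit. Everything is exercisable on synthetic
airway phantoms with known ground truth, so no imaging data is required
to run or validate the package.

## What it does

* **Decomposition** — given a 3D binary airway mask and a lung mask on a
  shared voxel grid, locates the trachea and carina, projects the
  bronchial tree axially, computes per-lung max-normalised radial
  distance maps and a normalised vertical depth below the carina, and
  classifies every airway voxel as *trachea*, *medium*, *small* or
  *terminal* (distance cuts 0.25 / 0.55, with an optional vertical-depth
  promotion step).
* **Biomarkers** — class volumes as percent of total lung volume:
  `STermAV`, `SSmallAV`, `SMedAV`, `STotalAV` (their sum; trachea
  excluded) and `SPAV` (small + terminal), plus 0.1-percentage-point
  model units and tertile risk groups.
* **Morphometry** — 3D skeletonisation, rooted branch graph, per-branch
  length, tortuosity, angle-to-parent and sibling angle, and a
  generation-percentage branch classification (cuts 40% / 70%).
* **Phantoms** — deterministic dichotomous trees of tapering capsules
  with per-branch generation ground truth, two-lobe lung masks, and
  optional peripheral "honeycomb" cyst clutter for robustness probes.
* **Survival** — Cox proportional hazards (Efron ties, via lifelines),
  Kaplan–Meier curves with Greenwood variance, log-rank tests, Harrell's
  C and C-index increments, IPCW cumulative/dynamic AUC(t) (via
  scikit-survival), Schoenfeld proportional-hazards checks, 12-month
  progression labelling (FVC ≥ 10% / DLCO ≥ 15% decline, relative or
  absolute), and a seeded proportional-hazards cohort simulator.

## Command line

```bash
airtree phantom --out phantom/ --generations 5 --seed 1
airtree decompose --airway phantom/airway.nii.gz --lung phantom/lung.nii.gz \
    --out labels.nii.gz --report report.json
airtree biomarkers --labels labels.nii.gz --lung phantom/lung.nii.gz \
    --out biomarkers.json
airtree morphometry --airway phantom/airway.nii.gz --out branches.csv
airtree simulate-cohort --n 500 --beta SPAV=0.405 --censor 0.3 --seed 7 \
    --out sim.csv
airtree survival --cohort sim.csv --covariates SPAV --strata SPAV \
    --horizons 1,3,5,7 --out results.json
airtree fixtures --out fixtures/ --seed 0
airtree run --config pipeline.yaml
```

`airtree run` executes decompose → biomarkers (→ optional morphometry
and survival) from a YAML config; every JSON artifact is stamped with
the package version and a config hash, and reruns with an identical
config reproduce identical outputs.

Conventions: all volumes are indexed `(z, y, x)` with slice 0 most
superior, y anterior→posterior, x patient-right→patient-left; NIfTI
inputs of any orientation are normalised on load. Cohort CSVs need
`id`, `time` (years), `event` (0/1) columns plus numeric covariates.

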