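# arcqa

A desk-scale toolkit for cylindrical diode-array delivery-verification
analysis in rotational radiotherapy QA. It models a spiral diode array
(1,386 diodes on a 21 cm cylinder) inside an annular acrylic phantom with an
optional central plug, reconstructs arc deliveries from DICOM-RT Plan
control points into MU-weighted subfield fluences, computes dose with a
simplified TMR / effective-path-length / inverse-square ray engine, and
evaluates agreement with a gamma-index engine (criteria sweeps, cylindrical
wrap-around metric). Four end-to-end studies are provided: open-field
depth-dose validation, a couch-rotation angular-response sweep, misalignment
sensitivity (cylindrical vs planar array vs central chamber probe), and
composite plan QA with a chamber-volume central dose.

Everything runs on synthetic fixtures: the package generates its own
DICOM-RT Plan/Dose files and diode-reading tables (deterministic for a given
seed), so no measurement data is required.

## Layout

| Module | Purpose |
| --- | --- |
| `arcqa.detector_geometry` | spiral diode layout, annular phantom, entrance/exit masks, cylinder unwrap, analytic radiological path |
| `arcqa.rt_io` | DICOM-RT Plan / Dose read & write (self-contained explicit-VR-LE codec in `arcqa._dicom`), CT-number density ramp |
| `arcqa.fluence_model` | control-point → subfield decomposition, MLC-aware fluence rendering (transmission, rounded leaf end, tongue-and-groove), angular binning |
| `arcqa.synthetic_dose` | beam model (analytic or tabulated TMR), ray dose engine, angular-response and noise perturbations, rigid misalignments, fixture generator |
| `arcqa.gamma_analysis` | gamma index with DTA search (auto-expanding, oracle-equal), criteria sweeps, unwrapped cylindrical maps with seam wrap-around |
| `arcqa.qa_pipeline` | the four studies, chamber-probe volume dose, QA reports (JSON + CSV) |

## CLI

```bash
arcqa fixtures make --config fixture.yaml --seed 1 --out fixtures/
arcqa qa open-field  --seed 1 --out results/
arcqa qa couch-sweep --config couch.yaml --seed 1 --out results/
arcqa qa misalign    --seed 1 --out results/
arcqa qa plan --plan fixtures/plan.dcm --dose fixtures/dose.dcm \
              --readings fixtures/readings.tsv --out results/
```

Config files are YAML; any omitted key falls back to the documented defaults
in `qa_pipeline.py` / `synthetic_dose.py`. Every stochastic element takes an
explicit seed and reports record a config hash, so identical inputs give
byte-identical reports.

## Conventions

* Frame: x toward patient left, y anterior, z superior (cylinder axis);
  gantry 0° enters from anterior; spiral angle 0 at anterior.
* Lengths cm, densities g/cc; doses are Gy in `DoseGrid` / DICOM files and
  cGy in readings tables and QA reports (calibration 1 cGy/MU at dmax,
  10×10 cm², 100 cm SSD).
* Gamma: global normalization to the reference maximum, 10% low-dose
  threshold by default (both configurable), evaluated distribution upsampled
  to ≤ DTA/10, search radius 3×DTA with automatic expansion so results equal
  the exhaustive search.
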