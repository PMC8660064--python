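# sedem

SeDeM / SeDeM-ODT expert-system scoring for pharmaceutical granules and
powders, with tablet quality-control metrics and a granule → tablet trend
analysis. The package takes raw lab measurements (densities, cone dimensions,
flow times, sieve analysis, compact strengths, disintegration times), turns
them into the 15 basic parameters, rescales each onto the 0–10 radius scale,
computes suitability indices (IP, IPP, reliability factor, IGCB/IGC) and the
six incidence factors, draws the radar diagram, evaluates compendial tablet
QC metrics (diametral tensile strength, specific crushing strength,
friability, weight variation, drug content, dissolution with withdrawal
correction), and checks the expected monotone links between granule scores
and tablet outcomes.

A reference dataset from a published atenolol high-shear wet-granulation
case study (13-trial design, radius tables, index tables, tablet metrics) is
bundled as plain CSV, and a synthetic-study generator reproduces the same
two-factor design with configurable effect slopes and noise so the whole
pipeline is testable offline.

## Library quick start

```python
import sedem

bundle = sedem.load_reference()
report = sedem.full_report(bundle.profile("Trial-5"))      # 15-parameter system
print(report.ipp, report.igcb, report.verdict)             # 5.455 5.297 suitable

study = sedem.simulate_study(sedem.EffectConfig(), seed=1) # synthetic 13 trials
result = sedem.recovery_check(study)                       # effect-sign recovery
print(result.all_passed)
```

## Command line

```sh
sedem simulate --seed 1 --out sim/                 # measurements.csv + tablets.csv
sedem profile --measurements sim/measurements.csv --out radii.csv
sedem indices --radii radii.csv --system both --out report.json
sedem diagram --radii radii.csv --batch Trial-5 --out trial5.svg
sedem tablets --tablets sim/tablets.csv --out tablet_report.json
sedem link --radii radii.csv --tablet-report tablet_report.json --out linkage.json
sedem reproduce-reference                          # pass/fail table for every bundled cell
```

`sedem reproduce-reference` recomputes every index/incidence cell of the
bundled reference tables from the bundled radii; two trials' ODT cells are
internally inconsistent in the source tables and are reported as documented
exceptions rather than failures.

## Layout

- `src/sedem/parameters.py` — the 15 basic parameters from raw measurements
- `src/sedem/radii.py` — parameter registry, factor transforms, clamping, profiles
- `src/sedem/indices.py` — IP, IPP, reliability factor, IGCB/IGC, incidence factors
- `src/sedem/diagram.py` — radar-diagram geometry, shaded-area ratio, SVG renderer
- `src/sedem/tablet_qc.py` — tablet QC metrics and dissolution profiles
- `src/sedem/linkage.py` — rank-correlation trend matrix and qualitative predictions
- `src/sedem/synthetic.py` — 13-run design builder and study simulator
- `src/sedem/reference.py`, `src/sedem/data/` — bundled reference tables
- `src/sedem/io.py`, `config.py`, `pipeline.py`, `cli.py` — formats, config, CLI
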