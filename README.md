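# cfqct — quantitative CT of mild cystic-fibrosis lung disease

In school-age children with mild cystic fibrosis (CF), spirometry is often
normal while structural and functional lung disease is already progressing
regionally. Quantitative analysis of paired inspiratory/expiratory chest CT
can expose this: airway wall geometry and tapering capture bronchiectasis
and wall thickening, and expiratory attenuation captures air trapping
behind obstructed small airways. `cfqct` implements that analysis chain as
a tested Python library — and, because clinical scans from such cohorts are
not publicly deposited, it ships a synthetic-data layer (digital phantoms
and simulated cohorts with exact ground truth) on which every stage is
exercised end-to-end.

It is written for imaging scientists and biostatisticians who want a
reproducible, inspectable reference implementation of these endpoints, not
a clinical device.

## What it computes

**Airway geometry** (per orthogonal cross-section, aggregated over
generations G5–10 per lobe): lumen area LA, wall area WA, and the derived

    WP = 100·WA/(LA+WA),   TD = 2·√((LA+WA)/π),   WT = (TD − 2·√(LA/π))/2

with borders located by ray-cast full-width-half-maximum (FWHM) and an
optional area-preserving thin-wall refinement. Generations count from the
trachea (G1) through main (G2), lobar (G3) and segmental (G4) bronchi.

**Bronchiectasis index (BEI)**: healthy airways taper, so for every
parent→child pair the normalized excess
`max(0, (LD_child − LD_parent)/LD_parent)` is a tapering violation; the BEI
is the sum of violations per lobe or for the whole lung. A strictly
tapering tree scores 0; the index is growth-independent and needs no
adjacent-artery reference.

**Air trapping** (paired insp/exp, per lobe and total lung): TLV/RLV
volumes, mean lung attenuation MLA, the ratio E/I MLA, RVC856–950 (change
in relative volume of voxels in [−950, −856] HU over non-emphysematous
lung, range −1…0), and the nested defect percentages A1 ≥ A2 ≥ A3 under
three patient-specific thresholds `T_k = MLA_I + f_k·(MLA_E − MLA_I)`
(defaults f = 0.75/0.50/0.25).

**Cohort statistics**: median/IQR descriptives, Friedman (exact permutation
P on small designs), McNemar, Wilcoxon–Mann–Whitney (exact for small
groups), Pearson correlation maps with Fisher-z CIs and Benjamini–Hochberg
adjustment, and two lobar mixed-model analyses with random intercepts for
patient and region-within-patient: cross-sectional
`endpoint ~ age + A3 + visit` and longitudinal
`endpoint@t1 ~ age@t0 + A3@t0 + endpoint@t0`. Linear endpoints use
Huber-robust REML; the wall percentage uses a logit-link beta mixed model
(Laplace approximation).

## Worked example

```bash
python examples/02_air_trapping_metrics.py
```

builds a paired lung phantom with a 10% defect-volume fraction planted in
the right middle lobe and prints:

```
planted RML defect fraction: 0.0999
region  TLV cm3     RVC  E/I MLA    A1%    A2%    A3%
 total     71.8  -0.431    0.769  15.89   3.64   1.84
   RUL     12.0  -0.437    0.765  14.87   2.00   0.25
   RML     12.0  -0.367    0.792  22.77  11.85  10.10
   ...
```

A3 in the RML returns the planted 10% almost exactly, the defect-free lobes
sit near zero severe trapping, and the nesting A1 ≥ A2 ≥ A3 holds
everywhere — exactly the behaviour the patient-specific thresholds are
designed to give. `examples/01_measure_airway_phantom.py` does the same for
airway geometry (a planted 1.5× dilation returns a lobar BEI of 0.502
against the exact 0.5), and `examples/03_cohort_mixed_models.py` fits the
mixed models on a simulated cohort and prints estimates next to the
generative truth.

## Pipeline

The same chain runs as a config-driven pipeline with a thin CLI:

```bash
cfqct all --out run1 --seed 20260929           # bundled demo config
cfqct init-config --out run.yaml               # print the editable schema
cfqct all --config run.yaml --out run2 --seed 7
```

Outputs land under `run1/{phantoms,measures,trapping,stats,qc}` with a
`manifest.json` carrying the config, seed, package version and SHA-256 of
every output; a re-run with the same config and seed reproduces all outputs
byte-for-byte. A breath-hold QC gate flags any subject whose total lung
volume changes by more than 5% between consecutive acquisitions.

## Layout

```
src/cfqct/        volume_io, phantoms, cohort, tree, airway, trapping,
                  stats, mixed, models, pipeline, cli, evaluation
tests/            pytest suite incl. end-to-end acceptance checks
examples/         one narrative script per capability
docs/methods.md   models, assumptions, parameter defaults, limitations
```
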