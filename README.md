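# trendkit

Longitudinal CT radiomics trend analysis. From paired pre/post-condition CT
volumes (NIfTI) plus externally supplied structure masks, trendkit

1. derives body-composition tissue masks by intersecting body-region masks
   with Hounsfield-unit intervals (7 tissue classes × 29 regions = 203 masks),
2. extracts an 8-metric feature set per structure (volume in mL plus HU sum,
   Q1, Q3, mean, median, min, max),
3. pairs pre/post features per patient (features existing in only one
   condition are excluded) and computes absolute and relative deviations
   (`post − pre`; relative difference is set to exactly 0 when either value
   is 0),
4. evaluates cohort-level trends per feature via macro-averaged relative
   differences and two-sided dependent paired t-tests, with optional
   Bonferroni correction, and
5. writes tidy CSV tables and a significance-colored overview plot.

Segmentation itself is out of scope: masks are inputs, either as a directory
of per-structure binary NIfTI files (`<structure_name>.nii.gz`) or as one
integer label image plus a two-column `label name` text table. Users running
external segmenters (e.g. TotalSegmentator) can feed their output directly
through either dialect. Grids are never resampled; any shape mismatch
between a mask and its CT is a fatal error.

A phantom module generates seeded synthetic paired cohorts (ellipsoidal
structures with normal HU noise and controlled volume/HU changes), so the
entire pipeline is testable without clinical data.

## CLI

```sh
trendkit run --pre pre/ --post post/ --out results/ \
    --masks-pre masks_pre/ --masks-post masks_post/ \
    [--labels labels.txt] [--pairs pairs.tsv] [--bonferroni] \
    [--keep-interim/--no-interim] [--seed N]

trendkit schema --out tissue_schema.tsv   # dump the 203-entry tissue schema
```

`--pre/--post` are either two single NIfTI files or two directories whose
volumes are matched by identical basename (override with a two-column TSV
via `--pairs`). In directory mode, per-patient masks live in
`<masks>/<patient_id>/` (binary masks) or `<masks>/<patient_id>.nii.gz`
(label image, used with `--labels`). Input masks named after one of the 29
body regions (`C1`–`C7`, `T1`–`T12`, `L1`–`L5`, `abdominal_cavity`,
`thoracic_cavity`, `ventral_cavity`, `mediastinum`, `pericardium`) are used
to derive tissue masks; all other masks are treated as anatomical structures.

Outputs under `--out`: `pairs.tsv`, per-patient `features/*.csv` and
`deviations/*.csv`, the cohort `evaluation.csv`, `overview.svg`, a
`run_log.txt` with versions/settings, and (by default) derived tissue masks
under `tissue_masks/`. Runs with identical inputs and configuration produce
byte-identical CSVs.

HU intervals: adipose classes (SAT, VAT, IMAT, PAT, EAT) use [−190, +30] HU,
muscle [−29, +150] HU (closed intervals; the two deliberately overlap on
[−29, +30]). Bone has no canonical published interval and defaults to
[+151, +3000] HU; override via `trendkit.tissue_masks.derive_tissue_masks(...,
hu_intervals={"bone": (lo, hi)})`.

## Python API

```python
from trendkit import (read_ct, read_mask_set, derive_tissue_masks,
                      extract_features, pair_features, compute_deviations,
                      evaluate_cohort)

ct = read_ct("patient1_pre.nii.gz", condition="pre")
masks = read_mask_set("masks/patient1_pre/", ct)
features = extract_features(ct, masks)
```

Synthetic cohorts:

```python
from trendkit import PhantomSpec, EllipsoidSpec, StructureChange, write_paired_cohort

base = PhantomSpec(grid_shape=(48, 48, 48), structures=(
    EllipsoidSpec(name="C3", center=(24, 24, 24), semi_axes=(12, 12, 12),
                  hu_mean=-30.0, hu_sd=40.0),))
change = {"C3": StructureChange(volume_change_pct=-15.0, hu_shift=-10.0)}
write_paired_cohort("cohort/", base, change, n_patients=5, seed=1)
```

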