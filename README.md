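# sbrtools

Semi-quantitative DAT-SPECT analysis in Python: regional specific binding
ratio (SBR) quantification, single-subject voxel-wise depletion screening,
group voxel-wise and ROI statistics, partial-correlation molecular
connectivity, and neurotransmitter-template spatial correlation — driven by
a synthetic cohort/phantom generator so the whole pipeline is testable
without access-controlled patient data.

## Modules

| module | what it does |
| --- | --- |
| `sbrtools.cohort` | Synthetic subject-by-ROI SBR panels: group-structured multivariate-normal draws with planted partial-correlation (precision) structure, two-timepoint trajectories with within-subject coupling, covariates; lossless TSV I/O. |
| `sbrtools.phantom` | 3-D SPECT-like phantoms: ellipsoidal target regions + posterior slab reference on a labelled grid, voxel values `(SBR + 1) × reference`, Gaussian smoothing, additive noise. |
| `sbrtools.sbr` | Regional means, SBR tables (`target/reference − 1`, occipital reference union), voxel-wise parametric SBR images. |
| `sbrtools.screen` | Single-case voxel-wise t-test (Crawford–Howell form), cluster-extent thresholding (6/18/26-connectivity, strict `> extent`), striatal-overlap classification. |
| `sbrtools.groupstats` | Voxel-wise OLS GLM contrasts with nuisance covariates, permutation cluster-FWE (Freedman–Lane), paired difference maps, per-ROI ANCOVA / Wilks'-lambda MANCOVA, two-timepoint change-score contrast (= mixed-model group×time interaction). |
| `sbrtools.connectivity` | Full partial-correlation networks per group (precision-matrix route), Fisher-z edge comparison with k-corrected variance, alteration percentages, network-level χ². |
| `sbrtools.ntmap` | Region-level patient-vs-control z-scores, Spearman correlation with template maps (e.g. DAT/SERT), group-label permutation inference with BH adjustment across templates. |

## CLI

Each stage ships as a console script (TSV tables, NIfTI-1 volumes, YAML
configs):

```bash
simulate-cohort --config cohort.yaml --out panel.tsv
simulate-phantoms --config phantom.yaml --panel panel.tsv --outdir vols/
sbr --volume subj.nii.gz --atlas vols/atlas.nii.gz --regions vols/regions.tsv --out sbr.tsv
screen-subject --subject s.nii.gz --controls hc_dir/ --atlas vols/atlas.nii.gz \
    --regions vols/regions.tsv --p 0.05 --extent 100 --out report.tsv
group-voxel --volumes list.tsv --groups PD,HC --covariates age \
    --cluster-p 0.005 --n-perm 1000 --seed 7 --out clusters.tsv
roi-stats --panel panel.tsv --covariates age,sex,updrs3 --out roi_stats.tsv
connectivity --panel panel.tsv --network mesocorticolimbic --groups SWEDD,HC \
    --alpha 0.01 --out edges.tsv
ntmap --panel panel.tsv --patients PD --controls HC \
    --templates dat.tsv,sert.tsv --n-perm 1000 --seed 3 --out ntmap.tsv
```

A cohort YAML may be a preset (`preset: default` with `n_pd`, `n_swedd`,
`n_hc`, `rho_t`, `seed`) or fully explicit (`rois`, per-group `means`/`sds`/
`followup_means`, optional per-group `partial_corr` matrices). Omitting
`--config` uses the default PD/SWEDD/HC cohort.

## Conventions

- All randomness flows from one seeded `numpy.random.Generator`; identical
  config + seed gives bit-identical panels and phantoms.
- Volumes and atlases must share shape exactly; no resampling, registration
  or partial-volume correction is performed.
- "More than N voxels" cluster rules are strict (`> N`).
- Panels are TSV with metadata columns `subject_id, group, timepoint, age,
  sex, updrs3` followed by one column per ROI.
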