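# ecmap

Eigenvector centrality mapping (ECM) of resting-state fMRI, with
permutation cluster-mass group inference, marker association and
single-subject genotype-risk prediction — plus a synthetic BOLD cohort
generator so every stage is testable without any imaging download.

## The problem

Functional brain networks reorganize early in Alzheimer's disease, and
carrying an APOE-ε4 allele is the main genetic risk factor. Eigenvector
centrality assigns every voxel an importance score proportional to the
summed scores of the voxels it is connected to: for the voxelwise Pearson
correlation matrix R, the map is the dominant eigenvector **v** of

    C = R + 1,        C v = λ v,    v > 0,

where the +1 shift puts connectivity on the non-negative scale [0, 2] so
the Perron–Frobenius theorem guarantees a positive dominant eigenvector.
With N voxels, C is far too large to store — but C = M Mᵀ + J for the
row-normalized data matrix M (N×T) and the all-ones matrix J, so the power
iteration evaluates C·v as M(Mᵀv) + (Σv)·1 at O(N·T) per step without ever
forming C. That matrix-free computation, the permutation cluster-mass test
that locates group differences in the resulting maps (automatic
cluster-forming threshold, at most one expected false-positive cluster per
image, intersection of the analyses with and without motion regression),
and the downstream association/prediction statistics are what this package
provides, for researchers studying network-level biomarkers of AD risk.

## Worked example

Simulate a 40-subject cohort with a strong (0.8) hub-connectivity deficit
in carriers and run the full pipeline:

```python
from ecmap import CohortSpec, PipelineConfig, run_full_pipeline

spec = CohortSpec(n_subjects=40, n_timepoints=150,
                  carrier_hub_deficit=0.8, seed=11)
cfg = PipelineConfig(out_dir="demo", cohort=spec,
                     n_permutations=200, permutation_seed=11,
                     n_boot=1000, bootstrap_seed=11)
report = run_full_pipeline(cfg)
```

The run prints/persists (abridged):

```
qc:                 n_total 40, kept 39, excluded 1      # motion > 0.5 mm
analysis mask:      4000 voxels
cluster test plain: forming t = 1.5, mass threshold 148.2, 2 significant
cluster test mreg:  forming t = 1.5, mass threshold 148.6, 2 significant
intersection:       670 voxels = 42880 mm^3
group ANOVA:        F = 7.75, p = 0.0084
prediction:         accuracy 0.769, AUC 0.688, 95% CI (0.477, 0.883)
with age added:     accuracy 0.744, AUC 0.786
```

Reading this: one subject failed the 0.5 mm motion screen; both analyses
(with and without motion regression) find significant clusters — the
decreased-centrality cluster recovers the planted hub, and a compensatory
increased-centrality region appears because centrality maps are
unit-norm, so connectivity lost by the hub redistributes. Cluster-mean
centrality separates carriers from noncarriers (ANOVA), and leave-one-out
logistic prediction of carriership from it is above chance. Marker fits
(`demo/association/marker_fits.tsv`) report slope, p and R² per marker,
whole-sample and per genotype stratum.

The same pipeline is scriptable from the shell:

```bash
ecmap run-all --out demo --seed 11 --n-subjects 40 --n-perm 200
ecmap simulate --out sim --seed 4 --n-subjects 3 --grid-shape 8,8,6 --n-timepoints 40
ecmap ecm --in sim/sub-000_bold.nii.gz --mask mask.nii.gz \
          --motion sim/sub-000_motion.txt --regress-motion --out ecm.nii.gz
```

## Layout

```
src/ecmap/cohort.py       synthetic BOLD cohort generator
src/ecmap/ecm.py          masks, filtering, motion regression, fast ECM
src/ecmap/cluster.py      voxelwise GLM + permutation cluster-mass test
src/ecmap/association.py  cluster means, marker fits, group ANOVA
src/ecmap/prediction.py   logistic LOOCV, ROC/AUC, bootstrap CI
src/ecmap/pipeline.py     orchestration, file formats, provenance
src/ecmap/cli.py          command-line interface (`ecmap ...`)
docs/methods.md           model, generator and numerical choices
```
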