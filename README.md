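# mclrad

PET radiomics and metabolic-risk survival analysis for mantle cell
lymphoma (MCL).

Pretherapy [¹⁸F]FDG-PET carries prognostic information in lymphoma beyond
the clinical indices: the average glucose metabolism of the total
metabolic tumour volume (SUVmean) and its spatial heterogeneity (the
co-occurrence-matrix feature Entropy) are associated with early
progression in MCL. `mclrad` implements that analysis chain end to end,
for imaging scientists who want to run or stress-test it on their own
volumes or on fully synthetic cohorts:

- **Segmentation** — total metabolic tumour volumes (TMTV) grown from
  seed voxels by the 41% SUVmax threshold, iterated to a fixed point
  (26-connectivity, configurable).
- **Radiomics** — SUVmax/SUVmean/SUVpeak, TMTV, TLG = TMTV × SUVmean, and
  the 16 grey-level co-occurrence (Haralick) texture features in 3-D:
  distance-1 offsets along the 13 unique directions, symmetrized
  matrices, ≥20 voxel pairs per direction, arithmetic mean over valid
  directions. Entropy is −Σ p(i,j) log₂ p(i,j).
- **Harmonization** — parametric empirical-Bayes ComBat across scanner
  batches, applied to the feature table.
- **Risk models** — MIPI and MIPI-b (score = 0.03535·age +
  0.6978·[ECOG≥2] + 1.367·log₁₀(LDH/ULN) + 0.9393·log₁₀(WBC) [+
  0.02142·Ki-67]), the majority-vote *metabolic risk* from dichotomized
  SUVmean (>3.55) and Entropy (>3.5), and the modified MIPI-m/MIPI-bm
  (metabolic risk shifts the MIPI category ±1, capped at 1..3).
- **Survival & prediction** — Kaplan–Meier, log-rank, Cox hazard ratios,
  Youden-J ROC cut-offs, univariate/forward-selection logistic
  regression, and a one-hidden-layer tanh MLP for 2-year PFS over five
  stratified 70/30 splits.
- **Synthetic cohorts** — a generator with known ground truth (correlated
  random-field lesion textures at 5.5 × 5.5 × 3.3 mm voxels, scanner
  batch effects, a logistic/proportional-hazards outcome model driven by
  SUVmean and Entropy) so every stage is testable without patient data.

## Worked example

Run the full chain on a synthetic 107-patient cohort (feature-level
simulation, five scanners with batch effects, ComBat on):

```python
from mclrad.pipeline import PipelineConfig, run_pipeline
from mclrad.synthdata import CohortConfig

res = run_pipeline(PipelineConfig(cohort=CohortConfig(n_patients=107, seed=3)))
two = res.survival["metabolic_risk_2cat"]
print("high-risk n:", two["n_per_group"]["high"])
print("median PFS high/low:", two["median_pfs_months"])
print("log-rank p:", two["logrank"]["p"])
print("HR high vs low:", two["cox"]["hazard_ratios"]["high"])
```

prints (seed 3):

```
high-risk n: 39
median PFS high/low: {'low': 44.3, 'high': 18.5}
log-rank p: 0.0009
HR high vs low: 2.12
```

Patients with high metabolic risk (SUVmean > 3.55 **and** Entropy > 3.5)
progress markedly earlier — a median PFS of 18.5 vs 44.3 months and a
hazard ratio of ~2.1, driven by the generator's built-in SUVmean/Entropy
outcome model.

The same chain is scriptable from the shell:

```sh
mclrad simulate --out cohort/ --seed 17
mclrad segment  --volume cohort/volumes/P0000.nii.gz --seeds cohort/seeds.csv --out mask.nii.gz
mclrad extract  --volume cohort/volumes/P0000.nii.gz --mask mask.nii.gz --out features.csv
mclrad run      --out results/ --seed 17        # full pipeline + manifest
```

A note on Entropy scales: image-extracted Entropy depends on the
grey-level bin count (default G=64) and log base (default 2); the 3.5
cut-off applies to the scale it was derived on. For synthetic cohorts the
`--recut` pipeline flag recomputes both cut-offs by ROC on the cohort.

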