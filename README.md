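# relaxo

Desk-scale multicenter MRI relaxometry of the rat brain, fully in silico.

Quantitative T1 and T2 relaxation times are tissue-specific and serve as
imaging biomarkers, but pooling them across imaging centers requires
knowing how much of the observed variation comes from the scanner, the
fitting software, and the segmentation pipeline rather than from biology.
`relaxo` rebuilds that whole comparison chain as a tested Python package
for anyone studying quantitative-MRI reproducibility: it simulates
multicenter inversion-recovery and multi-echo acquisitions on a digital
rat-brain phantom, fits voxel-wise T1/T2 maps with interchangeable
optimizers, parcellates the brain into 29 regions by multi-atlas
maximum-probability fusion, and quantifies every pairwise agreement
(center vs center, optimizer vs optimizer, atlas set vs atlas set, scan vs
rescan).

## Models

* **T1 (inversion recovery, magnitude):** `s(TI) = |A (1 − B e^(−TI/T1))|`,
  fitted per voxel over the seven-point protocol TI = 247…5000 ms
  (TR = 6500 ms). B is free; B = 2 is perfect inversion.
* **T2 (multi-echo decay):** `s(TE) = A e^(−TE/T2)` over 28 echoes,
  TE = 8…224 ms (TR = 600 ms).
* **Noise:** Rician, `sqrt((s+n₁)² + n₂²)`, the magnitude-MRI distribution
  with floor σ√(π/2) at zero signal.
* **Fusion:** per-voxel plurality vote over co-registered hard
  parcellations; Dice `2|A∩B|/(|A|+|B|)` quantifies overlap.
* **Agreement:** Bland-Altman (mean difference ± 2 SD), ordinary
  least-squares regression against the identity line with R², symmetric
  mean percent error, Mann–Whitney / Wilcoxon tests (exact for small
  samples), Shapiro–Wilk normality gate, and the scan–rescan
  two-standard-deviation criterion.

Estimates are filtered to the plausible ranges (0, 3000] ms for T1 and
(0, 300] ms for T2; everything else is marked invalid and excluded from
regional statistics.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
import relaxo as rx

spec = rx.PhantomSpec(grid_shape=(32, 32, 16), seed=1)
labels = rx.make_label_phantom(spec)
t1_truth, t2_truth, pd_map = rx.truth_maps(labels, spec)

protocol = rx.default_ir_protocol()
series = rx.simulate_ir_series(t1_truth, pd_map, protocol, noise_sigma=18.0, seed=2)

t1_map = rx.fit_t1_map(series, rx.FitOptions(optimizer=rx.Optimizer.LEAST_SQUARES_LM))
stats = rx.region_means(t1_map, labels)
print(stats.head(5)[["region_name", "n_valid_voxels", "mean_ms", "sd_ms"]].to_string(index=False))

truth = np.array([spec.region_truth[i].t1_ms for i in stats["label_id"]])
print(f"mean percent error vs truth: {rx.mean_percent_error(truth, stats['mean_ms'].to_numpy()):.3f}%")
```

prints

```
           region_name  n_valid_voxels     mean_ms      sd_ms
3rd and 4th ventricles              78 2508.784230 132.320074
            Amygdala L             234 1803.603662  73.435076
            Amygdala R             233 1805.811827  73.461241
            Brain stem             233 1659.524478  70.264724
     Caudate-putamen L             233 1760.764134  73.509546
mean percent error vs truth: 0.539%
```

Each row is one parcellation region: the number of voxels whose fit passed
the plausibility filter, and the mean ± SD of the fitted T1 there. The
ventricle region sits near its 2500 ms CSF ground truth with the larger
spread expected of a small, high-T1 structure; the parenchymal regions
recover their truths (1650–1810 ms) to a few ms despite the noise, and the
regional means agree with ground truth to ~0.5% on average at this noise
level.

A full study (several subjects, centers, optimizers and atlas sets, with
scan–rescan replicates) runs from one YAML config:

```sh
relaxo run-study --config study.yaml --out out/
```

which writes per-subject regional tables, inter-center and inter-pipeline
agreement reports, segmentation comparisons (Dice + parcel volumes) and
scan–rescan reports as CSV, alongside all simulated NIfTI volumes. The
`simulate`, `fit-t1`, `fit-t2`, `fuse`, `dice`, `stats` and `compare`
subcommands expose the individual stages.

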