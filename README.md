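# otmsi

Annotation, optimal-transport deconvolution and spatially aware segmentation
of mass spectrometry imaging (MSI) data.

## The problem

An MSI experiment records one mass spectrum per spatial pixel of a tissue
section. Two features of this kind of data routinely break naive analyses:

* **Overlapping isotopic envelopes (OIE).** At finite resolving power the
  isotopic peaks of ions with similar masses merge. A single peak then mixes
  the spatial distributions of several analytes — in extreme cases the
  apparent localization of a weak ion is completely inverted by a stronger
  neighbor one nucleon lighter.
* **Pixel-to-pixel variability.** Ionization efficiency, ion statistics and
  matrix inhomogeneity add per-pixel intensity fluctuations unrelated to
  analyte concentration, so intensity-threshold segmentations come out
  speckled and unreliable.

`otmsi` addresses both: per-ion signal is estimated by fitting theoretical
isotopic envelopes to each pixel spectrum with an optimal-transport linear
program (separating merged envelopes without m/z binning or peak alignment),
and each deconvolved ion image is segmented into high/low-concentration
regions with a spatially aware univariate Gaussian mixture.

## The model

For a centroided pixel spectrum normalized to unit intensity (masses `m_i`,
intensities `a_i`) and reference envelopes `μ_c` (from aggregated isotopic
fine structure of the candidate formulas), the deconvolution solves

```
min   Σ_ij γ_ij |m_i − m_j|  +  κ_mix Σ_i e_i  +  κ_comp Σ_cj t_cj
s.t.  Σ_j γ_ij + e_i   = a_i            (experimental mass dispatched)
      Σ_i γ_icj + t_cj = p_c μ_cj       (envelope scaling)
      γ, e, t, p ≥ 0
```

— a Wasserstein transport plan `γ` with two "trash" channels: experimental
signal may be discarded at κ_mix per unit and envelope signal at κ_comp per
unit, so the κ parameters act as soft m/z matching windows. The reported
proportion of ion `c` is the experimental mass transported to its envelope;
proportions plus the unexplained fraction sum to 1. Whole envelopes compete
for the merged experimental mass, which is what resolves OIE.

Each deconvolved ion image is then segmented with a univariate k-component
Gaussian mixture in which every pixel carries its own mixing weights: after
each E-step the posteriors are averaged over a Chebyshev radius-`r`
neighborhood with Gaussian distance weights, raised to `β/(β+1)` and
renormalized to form the next pixel-wise prior. `β = 0` recovers a plain
GMM; large `β` enforces neighborhood consensus and suppresses speckle.

A full synthetic data generator (three potassiated lipids on a 40×40 grid
with region-dependent negative-binomial ion counts, multinomial isotope
statistics, background noise peaks and Gaussian peak broadening) makes every
stage testable without downloading data.

## Worked example

```python
from scipy.stats import pearsonr
from otmsi import (SimulationConfig, simulate_dataset, centroid_dataset,
                   DeconvolutionConfig, deconvolve_dataset, SegmentationConfig,
                   kmeans_threshold_segment, spatial_dgmm_segment,
                   segmentation_accuracy)

cfg = SimulationConfig()                       # 40x40 px, three lipid ions
ds, truth = simulate_dataset(cfg, seed=0)
cds = centroid_dataset(ds, height_fraction=0.2, max_width=0.4)
images = deconvolve_dataset(cds, cfg.envelopes(), DeconvolutionConfig(0.2, 0.5))
for label in cfg.labels:
    rho = pearsonr(truth.counts[label].ravel(),
                   images[label].values.ravel()).statistic
    naive = kmeans_threshold_segment(images[label], seed=0)
    aware = spatial_dgmm_segment(images[label],
                                 SegmentationConfig(k=2, r=3, beta=6.0), seed=0)
    print(f"{label}: rho={rho:.3f}"
          f"  naive={segmentation_accuracy(naive, truth.high_mask[label]):.1f}%"
          f"  aware={segmentation_accuracy(aware, truth.high_mask[label]):.1f}%")
```

prints

```
PC(38:1): rho=0.999  naive=99.8%  aware=100.0%
PA(44:0): rho=0.989  naive=93.2%  aware=99.1%
PC(38:0): rho=0.969  naive=94.9%  aware=99.6%
```

`rho` is the Pearson correlation between each lipid's true simulated ion
counts and its deconvolved signal — near 1 even for PA(44:0) and PC(38:0),
whose monoisotopic peaks are buried inside the PC(38:1) envelope and whose
raw single-ion images are badly distorted. The percentages score the
high/low-concentration segmentations against the ground-truth masks; the
spatially aware segmentation beats the naive K-means threshold for every
lipid.

The same stages are available from the shell:

```bash
otmsi simulate --seed 0 --out demo/
otmsi preprocess demo/simulated.imzML --no-normalize \
      --centroid-height-fraction 0.2 --centroid-max-width 0.4 \
      --out demo/centroided.imzML
otmsi annotate demo/centroided.imzML --library demo/library.csv --out out1.csv
otmsi deconvolve demo/centroided.imzML --library demo/library.csv \
      --kappa-mixture 0.2 --kappa-components 0.5 --out out2.csv
otmsi segment out2.csv --r 3 --beta 6 --out out3.csv
```

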