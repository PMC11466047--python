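# myoshg

Quantitative analysis of label-free second-harmonic-generation (SHG) and
autofluorescence (AF) microscopy of myocardial tissue sections:

* **Sarcomere length (SL)** from striation images: line profiles along the
  myofibril axis, local-minima detection, and exclusion of minima inside
  A-bands.
* **Capillarization metrics** from categorized instance masks: capillary
  density per field of view, capillary density per cardiomyocyte area, and
  the capillary-to-cardiomyocyte ratio.
* **Z-stack preprocessing**: frame averaging, Gaussian/Wiener filtering,
  translational drift correction by phase correlation, and global/adaptive
  binarization.
* **Synthetic ground truth**: generators for striated myosin-lattice images
  (Gaussian PSF + Poisson photon noise) and cross-sectional tissue layouts
  with exact instance masks, so every stage is testable without microscope
  data.

## Background

In forward-SHG images of cardiomyocytes only the rod domain of the myosin
filament has contrast, so each sarcomere appears as a bright A-band with a
dark M-line gap at its centre, flanked by dark I-bands centred on the
Z-lines. SL is the Z-line-to-Z-line distance: the spacing of adjacent
*I-band* intensity minima along the myofibril axis. When the optics resolve
the two halves of the A-band (the "double-band" regime) the M-line produces
an extra local minimum halfway between Z-lines; measuring adjacent minima
without excluding those M-line minima returns roughly half the true SL. The
package automates that exclusion with a prominence/periodicity
classification rule (see `docs/methods.md`).

Capillarization metrics are pure count-and-area arithmetic over instance
label maps whose labels carry a category (cardiomyocyte or capillary);
segmentation itself is out of scope — masks come from the synthetic
generator or any external instance-segmentation tool.

## Worked example

```python
from myoshg import (LatticeParams, generate_lattice_image,
                    measure_sarcomere_lengths, SarcomereConfig)

params = LatticeParams(period_um=1.84, psf_fwhm_um=0.25, pixel_um=0.04, seed=1)
image, truth = generate_lattice_image(params)
m = measure_sarcomere_lengths(image)
print(f"SL {m.mean_um:.3f} +- {m.sd_um:.3f} um, n={m.n}, "
      f"regime={m.band_regime_detected}, excluded={m.n_excluded_aband}")

naive = measure_sarcomere_lengths(
    image, config=SarcomereConfig(exclude_aband=False, sl_bounds_um=None))
print(f"naive (no A-band exclusion): {naive.mean_um:.3f} um")
```

prints

```
SL 1.840 +- 0.002 um, n=7, regime=double, excluded=8
naive (no A-band exclusion): 0.920 um
```

The generated lattice has a true period of 1.84 um (the mean SL of adult
murine left-ventricular myocardium). The measurement recovers it to within
a small fraction of a pixel after excluding the 8 M-line minima it
classified as A-band-internal; the naive adjacent-minima estimate collapses
to half the period, which is why the exclusion rule is load-bearing.

Equivalent CLI:

```sh
myoshg simulate-lattice --period-um 1.84 --seed 1 --out sim/
myoshg measure-sl sim/lattice.tif --out sl/
myoshg simulate-tissue --seed 2 --out tissue/
myoshg capquant tissue/tissue_masks.tif --categories tissue/tissue_categories.csv --out cq/
```

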