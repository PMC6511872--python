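# fric — Fluorescence Ratiometric Imaging of Chromatin

`fric` quantifies the **spatial distribution of euchromatin and
heterochromatin in cell nuclei** from two-channel fluorescence microscopy.
It is written for cell biologists studying chromatin organization at the
nuclear periphery — for example the loss of peripheral heterochromatin
under lamin-associated perturbations, or its redistribution after
treatment with histone acetylation modifiers — using live cells
co-expressing a euchromatin marker (such as the histone variant
H3.3-EGFP) and a total-chromatin marker (such as H2B-mCherry).

## The method

For each nucleus, segmented on the total-chromatin channel (Gaussian
smoothing of size 5, Otsu threshold, objects above 50 px equivalent
diameter not touching the border) at its equatorial optical section (the
z-slice with the largest cross-sectional area), both channels are
normalized by their in-mask mean and divided pixelwise:

```
r(x) = (H3.3(x) / ⟨H3.3⟩) / (H2B(x) / ⟨H2B⟩)
```

so r(x) > 1 marks relatively euchromatic pixels and r(x) < 1 relatively
heterochromatic ones, independent of expression level and detector gain.
A Euclidean distance transform of the nucleus mask divides it into
n = 40 concentric zones of equal width from periphery (zone 1) to
interior (zone 40) — about 150 nm per zone for a typical 6 µm nuclear
radius — and the mean of r per zone forms the **radial profile**.  Two
scalar summaries follow:

* the **relative ratio P/I** — pooled mean of r over peripheral zones
  1–3 divided by the pooled mean over interior zones 4–40;
* the **GLCM texture variance** of the inverse ratio (H2B/H3.3), an
  8-level co-occurrence statistic measuring structural organization, in
  the 10 outermost zones and in the whole nucleus.

Groups of nuclei are compared zone by zone with the unpaired
pooled-variance Student *t*-test (α = 0.05, mean ± SEM reporting,
star labels `*`…`****` at 0.05/0.01/0.001/0.0001), including the count of
consecutively significant peripheral zones, a P/I comparison, and
time-lapse zone-1 trajectories.  Image quality control excludes nuclei
from blurred fields (log-log power-spectrum slope deviating > 2 SD from
the batch), saturated objects (> 0.2% of pixels at detector maximum) or
poor signal-to-noise (Otsu threshold > 0.15 above the batch median on the
normalized intensity scale).  Pearson and Manders coefficients validate
the ratio against independent immunostains.

A built-in synthetic-image generator produces two-channel nuclei with
known ground truth (mask, zone map, radial modulation g, true P/I) under
a realistic camera model (shared multiplicative texture, diffraction-soft
edge, Poisson shot noise, Gaussian read noise, 12-bit quantization), so
the entire pipeline is testable without a microscope.

## Worked example

Simulate a control cohort and one with a 20% euchromatin depression over
the three outermost zones, analyze both, and compare:

```bash
$ fric simulate --n 10 --seed 1 --out cohort
wrote 20 nuclei to cohort
group
control      1.0
depressed    0.8

$ fric analyze cohort/control_*.ome.tif --euc-channel euchromatin \
      --total-channel total --group control --out control_results
analyzed 10 image(s): 10 nuclei -> control_results

$ fric analyze cohort/depressed_*.ome.tif --euc-channel euchromatin \
      --total-channel total --group depressed --out depressed_results
analyzed 10 image(s): 10 nuclei -> depressed_results

$ fric compare control_results/profiles.csv depressed_results/profiles.csv \
      --out comparison
significant peripheral run: 40 zone(s) -> comparison
```

The `simulate` summary prints each group's true P/I (1.0 and 0.8).  The
comparison table (`comparison/comparison.csv`) starts:

```
zone,t,p,significant,stars,mean_1,sem_1,mean_2,sem_2
1,60.34,3.1e-22,True,****,1.0037,0.0008,0.8359,0.0027
2,55.55,1.4e-21,True,****,1.0011,0.0004,0.8378,0.0029
3,31.38,3.6e-17,True,****,1.0010,0.0005,0.8679,0.0042
4,4.09,0.0007,True,***,1.0005,0.0007,0.9780,0.0054
...
P/I,49.86,9.5e-21,True,****,1.0007,0.0004,0.8308,0.0034
```

Zones 1–3 of the depressed group sit near 0.84 against 1.00 in controls
and the recovered P/I is 0.83 — the injected 0.8 up to the small
segmentation-edge bias discussed in `docs/methods.md`.  Because the
per-nucleus normalization fixes each nucleus's mean ratio at 1, a
peripheral deficit necessarily raises interior zones slightly, which is
why deep zones also reach significance at these sample sizes; the
peripheral zones carry the biological signal.  `fric compare` also writes
`radial_profile.png`, the mean ± SEM profile of the first 10 zones with
star annotations.

The same machinery is available as a library (`fric.analyze_stack`,
`fric.compare_zones`, `fric.generate_dataset`, …) for scripted analyses.

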