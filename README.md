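# osmochrom

Quantitative analysis of how a transient hyposmotic stimulus (brief
exposure to diluted PBS, which swells cells and their nuclei) remodels
chromatin and RNA polymerase II dynamics. The package is aimed at
cell-biology and epigenomics groups running the corresponding bench
assays — FLIP photobleaching of GFP-tagged Pol II, DAPI imaging, MNase/
DNase digestion gels, EU/EUTP incorporation, Pol II ChIP-seq — who need the
downstream numbers computed reproducibly, plus a synthetic-data layer that
makes every estimator testable against known ground truth.

## What it computes

**FLIP kinetics** (`osmochrom.flip`). A three-population kinetic model of
nuclear Pol II — free, initiation-bound (dissociation rate `k_init_off`),
and elongation-engaged (`k_elong_off`) — is forward-simulated under the
half-nucleus bleaching protocol (a pulse every 5 s for 900 s), and observed
decays are inverted by bounded multi-start least squares on

    f(t) = a e^(-b t) + c e^(-d t) + g e^(-h t),    a..h >= 0.

Amplitude shares estimate the state fractions (fastest component = free,
slowest = engaged); `ln 2 / rate` gives half-lives in minutes. Shipped
presets encode the two conditions: isosmolar (engaged half-life 16 min) and
hyposmotic (140 min, with the free pool shifted into the initiating pool).

**Chromatin condensation and accessibility** (`osmochrom.chromatin`). The
per-nucleus DAPI coefficient of variation, CV = SD/mean of masked pixel
intensities (condensed chromatin has bright heterochromatic foci, hence
high CV), with Welch/Mann-Whitney group comparison; and gel-lane
densitometry that decomposes a nuclease-digestion profile on a log10(bp)
axis into mono/di/tri-nucleosome bands plus a sub-nucleosomal smear by
non-negative least squares, summarized by an accessibility score
(smear + mononucleosome fraction).

**Transcription assays** (`osmochrom.assays`). Saturating-exponential fits
`S(t) = s_max(1 - e^(-kt))` to incorporation time courses, percent signal
increase between conditions as a fitted-AUC ratio over a window (default
the first 50 min), transcription-unit copy times (length/rate: a median
~14 kbp unit at 1.1–2.5 kb/min takes 6–13 min), and qRT-PCR 2^-ddCt ratios.

**ChIP-seq peak post-processing** (`osmochrom.peaks`). narrowPeak/BED I/O,
IgG background subtraction, condition-specific "new peaks" (no control
overlap, fold enrichment > 30 — or 15 for the elongating PhosphoS2 form —
and p < 1e-9), cross-antibody containment percentages, nearest-TSS gene
assignment, and a PASTAA-style TF association score: -log10 of the most
significant hypergeometric upper-tail p-value of the overlap between an
affinity-ranked gene list's top-k and a target gene set, over a grid of
cutoffs k.

**Synthetic data** (`osmochrom.simulate`) generates all of the above with
ground truth attached; **workbench** (`osmochrom.workbench`) ties stages
into seeded, config-driven runs.

The curve models are scikit-learn estimators (`TriExponentialDecay`,
`SaturatingExponential`, `GelBandMixture`) and compose with sklearn
pipelines; the module-level functions are thin wrappers.

## Worked example

Simulate ten isosmolar FLIP traces at 1% measurement noise, fit each, and
read off the engaged-polymerase half-life:

```python
import numpy as np
from osmochrom import (ISO_PRESET, fit_triexponential, gen_flip_trace,
                       half_life, population_fractions)
from osmochrom.simulate import FLIPSimConfig

hls = []
for i in range(10):
    trace, truth = gen_flip_trace(
        FLIPSimConfig(model=ISO_PRESET, noise_sd=0.01, seed=42 + i))
    fit = fit_triexponential(trace, seed=42 + i)
    hls.append(half_life(fit.rates[2]))

fit = fit_triexponential(
    gen_flip_trace(FLIPSimConfig(model=ISO_PRESET, noise_sd=0.01, seed=42))[0],
    seed=42)
print("fractions :", tuple(round(f, 3) for f in population_fractions(fit)))
print("half-lives (min):", tuple(round(h, 2) for h in fit.half_lives_min))
print("R^2 :", round(fit.r_squared, 4))
print("group mean slowest half-life: %.2f min (n=10)" % np.mean(hls))
```

prints

```
fractions : (0.394, 0.314, 0.291)
half-lives (min): (0.09, 1.27, 16.86)
R^2 : 0.995
group mean slowest half-life: 16.28 min (n=10)
```

The recovered fractions match the preset's (0.40, 0.30, 0.30) generating
values; the fastest half-life (~0.09 min) is the free pool, set by the
bleach protocol itself; the middle (~1.3 min) is the initiation-bound pool
(`ln 2 / 0.01 s^-1`); and the slowest recovers the preset's 16-minute
engaged-polymerase residence time, the quantity that lengthens roughly
nine-fold after hyposmotic modulation.

The same workflow is available from the shell:

```sh
osmochrom flip simulate --preset iso --noise-sd 0.01 --seed 42 -o iso.tsv
osmochrom flip fit iso.tsv
osmochrom assay ttime --length 14000 --rate 1100   # -> 12.73 min (rounded: 13 min)
osmochrom demo --seed 1 --outdir demo_run          # every stage end to end
```

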