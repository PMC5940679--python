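# Methods

This note documents the models, conventions and numerical choices behind
`osmochrom`. The package quantifies how a transient hyposmotic stimulus
(brief exposure to diluted PBS, which swells cells and nuclei) changes
chromatin state and RNA polymerase II dynamics, using four largely
independent readouts: FLIP photobleaching kinetics, DAPI condensation
statistics, nuclease-digestion densitometry and incorporation assays, plus
post-processing of ChIP-seq peak tables. All stages are exercisable on
synthetic data whose generating parameters are returned alongside, so every
estimator is tested as a round trip against known truth.

## FLIP kinetics

### Model

Fluorescence loss in photobleaching (FLIP) repeatedly bleaches one half of
the nucleus (a pulse roughly every 5 s over 900 s, at full laser power) and
reads out GFP-tagged Pol II fluorescence in the other half. The model
partitions polymerase into three pools:

| pool | meaning | exchange |
|---|---|---|
| free | diffusing, well mixed between pulses | bleached at the pulse rate |
| initiation-bound | on DNA, not engaged | dissociates at `k_init_off` |
| elongation-engaged | productively transcribing | dissociates at `k_elong_off` |

Dissociated molecules join the free pool and are then lost to the bleach
region within a few pulses; rebinding is folded into this
dissociation-dominated scheme (an explicit finite free-pool mixing rate is
available as a config option, default "complete", justified by GFP
diffusion being much faster than the 5 s pulse interval). Bleaching is
instantaneous and complete within the bleached region; a partial-bleach
efficiency knob exists and defaults to 1. Each pulse removes the bleached
fraction of the free pool, so a pure free pool decays exactly as
`(1 - bleach_fraction)^n` after n pulses, and a locked engaged pool
(`k_elong_off = 0`) stays at 1 — both are unit-tested identities.

The observed trace is therefore close to a sum of three exponentials,

    f(t) = a exp(-b t) + c exp(-d t) + g exp(-h t),   a,b,c,d,g,h >= 0,

with the fastest component reporting the free pool (its rate is set by the
bleach protocol, `-ln(1 - bleach_fraction)/pulse_interval ≈ 0.14/s` for the
default half-nucleus, 5 s protocol), the middle component the
initiation-bound pool, and the slowest component the engaged pool. All
three components decay; rates are stored non-negative because fluorescence
loss cannot grow. Component-to-state assignment is by rate ordering, the
only rule consistent with the protocol. Amplitude shares at t = 0 estimate
the state fractions, and `ln 2 / rate` (converted to minutes) gives
half-lives; internal time is seconds throughout.

### Presets

Two presets define the study conditions.

* `iso` (isosmolar): fractions (0.40, 0.30, 0.30), `k_init_off = 0.01/s`,
  `k_elong_off = ln2/960 s` (engaged half-life 16 min).
* `hypo` (after transient hyposmotic modulation): fractions
  (0.25, 0.45, 0.30) — the free pool shrinks in favour of the initiating
  pool while the engaged share is unchanged — and
  `k_elong_off = ln2/8400 s` (engaged half-life 140 min).

### Inference

`fit_triexponential` / `TriExponentialDecay` performs bounded nonlinear
least squares with 25 starts: candidate rate triples are drawn from a
log-spaced grid spanning `[1/duration, 1/pulse_interval]`, amplitudes are
initialized by non-negative linear least squares at fixed rates, and the
lowest-RSS refined solution wins. Two refinements matter numerically:

* **Polish.** The trust-region solver is restarted from its own optimum up
  to three times; each restart resets the trust radius and descends several
  further orders of magnitude on (near-)noiseless data, which is what makes
  the 1e-4 relative-recovery guarantee on exact samples attainable.
* **Nested-model tie-break.** Degenerate data (fewer than three true
  components) admit solutions that split one exponential across two nearly
  identical rates. After fitting, pairs of components are tentatively
  merged (amplitude-weighted rate); a merge is kept only when it does not
  worsen the residual beyond float noise and strictly reduces the amplitude
  mass outside the dominant component. This returns the canonical sparse
  representative without affecting genuinely three-component fits.

R² is `1 - RSS/TSS`. If no start converges the fit raises with per-start
diagnostics rather than returning a silent partial result.

Identifiability: the 140 min preset decays only ~7% over the 900 s window,
so its half-life is weakly identified; group recovery (10 cells, 0.2%
noise) is accurate to well within the documented ±25% band, while the
16 min preset at 1% noise recovers within ±10%. Per-condition half-lives
are computed per cell and then averaged (mean ± SEM, Welch's t between
conditions); non-converged fits are excluded with a logged count.

The stochastic simulation mode tracks individual molecules (state, spatial
half, fluorescence) with per-interval dissociation probabilities
`1 - exp(-k dt)` and per-pulse Bernoulli bleaching; it matches the
deterministic compartment expectation within 3 standard errors at
10^4 molecules and exists to validate that the deterministic propagator is
the correct expectation, and to let users study shot-noise-limited traces.

Measurement noise is additive Gaussian on the normalized intensity —
the simplest model consistent with fits of quality R² > 0.99 — applied to
every reading except the t = 0 anchor so the normalization invariant
(first intensity exactly 1) holds; negative readings are clipped at 0.

## Chromatin condensation (DAPI CV)

Heterochromatin appears as bright DAPI foci, euchromatin as a smoother,
dimmer background, so the coefficient of variation of pixel intensity
within the nuclear mask (CV = SD/mean) is a per-nucleus condensation proxy:
it falls when chromatin decondenses. The **population** standard deviation
is used — the statistic is a descriptor of the imaged pixel population, not
an estimate from a sample — and this is a documented convention. No
background subtraction is applied. Nucleus segmentation is out of scope:
masks are inputs (or come from the generator). CV is invariant to rescaling
all intensities and, over the generator grid, non-decreasing in both spot
amplitude and spot count; both properties are tested. Group comparisons use
Welch's t by default with a Mann-Whitney switch.

The synthetic nucleus is an elliptical mask filled with a flat background
plus Gaussian pixel noise and a configurable number of Gaussian foci placed
uniformly inside the mask. It emulates the intensity statistics the CV
depends on — it does not emulate optics (no PSF, no shading, no chromatic
structure), so passing tests certify the statistic and its comparisons, not
robustness to real microscopy artifacts.

## Nuclease-accessibility densitometry

A digestion lane is modelled on a log10(bp) migration axis as a mixture of
Gaussian nucleosomal bands plus one broad sub-nucleosomal smear component.
Band centers default to 147/320/500 bp for mono/di/tri-nucleosomes — a
convention (fully configurable), since fragment-size calibration is
instrument-specific. The smear is a Gaussian centred at 80 bp with sigma
0.30 log10-units. `lane_densitometry` solves for component weights by
non-negative least squares against unit-integral basis columns and
renormalizes to mass fractions; recovery is within ±0.02 at zero noise and
±0.05 at 2% noise (tested). The scalar **accessibility** score is the
smear plus mononucleosome fraction — the fully digested end of the ladder —
an explicit convention chosen because gel shifts are otherwise only
qualitative; `accessibility_shift(A, B)` is its signed difference, positive
when A is more digested (more accessible chromatin).

## Incorporation assays

EU/EUTP incorporation time courses saturate, so each is fitted with
`S(t) = s_max (1 - exp(-k t))` (bounded least squares, multi-start on k).
The saturating-exponential family is a design choice for the unspecified
nonlinear regression; it yields a defined initial rate `s_max * k` and the
form is pluggable. Conditions are compared by the ratio of fitted-curve
areas over a stated window (default 50 min) because the quantity of
interest is signal accumulated *during* an interval; when both conditions
share k the AUC ratio reduces exactly to the `s_max` ratio, so a generated
pair with initial-rate ratio 1.54 yields a 54% increase identically at zero
noise (and within ±3 points at 1% noise over 100 replicates, tested). The
EUTP run-on protocol holds nucleotide supply fixed, which is why the
incorporation increase is interpretable as a transcription-rate increase;
plain EU incorporation in intact cells confounds with ATP depletion under
hyposmotic stress, which is why the shipped preset models the run-on assay.

Copy time of a transcription unit is `length / rate`, rounded half-up to
whole minutes: a median ~14 kbp unit at 1.1–2.5 x 10^3 nt/min takes 13
down to 6 minutes. qRT-PCR ratios use the standard 2^-ddCt with per-gene
pairing across conditions; unpaired genes are excluded with a logged list.

## ChIP-seq peak post-processing

Coordinates are BED convention (0-based, half-open); overlap means at least
`min_overlap` shared bases (default 1). p-values are stored raw internally;
narrowPeak's -log10 encoding is converted at I/O boundaries only.

* **Background subtraction** removes whole sample peaks overlapping any IgG
  peak (the artifact consumes peak tables, not coverage tracks, so trimming
  is not meaningful). Output is a subset of input; idempotent.
* **New peaks**: "present only in the condition" is operationalized as zero
  overlap with any control peak — the field has no standard
  presence/absence definition, so this is stated prominently — combined
  with fold enrichment above 30 (15 for PhosphoS2) and p below 1e-9.
* **Containment** is computed on peak intervals (percentage of subset peaks
  overlapping at least one superset peak); a healthy paired experiment
  shows 85–95% of initiating-form (PhosphoS5) peaks inside the
  total-antibody list.
* **Gene assignment** is nearest strand-aware TSS (start on `+`, end on
  `-`, using the BED end coordinate) to the peak midpoint; ties go to the
  first gene in sorted order and are logged.
* **Association score**: for each rank cutoff k of a TF-affinity gene
  ranking, the overlap with the target gene set is scored by the
  hypergeometric upper tail P(X >= o); the score is -log10 of the minimum p
  over the cutoff grid (-log10 matching the published PASTAA convention; a
  natural-log switch exists). No multiple-testing correction is applied
  inside the score, mirroring how such scores are used; a Bonferroni-over-
  grid p is reported alongside as a diagnostic. The implementation is
  verified against exhaustive tail-sum enumeration for every configuration
  with up to 20 genes and 6 targets, and its null calibration against a
  Monte-Carlo band.

The interval engine is an interval tree per chromosome, validated against
a brute-force all-pairs checker on random peak sets.

The peak-table generator lays peaks out on a slot grid (one slot fits the
widest peak, its engineered-overlap partner and a guard gap) so that only
intended overlaps exist: cross-antibody containment is engineered to the
target fraction exactly (rounded to a whole peak count), contaminated
sample peaks sit directly on IgG intervals, and requested counts exceeding
the genome's slot capacity are rejected. Real peak tables have length,
enrichment and spacing distributions this generator does not attempt to
match; what the tests certify is the correctness of the set operations and
thresholds, not peak-caller behaviour.

## Workbench

`osmochrom run config.yml` executes the stages on synthetic demo data from
a YAML config validated by a strict schema (unknown keys rejected; all
violations reported at once). One global seed is expanded deterministically
into per-stage seeds; artifacts are TSV/JSON (figures are never
load-bearing), and a rerun with the same config reproduces deterministic
outputs bit for bit. The run report records the package version, a config
hash, and per-stage outputs and wall-clock.

## Problem sizes and defaults

Recovery analyses use 10 simulated cells per FLIP condition (181 points per
trace), 100 nuclei per CV group, 11-point incorporation curves to 100 min
with 100 replicates for the noisy-comparison check, and peak fixtures of a
few hundred to a thousand peaks on a 50 Mb, 5-chromosome toy genome — sizes
at which every statistic is stable while the full suite runs in about two
minutes.

## Known limitations

* No spatial diffusion modelling of the nucleus (no PDE/FRAP mode) and no
  photobleaching-during-acquisition correction; the well-mixed free pool is
  an approximation that breaks down for very short pulse intervals.
* The slowest FLIP component is weakly identified when its half-life is an
  order of magnitude longer than the acquisition window; report
  uncertainties accordingly.
* The CV statistic ignores optics and background structure; absolute CV
  values are not comparable across instruments, only across conditions
  imaged identically.
* The accessibility scalar weights smear and mononucleosome mass equally;
  other monotone scalarizations are defensible.
* Peak post-processing trusts the caller's fold-enrichment and p-value
  columns; it applies no re-normalization beyond IgG overlap removal.
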