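# Methods

This note documents the models, calibrations and numerical choices behind
`rush-screen`: what the simulator states about the world, how the analysis
stages are defined, and what a passing test does and does not establish.

## 1. Secretion kinetics

The cytoplasmic GFP retained at `t` minutes after biotin addition is
modelled as a lagged single exponential:

```
retained(t) = (1 − leak) · exp(−k · f · max(0, t − t_lag))      (biotin)
retained(t) = 1 − leak · clip(t / 240, 0, 1)                    (no biotin)
```

* `k` (`k_release`, default `ln(20)/200 ≈ 0.01498 min⁻¹`) — chosen so that
  an untreated biotin well decays to ≤ 5% of baseline by 240 min,
  reproducing the observed near-complete loss of cytoplasmic signal within
  4 h, while leaving a strong measurable signal (~73% retained) at the
  60-min screening timepoint. The screening-timepoint level itself is a
  free calibration: the source observations constrain the 4-h endpoint,
  not the 1-h value.
* `t_lag` (40 min) — delay before decay begins, set to the lower edge of
  the observed 40–120 min ER→Golgi relocation window.
* `leak` (0.02) — basal loss without biotin, reflecting that only trace
  amounts of cargo escape a tight hook.
* `f` — the compound's fold-change of the release rate, linked to dose by a
  hyperbolic (Hill-1) law `f(d) = 1 + (f_max − 1)·d/(d + EC50)`; `f_max>1`
  activator, `f_max<1` inhibitor, `f_max=1` inactive. Dose tiers default to
  `low = EC50` and `high = 10·EC50`, mirroring the screen's 10-fold spacing.
  Cytotoxicity scales the expected cell count by `1 − tox·d/(d + EC50)`.

`retained` is deterministic and non-increasing in both `t` and `f`
(property-tested). A `f = 0` well models a brefeldin-A-like complete block
and doubles as the positive control.

## 2. What the simulator renders (and what it does not)

One field is 256×256 px with ~50 cells — a stated stand-in for the full
scale of ~2000 cells/well over ≥ 4 fields; full-scale parameters are
accepted but not default. Nuclei are non-overlapping filled ellipses
(semi-axes ~ N(6 px, 1 px) truncated at 3 px, random orientation, placed by
rejection sampling with ≤ 1000·n attempts); the cytoplasm is the nucleus
footprint expanded by 5 px with nearest-nucleus tie-breaking, minus the
nucleus. Cells may touch (exercising the watershed split) and may cross the
field border.

Intensities (arbitrary fluorescence units of a 16-bit camera): baseline
cytoplasmic GFP 8000 AFU/cell at t=0, nuclear-stain level 12000 AFU,
per-cell lognormal expression heterogeneity of unit mean (σ = 0.25 for GFP,
0.15 for DNA), and a dim GFP bleed of 0.35× the cell's value inside the
nucleus (perinuclear/out-of-focus light). The noise chain is applied in a
fixed order, because the order changes the moments: multiplicative radial
vignetting (1 at centre → 0.8 at corners) → Poisson shot noise at gain
0.1 (variance = signal/0.1) → Gaussian read noise (σ = 10) → additive
background (200) → clip to [0, 65535] and round. All values were chosen
once as plausible for a 16-bit sCMOS screen and are config-overridable.

Not emulated: Golgi puncta of the intermediate trafficking state (bulk
cytoplasmic intensity only), photobleaching, focus drift, debris,
well-position (edge) effects, and plate-to-plate batch drift. A green
end-to-end test therefore establishes that the pipeline recovers effects
under idealized-but-noisy optics, not that it is robust to every real-plate
artefact — in particular, no spatial polish is needed on simulated plates
because no row/column effect exists (a B-score-style polish is deliberately
not applied by default).

Screens place each dose tier on its own plate; every plate carries 20
biotin-only/DMSO negative controls, 6 secretion-blocked (f=0) and 6
no-biotin positive controls in its last wells. Wells are rendered lazily and
every artefact derives from one integer seed through spawned generators —
identical seeds give bit-identical images.

## 3. Segmentation

Nuclei: Gaussian smooth (σ = 1.5 px) → white top-hat (disk radius 25 px,
decomposed footprint) → global Otsu → fill holes → watershed on the
distance transform seeded at its regional maxima (min separation 5 px) →
drop components outside 20–800 px² → consecutive relabel. Global (not
adaptive) thresholding is used: fields are small and background-corrected,
and determinism is easier to audit. An all-constant image yields zero
nuclei rather than an error.

Cell bodies: the GFP foreground is thresholded on the *unsmoothed* raster —
the cell/background contrast dwarfs pixel noise, and thresholding the
smoothed image biases the boundary of a ring only a few pixels wide
outward. The default strategy is `halfmax` (Otsu split, then the midpoint
of the two class medians, i.e. the half-maximum edge of a step); plain
`otsu` and `none` are available. A watershed of the inverted smoothed GFP
seeded by the nuclei determines which foreground pixels are reachable;
pixel *assignment* resolves to the nearest nucleus within `cyto_max_radius`
(12 px). The flood assignment alone is unreliable in this regime: seeds
(nuclei) are dimmer than the surrounding cytoplasm, so the flood order lets
the brightest cell annex its neighbours' plateaus; nearest-seed resolution
keeps adjacent cells disjoint and the partition deterministic. The
cytoplasm is the cell region minus the nucleus; cells left with no
cytoplasm pixel are dropped (logged). Border-touching cells are kept but
flagged, since the well statistic (median) is robust to their truncation.

Illumination correction (`poly2`) divides by a least-squares full
second-order polynomial surface normalized to unit mean; it is off by
default because vignetting is identical across wells and cancels in
plate-normalized scores.

## 4. Quantification and scoring

The per-cell readout is the **mean** cytoplasmic GFP (nucleus excluded) —
the assay measures per-cell signal decay, not cell size, so integrated
intensity would confound size; pixel-pooled alternatives are available in
config. The well statistic is the **median** of per-cell means, robust to
debris and segmentation outliers. Wells with fewer than 10 cells are
flagged `low_cell_count`; empty wells are flagged `segmentation_failure`
with undefined signal.

Plate normalization uses robust control statistics: negative centre
`median`, scale `1.4826·MAD` of the biotin-only/DMSO (and untreated) wells;
`normalized_activity = (raw − neg)/(pos − neg)` maps 0 → full secretion,
1 → full retention. The Z-score is referenced to the negative-control
distribution, not to all samples: true actives would contaminate a
sample-based reference (a `reference: samples` switch exists). An exact
zero MAD raises a degenerate-scale error rather than emitting infinities.
The normalization sequence is aggregate → normalize → Z-score.

Viability: `ratio = n_cells / median(n_cells over negative controls)`;
wells below 0.5 keep their scores but are barred from hit eligibility —
a dead well's low GFP is artefactual.

Colocalization statistics for clone characterization: PCC is the plain
Pearson correlation over (optionally masked) co-registered pixels; SOC is
defined here as the Jaccard overlap `|A∩B|/|A∪B|` of per-channel
Otsu-thresholded foregrounds, with Manders `M1 = |A∩B|/|A|` as an
alternative. SOC has no universally fixed definition; this choice is
recorded as an open interpretation and cannot be validated against
published single-image values.

## 5. Hit calling

Per compound, `(z_low, z_high)` with viability flags at both doses.
Activator direction (most negative z = rank 1; inhibitors mirror with signs
flipped):

* eligible: viable at both doses;
* candidates: union of the top-K (default 20) at either dose;
* "working at both concentrations": a candidate must satisfy
  `z ≤ −z_other` (default 1.0) at each dose *other than* the one(s) that
  put it in the top-K — a threshold, not top-K intersection, because the
  motivating screen's shortlist was drawn from the top-20 union
  (`both_mode: topk` gives the intersection behaviour);
* rescue (on by default, activator side): the rank-1 compound at either
  dose enters the shortlist regardless, provided it is actually active in
  the direction at that dose — mirroring the historical case of a compound
  best-in-screen at the low dose only;
* ties in z break lexicographically by compound id, so shortlists are
  fully deterministic;
* final classes with precedence toxic > activator > inhibitor > inactive.

Shrinking K or raising `z_other` never adds compounds (property-tested).

A structural note, established quantitatively by the acceptance run: when
only a handful of true actives exist, the top-20 union necessarily contains
~24 null compounds per direction, each of which passes the other-dose
filter with probability `P(|z| ≥ 1) ≈ 0.16` under a calibrated Gaussian
null — an irreducible expected ~3.8 false positives per direction at these
defaults, independent of assay noise (Z-scoring standardizes the null by
construction). Stricter `z_other` or `both_mode: topk` trades sensitivity
for specificity.

## 6. Determinism and serialization

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` spawns (one child per well); no global RNG
state is touched. Tables are CSV (UTF-8, comma, header, 6 significant
digits); rasters are 16-bit grayscale TIFF, one file per channel per field.
Re-running a pipeline with identical config and seed reproduces every CSV
and label mask byte for byte; `run_log.json` records the seed, a SHA-256 of
the full resolved configuration, and every parameter default actually used.

## 7. Known limitations

* Segmentation parameters are tuned to the simulator's geometry; real
  micrographs will need per-dataset tuning of areas, radii and σ.
* The nearest-seed cytoplasm assignment approximates cell boundaries by a
  distance partition where no intensity valley exists; strongly asymmetric
  real cells will be truncated at `cyto_max_radius`.
* Only two doses exist by design: no EC50 fitting or potency ranking, only
  dual-dose concordance.
* The simulator's lognormal heterogeneity and Poisson/Gaussian optics are
  stationary; conclusions about drift, batch effects or spatial artefacts
  cannot be drawn from green tests here.
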