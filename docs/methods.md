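# Methods

This note documents the models, parameters and numerical choices behind
`emtscreen`, and what the synthetic-data generator does and does not
emulate.

## Readout model

Four per-well features are quantified from four-channel micrographs:
nuclei count (DAPI), focal adhesions per cell (FITC/paxillin), and
stress-fiber and fibronectin scores (TxRed/phalloidin, Cy5/fibronectin).
All thresholding is *local-background relative*: the background is a
grayscale morphological opening (erosion then dilation) with a square
window whose half-width defaults to 3× the largest target object's
diameter. The square window makes the filter separable and therefore
cheap at the large radii involved; like the disk variant it is monotone
and commutes with additive offsets, so all counts are invariant under
uniform intensity shifts. Foreground is `image − background > offset`,
with a per-channel offset (default 500 counts on a 16-bit scale) that can
be re-calibrated per batch by grid search maximizing the control-well Z′
(`calibrate_thresholds`), mirroring how imaging screens compensate
inter-batch staining variation.

**Size windows.** "Size" is interpreted as equivalent circular diameter
(the area-equivalent diameter of the connected component); the windows
are closed intervals — an object at exactly 9 or 16 µm is kept. Nuclei:
[9, 16] µm with a distance-transform watershed to split touching pairs
(marker minimum separation 0.7× the lower diameter bound). Puncta:
[1, 10] µm, no splitting.

**Fiber networks.** The thresholded mask is skeletonized; skeleton pixels
with ≥ 3 eight-neighbors are junction pixels, whose 8-connected clusters
are branch points (B); pixels with exactly one neighbor are endpoints,
clustered into nodes (N); removing junction clusters leaves maximal
paths, each counted as a segment (S) if its path length — approximated as
(n_pixels − 1) × pixel size, an isolated pixel counting one pixel — lies
in the [1, 5] µm window. The window is applied to path length; applying
it to fiber width would be an alternative reading, but the downstream
score (S + B + N)/nuclei is robust to the choice because all three terms
are summed. The commercial operators this emulates are proprietary;
"nodes = endpoint clusters" is this package's definition, checked against
a brute-force graph oracle in the tests.

**Aggregation.** Per-site results are averaged over the sites of a well
with the mean (not median) before per-cell normalization — the mean is
linear in counts, so well values stay unbiased estimates.

**Line scans.** The signal-to-background metric for junctional stainings
takes horizontal scans (image midline plus evenly spaced parallels — scan
placement is not standardised anywhere, so the simplest deterministic
choice is used), computes max/min per scan (a zero minimum is lifted to a
1-count pseudo-floor with a warning) and averages the ratios.

## Plate normalization and QC

Percent effect per plate and readout is
`100 · (x − μ_neg)/(μ_pos − μ_neg)` with each plate's own TGFβ + vehicle
(negative) and TGFβ + 10 µM SB-431542 (positive) control wells; effects
are deliberately not clipped, since values outside [0, 100] carry
information (Emax, toxicity-distorted readouts). Toxicity percent is
`100 · (μ_ref − x)/μ_ref`, clipped below at 0, with the TGFβ + DMSO
negative controls as the reference by default — every screen well
received TGFβ, so that is the comparable vehicle state; the no-TGFβ DMSO
wells can be selected instead by config. Z′ uses sample (n − 1) standard
deviations and the absolute mean difference; at n = 4 positive wells the
ddof choice is material (population SDs would flatter Z′ by ≈ 13 % of the
spread term), and the sample convention is the conservative one.

## Dose–response model

The four-parameter logistic with variable slope,
`y(x) = bottom + (top − bottom)/(1 + (IC50/x)^hill)`, is fitted by
least squares on the percent-effect scale (the IC50 definitions are
phrased in percent of the SB-431542 reference, so fitting raw per-cell
values would answer a different question). The model object
(`FourParamLogistic`) fits IC50 in log-space with one start per tested
concentration decade, hill constrained to (0.01, 20), ties broken by
lowest RSS then lowest IC50; `fit()` returns a results object with the
estimates, RSS, convergence flag and a `summary()` table. A fit is
declared unconverged when its RSS is not below the total sum of squares —
i.e. the curve explains no more than a flat line (no dose dependence).

**Censoring.** The reported IC50 solves `y(x) = 50` by bisection in
log-concentration (the closed form
`IC50 · ((top − 50)/(50 − bottom))^(−1/hill)` is the independent oracle in
the tests, agreement 1e−9 relative). No crossing below the top tested
concentration → `ia` when the series reaches the 25 µM verification top,
otherwise `n.m.`; a crossing at or above the compound's toxicity IC50 →
`n.m.` (no measurable effect at non-toxic concentrations); a crossing
below the lowest tested dose is reported as `<lowest` with an
extrapolated flag rather than as a numeric claim. An unconverged fit
whose observed responses sit clearly below 50 % is a flat, inactive
response and is censored like any non-crossing curve; `n.d.` is reserved
for fits that fail with responses near or above the 50 % level, where no
statement is defensible. The toxicity curve is fitted with its lower
plateau pinned at 0 % (zero dose, zero toxicity), which prevents spurious
50 % crossings on near-flat noisy curves.

**Compound profile.** Combined EMT IC50 = arithmetic mean of the FA, SF
and FN IC50s, defined only when all three are measured; any censored
input propagates, the least informative label winning (`n.d.` over
`n.m.` over `ia`). Reported values are rounded to 0.1 nM; internal values
are unrounded. Emax is the maximal CCI percent effect over non-toxic
concentrations. Hit rule (strict inequalities throughout, evaluated
per concentration with toxic concentrations excluded): CCI > 10 %, or one
pattern readout > 60 %, or two pattern readouts > 40 %; clause precedence
CCI → single → double at the lowest firing concentration. The
cytotoxicity flag is a strict `count < 50 %` of reference; a decrease of
exactly 50 % is not toxic. These boundary decisions are tested
exhaustively.

## Kinase arm

Residual activity = `100 · (cpm − low)/(high − low)` with *median*
high/low control cpm; the cellular ROCK rescaling uses control *means* —
the two assays' own conventions, preserved rather than unified (both are
instances of the same linear rescale contract, tested as one property).
Biochemical IC50s come from the same 4PL machinery with top fixed at
100 % and bottom at 0 %, on a 10-point half-log series from 1×10⁻⁵ M to
3×10⁻¹⁰ M; `ia` is bound to the 10 µM assay top. Immunoblot analysis
computes p-SMAD3/GAPDH per lane and paired t statistics across complete
biological replicates (two-sided; identical pairs short-circuit to t = 0,
p = 1 rather than 0/0).

## Synthetic-data generator

The generator defines the study conditions the tests run under.

* **Control means** (negative = mesenchymal, positive = epithelial):
  FA 40 → 10 per cell, SF 30 → 6, FN 24 → 5, nuclei 800 → 1600 (TGFβ
  arrests the cell cycle, so the epithelial state has ~2× the cells
  after 4 days).
* **Compound responses**: each treated well's noiseless mean is
  `μ_neg + effect · (μ_pos − μ_neg)` with
  `effect = max_effect/(1 + (IC50_r/c)^hill)`; per-readout IC50s are
  drawn with a ±0.15 log10 spread around a compound-level value
  (published per-readout IC50s of the same compound agree within ~3-fold,
  not exactly), hill ∈ [0.8, 1.5], compound IC50s log-uniform over
  10–10 000 nM, with designated inactive (10 %) and toxic (10 %,
  toxicity IC50 log-uniform 2–30 µM) fractions. Toxicity multiplies the
  expected nuclei count by a logistic survival term — effects compose
  multiplicatively, reproducing the real screen's confound of cell loss
  distorting pattern readouts.
* **Noise**: mean-preserving multiplicative log-normal, CV 10 % for the
  per-cell pattern readouts (well-to-well CVs are not published for this
  assay class; ~8–12 % is typical of per-cell imaging features and
  reproduces the observed Z′ band, which is why it is the default and is
  documented here as an assumption) and CV 4 % for nuclei counts
  (counting ~10³ objects is intrinsically less noisy). With these
  defaults, downstream Z′ from 4 positive/16 negative wells lands in
  [0.4, 0.8] for ≳ 90 % of plate-readouts, centred near 0.55.
* **Plate layout**: controls occupy columns 1–2 (16 negative, 4
  positive, 4 no-TGFβ DMSO wells); treatments fill columns 3–24; the
  layout builder spans as many plates as the compound × dose × replicate
  grid needs. A 48-compound, 8-dose, duplicate screen needs 768 treatment
  wells and therefore three 384-well plates.
* **Rendering**: nuclei are ellipses with area-equivalent diameters drawn
  from 9.5–15 µm (the interior of the 9–16 µm detection window, since
  pixelation at 0.645 µm/px — typical 10× widefield sCMOS sampling — can
  inflate the measured diameter by about a pixel); focal adhesions are
  1–3 µm puncta on concentric rings outside the nucleus (5 µm spacing
  along rings, 4.5 µm between rings, so puncta never merge); fibers are
  straight ~3 µm lines, each decomposing to one segment plus two endpoint
  nodes, so `round(score/3)` fibers per cell reproduce a target
  (S+B+N)/cell. Optional Poisson shot noise.

**What the generator does not emulate**: real cell morphology
(elongation, junctional staining, cell crowding), spatial plate effects
(edge gradients, dispenser bias — there is no B-score correction because
the modelled screen used none), segmentation ambiguity from overlapping
cells, or channel crosstalk. Passing round-trip tests therefore show the
quantification is correct for well-separated objects of the stated sizes,
not that it is robust to confluent real imagery.

## Problem sizes

The test suite and acceptance script use deliberately scaled-down runs:
48 compounds on three plates with duplicate 8-dose series for parameter
recovery, 16 rendered wells (one 512×512 site each) for the image round
trip, 8 simulation seeds for the Z′ band statistic, 200 replicate fits
for the noisy-recovery check, and 1000 parameter draws for the
closed-form oracle. These sizes give stable statistics while keeping a
full run in minutes on a single core. The screen-scale funnel totals of
the original campaign (thousands of compounds) depend on raw data that
were never released and are not reproduction targets.

## Known limitations

* MetaXpress's vesicle/node semantics are proprietary; the definitions
  here (equivalent-diameter windows, endpoint-cluster nodes) are
  documented choices validated only against their own oracle.
* The 4PL fit reports no parameter uncertainties; profile-likelihood or
  bootstrap intervals would be the natural extension.
* Hit evaluation excludes toxic concentrations per concentration, not per
  compound; both readings are defensible, one is implemented.
* `zprime` requires ≥ 2 wells per group and is undefined for equal means;
  callers see an exception, not a sentinel.
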