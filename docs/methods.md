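# Methods

## The measurement model

A biopsy section is modelled as a horizontal strip of `n_fields`
contiguous square imaging fields, 144.72 μm per side (1024 px at the
default 0.14133 μm pixel), with the epithelial border running as a gently
undulating polyline near the lower edge. This geometry makes the
"maximum bacteria in one field" statistic equal to a tile maximum over
origin-anchored, half-open tiles; a brute-force sliding-window variant is
available behind `QuantConfig(sliding_window=True)` for sensitivity
analyses. Real acquisition geometry (separate fields imaged wherever
bacteria were visible) is not reconstructable from a published figure, so
the strip is a deliberate simplification: it preserves the per-field count
distribution and the epithelium-distance structure, which are what the
downstream metrics consume.

Coordinates are continuous micrometres with the origin at the image's
top-left corner; pixel index `i` maps to `(i + 0.5) · pixel_size`.

## Synthetic sections

Per-field bacterial counts are Poisson. The biofilm-negative (BF−) rate
defaults to 12 bacteria per field, and biofilm-positive (BF+) fields have
a 10-fold higher rate — the contrast reported between the two phenotypes.
The per-field rate itself is not published for real sections; 12 is a
placeholder chosen so that a BF− field is sparse (no overlapping spots at
the 0.5-μm PSF scale) while a BF+ field is visibly crowded, and it is
exposed in `SectionSimConfig`.

Spatial structure encodes the histology: in BF+ sections a fixed
⌈0.8·n⌉ of each field's bacteria sit within 15 μm of the epithelium
(dense adherent band; the ceiling makes the ≥ 80 % adherent-fraction
guarantee deterministic rather than probabilistic), the rest anywhere in
the mucus; in BF− sections every bacterium keeps at least a 30-μm
standoff from the epithelium, emulating an intact mucus layer — verified
against the exact polyline distance, with rejection resampling where the
undulation shortens the vertical offset. Each bacterium is rendered as a
Gaussian spot (σ = 0.5 μm, peak 20 000 on a background of 100) and
optional Poisson shot noise is applied to the whole image. Images are
written as 16-bit single-channel TIFF with the pixel size in the
resolution tags (micron unit) and a YAML sidecar.

Surface-layer height profiles are min–max-normalised smoothed Gaussian
fields scaled by an amplitude (default 50 μm for BF+, 15 μm for BF−, on a
zero base), so the profile maximum equals base + amplitude exactly and
the BF+ > BF− maximum ordering is deterministic. Heights are per image
column (vertical distance), not normal to the epithelium; at the default
5-μm undulation amplitude the difference is below 2 %.

One root seed is split into named substreams (epithelium, counts,
placement, noise, profile) via `numpy.random.SeedSequence`. Identical
(config, seed) reproduces byte-identical output within this
implementation; across implementations only distributional equivalence is
meaningful.

Deviation from the configuration contract: the field/pixel integrality
tolerance is 0.05 px rather than 0.5 px — a 0.5-px tolerance can never be
exceeded (every real number is within 0.5 of an integer), so it would
make the documented configuration error unreachable. The default
144.72/0.14133 = 1023.986 passes.

## Spot detection

The published analysis used a trained U-Net; this package substitutes a
deterministic classical detector with the same contract, validated on
synthetic ground truth. The response is the scale-normalised negative
Laplacian of Gaussian, maximised over three scales around the expected
spot σ (factors 0.75/1.0/1.3). Local maxima above
`response_threshold × dynamic range` are gated by a background-intensity
quantile (default 0.99) and thinned by greedy descending-score
suppression at `min_separation_um` (default 1 μm). The detector is
translation-equivariant and monotone in the threshold; on noiseless
sparse sections it recovers ground truth one-to-one within 0.5 μm, and on
default-noise BF− sections precision and recall exceed 0.9 at a 1-μm
matching radius. On crowded BF+ adherent bands recall drops to ~0.9
because spots closer than the separation limit merge — which is why the
recovered BF+/BF− fold change sits slightly below the planted 10 (≈ 8.8–9
at defaults, within the ±30 % recovery band). No parity with the original
learned detector is claimed; the published work reports no
precision/recall figures to compare against.

The epithelium is consumed as a provided trace (from ground truth or
manual annotation), never segmented from the image: the original
epithelium lengths came from neighbouring H&E-stained sections, for which
there is no computational specification.

## Per-section metrics

Adherence uses the exact Euclidean point-to-polyline distance (shapely)
with an inclusive ≤ 3 μm boundary ("within" read inclusively). Rates are
per mm of epithelium arc length; the published figure axes leave the unit
unlabelled, so per-mm is this package's reporting choice.

The volumetric criterion converts the field-maximum count to a density by
dividing by field area × section thickness. The original conversion from
2D counts to the literature's > 10⁹ bacteria · mL⁻¹ threshold is not
described; the default 5-μm thickness is typical histology and makes the
criterion trip above 104.7 bacteria per field. Both the thickness and the
choice of applying the criterion to the maximum field (rather than the
whole-biopsy volume, which is also computable from the same pieces) are
configurable and flagged here deliberately: they are the least constrained
numbers in the pipeline. The call itself is strict (> threshold).

## Cohort simulation and screening statistics

The cohort generator's defaults are the observed multicenter screening
table: per-cohort, per-center analysable counts and prevalences (e.g. IBS
65/114 overall, healthy controls 10/155; 756 Austrian and 356 German
records, 1112 total). Enrolment counts are interpreted as post-exclusion
counts, and extra to-be-excluded records are appended at 10 % independent
failure rates per rule (BBPS < 6, non-PEG preparation, cecum not
reached), so the exclusion filter has realistic work to do and the
analysable sample sizes match the table. Biofilm status is Bernoulli per
(cohort, center) prevalence; *R. gnavus* bloom flags are Bernoulli at
51 % (BF+) / 18 % (BF−); microscopic-biofilm flags at 89 % / 40 %;
locations are independent per-segment Bernoulli draws at the published
rates (cecum 72 %, terminal ileum 71 %, ascending 45 %, transverse 18 %,
descending 11 %, sigmoid 8 %, rectum 6 %), resampled to be nonempty for
BF+ patients. The generator does not model within-patient correlation of
segments, per-endoscopist effects, or longitudinal follow-up; passing
recovery tests therefore shows the pipeline is unbiased under independent
sampling, not that real screening data meet those assumptions.

Exclusions are evaluated in the fixed order BBPS → prep → cecum so the
exclusion log is deterministic; the screening description implies no
order. Report percentages round half away from zero, which reproduces
every checkable row of the published table.

Odds ratios: crude per-cohort 2×2 ORs versus healthy controls, Wald CIs
on the log scale, Haldane–Anscombe 0.5 correction only when a cell is
zero (flagged). Center-adjusted ORs come from grouped binomial logistic
regression fitted by IRLS (tolerance 1e-8, max 50 iterations; separation
reported as an explicit diagnostic), jointly over all cohorts or pairwise
per cohort — the original multivariate model's exact composition is
unstated, so both modes exist. Published CIs (e.g. 9.5–42.5 for IBS) do
not match plain Wald intervals exactly and the original CI method is
unknown; point estimates, not CIs, are the comparison surface. The
concordance report takes the microscopic criterion as the reference
standard and the endoscopic call as the test.

## Statistical components

Fisher's exact test uses the minimum-likelihood two-sided rule (sum of
hypergeometric probabilities ≤ that of the observed table), with the
tail-doubling rule as an option; it is checked against full enumeration
for small tables. Mann-Whitney U uses exact enumeration when the pooled
sample is ≤ 16 without ties, otherwise the tie- and continuity-corrected
normal approximation. Kruskal-Wallis applies the tie correction and a
χ²(k−1) reference, returning H = 0, p = 1 when all values are identical.
Benjamini-Hochberg adjustment is the standard step-up (the adjusted
vector is *not* a fixed point of re-adjustment — that property fails in
general, e.g. p = [0.25, 1] adjusts to [0.5, 1] and re-adjusts to [1, 1] —
so the invariant checked is agreement with an independent step-up oracle).
The IRLS fitter is cross-checked against statsmodels GLM; on a single
saturated 2×2 its exponentiated slope equals the crude OR to machine
precision.

## Assay scoring

Ratios are computed per well (OD595/OD600, OD600 > 0 enforced; wells with
nonpositive OD600 are dropped with a log entry) and then aggregated per
strain — per-well ratios are the plotted quantity in microtiter assays —
with mean (default) or median aggregation and an off-by-default blank
subtraction, since whether the original assay blanked before the ratio is
unstated. The former call is strict (aggregate > 5). The plate simulator
plants formers at a lognormal mean ratio of 10 and non-formers at 1.5
(well CV 15 %), a separation typical of strong crystal-violet producers
versus non-producers; label recovery is essentially perfect at 8
replicates.

## Problem sizes and numerical choices

Tests and the acceptance script use 1-field sections for detector quality,
8-field sections per phenotype for fold-change recovery, 50 simulated
cohorts (~1 500 records each) for the screening recovery, and 50 plates
for assay label recovery — sizes chosen so distributional checks have
narrow enough Monte-Carlo error while each full run stays in tens of
seconds. Detection thresholds are relative to image dynamic range, so
constant images yield zero detections rather than errors; empty detection
sets propagate as zero counts, and a zero-length epithelium is an error
because per-length normalisation is undefined.

## Known limitations

* The detector undercounts in bacterial aggregates denser than the
  minimum-separation limit; learned detectors were presumably trained to
  do better there.
* The volumetric criterion depends linearly on the assumed section
  thickness; a 4-μm section moves the per-field boundary to 83.8.
* Cohort simulation treats patients and anatomical segments as
  independent Bernoulli draws.
* Layer heights are column-wise, not epithelium-normal.
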