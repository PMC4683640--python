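# Methods

## Synthetic cohorts

The package replaces the raw material of a strain survey — stained
sections, CASA video tracks, and animals — with generators whose outputs
carry exact ground truth. Each generator is a pure function of its config
(seed included), so every figure and test is reproducible bit for bit.

### Histology sections

A section is rendered as an elliptical "tissue" mask (pale pink
interstitium) on a white background, packed with non-overlapping circles
placed by rejection sampling (dart throwing): a candidate center is drawn
uniformly, kept only if its circle plus the configured interstitial gap
(`min_gap_um`, default 6 µm) clears every accepted circle, and the run
aborts with an infeasible-config error after a bounded number of
attempts. Radii follow a lognormal law parameterized by mean and
standard deviation in micrometers (defaults 28 ± 4 µm at 1 µm/px on a
640 × 640 canvas with 40 tubules — a scaled-down transverse section that
keeps the packing appearance of real tissue at tractable image sizes).
Each tubule is an annulus: purple epithelium ring around a near-white
lumen (lumen radius 0.55 r, or 0.85 r for germ-cell-loss tubules, whose
thin epithelium is the rendered correlate of the label). Vacuoles are
pale ellipses in the epithelium ring; sloughing is an epithelium-colored
blob inside the lumen; abnormal germ cells are small dark nuclei in the
ring. An optional rete testis region is a larger pale area crossed by
epithelial strands. Independent Gaussian pixel noise (sd 6 of 255) is
added last. The four-color palette plus noise is deliberately minimal:
it is sufficient for local color histograms to be informative, which is
the property the detector exploits, and no attempt is made at
photorealism, staging of the seminiferous epithelium, or tile-stitching
artifacts. Abnormality rates default to 15% of tubules carrying
vacuoles (with a geometric-tailed count on 1..10), 5% germ-cell loss,
5% abnormal germ cells and 3% sloughing; all are configurable. What
"many vacuoles" means is not biologically fixed; the threshold is
exposed (`many_vacuole_threshold`, default 3 per tubule).

### Sperm tracks

A track is a constant-speed drift along a diffusing heading, plus a
sinusoidal lateral displacement perpendicular to the heading, plus iid
Gaussian positional jitter — the minimal model that spans the CASA
parameter space (speed, path curvature, lateral beat amplitude and
frequency). Five class-conditional parameter ranges make the motility
classes separable by construction: progressive (fast, straight),
intermediate (moderate speed and linearity), hyperactivated (very high
curvilinear speed from a large 10–18 µm lateral beat, low linearity),
slow (low speed but steady progression — it passes the motile gate via
net displacement, mirroring the convention that slow sperm are motile),
and weakly motile (a low-amplitude tail beat with almost no progression:
moderate VCL, near-zero VSL and VAP). A sixth, non-classified "static"
profile (jitter only) is available to the pipeline so that time-course
demos contain tracks for the gate to remove. Defaults are 90 frames at
60 Hz. The generator does not emulate video tracking, collisions between
tracks, or drift of the imaging chamber.

### Phenotype panels

Trait values follow the variance-component model
`y_ij = µ + s_i + β_age · age_ij + e_ij` with strain effects
`s_i ~ N(0, V_A)` and residuals `e_ij ~ N(0, V_E)`; the simulated
broad-sense heritability is `V_A / (V_A + V_E)`. Ages are uniform
integers over a configurable adult window (default 70–461 days, a
realistic survey age range) and cells can be masked missing at a given
rate. Defaults are 8 strains × 25 animals. `gen_phenotype_panel` draws
several traits on one shared design so correlation and ANOVA analyses
see a realistic table. Real surveys add measurement batch effects,
trait-specific distributions (counts, percentages) and correlated traits;
none of these are modelled, so passing tests demonstrate correctness of
the estimators under the model, not robustness to real-data pathologies.

## Tubule-center detection

Features at a pixel are the three per-channel color histograms of the
surrounding square window (default 25 px, 8 bins per channel, so 24
features), each channel normalized to sum 1; border windows shrink by
clipping. The whole-image feature stack is computed with box filters
over per-bin indicator images and matches the per-pixel definition
exactly. Training samples at most a `training_fraction` (default 0.001)
of all pixels across the training sections; positives are pixels within
0.3 of a truth radius of a truth center — a spatially coherent "center
core" — with tubule and rete cores as separate classes, and up to half
the budget is spent on positives. The classifier is a 200-tree random
forest with a fixed seed. Localization smooths the foreground
probability map with a Gaussian (sigma 3 px), thresholds at 0.5 and
takes local maxima with non-maximum suppression at `min_distance_px`
(default 22 px ≈ 0.8 of the expected radius); all three are exposed as
configuration because reasonable values depend on the expected tubule
scale. Detection quality is scored by greedy one-to-one matching of
detections to truth centers within half of each truth radius; recall is
matched/truth and the type-1 error is unmatched detections as a
percentage of the truth count per image (the denominator is a
convention; detections-per-image would be the main alternative and is
easily derived from the per-section table).

Radii use the nearest-neighbour rule — half the distance to the closest
other center — which in packed tissue tracks the true radius well but is
an overestimate for tubules whose neighbour is beyond the contact
distance (isolated tubules at the section edge); on the default
synthetic sections the rule runs ≈ 10–15% above the generative mean
radius. Radii are recomputed after every correction pass because the
nearest-neighbour graph changes when centers are added or removed.
Corrections reference records by exact center coordinates: deleting an
already-absent center is a no-op and re-adding an identical corrected
center is a no-op, so applying the same correction file twice equals
applying it once; relabelling an unknown center is an error, as is
adding a center on top of an unrelated record.

## CASA parameters

With duration `T = (n_frames − 1) / frame_rate`: VCL is the raw
point-to-point path length over `T`; VSL the net displacement over `T`;
VAP the path length of the average path over `T`, where the average path
is a centered moving average (default window 5 frames) with symmetric
shrinking windows at the ends. ALH is defined here as twice the mean
unsigned perpendicular deviation of raw points from the average path
(vendors differ between 2 × mean and 2 × max; the mean convention is
less outlier-sensitive), with the sign of the deviation taken against
the local tangent of the average path; BCF counts sign changes of that
signed deviation per second, skipping exact zeros. STR = VSL/VAP and
LIN = VSL/VCL, stored as fractions in [0, 1] with zero denominators
mapping to 0. Note that a finite smoothing window removes only part of
a beat whose period is comparable to the window, so ALH on 60 Hz tracks
underestimates the geometric beat amplitude; comparisons are therefore
made against the same formulas at dense sampling with the window scaled
in time, not against the generator's amplitude parameter. The motile
gate is `VCL ≥ 25 µm/s or net displacement ≥ 4 µm`, chosen permissive so
slow-but-progressing tracks count as motile; both bounds are
configurable, and the track duration is carried inside the kinematics
record so the displacement gate needs no second data structure.

## Motility classification

The five-class problem is solved by a cascade of binary SVMs (RBF
kernel, C = 10, standardized inputs): vigorous vs nonvigorous first,
then hyperactivated vs not and progressive vs intermediate within the
vigorous branch, then slow vs weakly motile. The cascade mirrors the
biological hierarchy (vigor first, pattern second) and keeps each
decision a well-balanced binary problem; the boundaries are learned from
labelled data rather than hard-coded, since published decision surfaces
are instrument-calibrated. Static tracks must be gated out before
classification — the classifier never emits "static". Time-course
profiles report class percentages over motile tracks (summing to 100 per
time point), percent motile over all tracks, and vigorous motility as
progressive + intermediate + hyperactivated.

## Strain statistics

The modified z-score uses the raw median absolute deviation (no 1.4826
consistency factor — the 0.6745 multiplier in the formula plays that
role) and falls back to the mean absolute deviation from the strain
median (multiplier 0.98) when the MAD is zero; a strain with zero MAD,
zero meanAD and a median off the population median is reported as a
signed infinite score with a warning. The population median pools all
animals of all strains, including the strain being scored. Outlier
classes are strict: z must exceed 1 (or 3) in magnitude.

Broad-sense heritability offers two estimators because the ratio
`V_A/(V_A+V_E)` does not pin them down: the default takes V_A as the
sample variance of strain means and V_E as the unweighted mean of
within-strain variances; the alternative is the one-way-ANOVA method of
moments, `V_A = (MSB − MSW)/n₀` clipped at zero with `V_E = MSW` and n₀
the effective group size for unbalanced designs. On balanced panels the
two differ by `MSW/n` in V_A and agree closely for n per strain ≥ 25.
With only 8 strains the estimate is noisy (7 degrees of freedom for
V_A), and the ratio is slightly biased toward 0 in the mid-range;
recovery simulations at 8 × 25 show the mean estimate within ±0.07 of
the truth across h² from 0.1 to 0.9.

Correlations are pairwise-complete Pearson (cells with fewer than 3
complete pairs are reported missing; per-pair n is returned alongside
r). Missing values elsewhere are dropped per trait. The two-way ANOVA
fits `trait ~ strain + age + strain:age` with age continuous in days and
sequential (type-I) sums of squares in that order — age could instead be
binned as a factor, and the one-way interface accepts either reading.
No multiple-testing correction is applied anywhere; the analyses are
reported trait by trait.

## Pipeline and numerical conventions

One global seed drives a run; stages derive sub-seeds by fixed offsets
so stages are independently reproducible, and all derived seeds stay
below 2³¹. CSVs are comma-separated UTF-8 with a header row, empty
string for missing, and shortest-round-trip float formatting (readers
use round-trip parsing so writer→reader is exact). Coordinates are
0-based (row, col) pixels; radii are carried in both pixels and
micrometers. The run manifest records a config hash and a SHA-256 per
output file; identical configs reproduce identical checksums.

Problem sizes in the standard protocols — 640 × 640 sections with 40
tubules, 12 sections split 6/6 for detector evaluation, 200 tracks per
batch, 8 strains × 25 animals with 200 replicates per heritability grid
point — are scaled-down stand-ins for a full survey chosen so that the
whole analysis re-runs from scratch in minutes on a single CPU while
leaving each estimator enough data to hit its quality targets.

## Known limitations

* The histology renderer's color model is far simpler than real
  PAS/hematoxylin variation; detector performance on synthetic sections
  bounds nothing about stain drift, tile seams or focus artifacts.
* Nearest-neighbour radii are biased upward for isolated tubules.
* The ALH/BCF conventions follow one of several vendor definitions;
  absolute values are not comparable across instruments.
* Heritability estimates inherit the small-k noise of an eight-strain
  panel; confidence intervals are not provided.
* The SVM cascade is trained per cohort; no pretrained model ships with
  the package.
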