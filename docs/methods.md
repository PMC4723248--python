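# Methods

This note documents the statistical models, the defaults that matter,
the synthetic-data generators behind the test suite, and the design
choices made where the procedure was genuinely open.

## Spectral-count enrichment calling

Spectral counts — the number of MS/MS spectra matched to a protein's
peptides — are a semi-quantitative proxy for protein abundance in the
affinity-purified SUMO conjugate fraction. The caller works on
per-replicate, per-protein *summed* counts:

1. **Identification filter.** Peptide records with posterior probability
   below 0.55 are discarded (boundary inclusive). The probability is
   consumed as given; the package does not recompute identification
   error rates.
2. **Fold change.** Σcounts over 15-minute samples divided by Σcounts
   over 0-minute samples. With a zero denominator and a positive
   numerator the fold is +∞ and passes the fold gate; with both sums
   zero the fold is 1 and *p* = 1. A pseudocount option exists
   (default 0) for users who prefer finite folds; the default preserves
   the "exceeded by ≥ 3-fold" semantics of a ratio of sums.
3. **Test.** A two-tailed pooled-variance (homoscedastic) t-test on the
   per-replicate summed counts, df = n₁ + n₂ − 2. When both groups are
   constant, *p* = 1 if the means are equal (no evidence of change) and
   0 otherwise. The test is run on replicate-level sums, not
   peptide-level counts: the replicate is the unit of biological
   variation being compared.
4. **Gate.** fold ≥ 3 and *p* ≤ 0.01, both boundaries inclusive; output
   sorted by descending fold, ties broken by ascending *p*, then
   protein id.

Because counts are discrete, the attainable null rate of *p* ≤ 0.01 is
not exactly 1%; calibration is therefore checked against an independent
explicit-formula t-test on identical data rather than against the
nominal level.

## Empirical-null microarray analysis

All values are gene-level log₂ expression ratios against the unstressed
wild-type reference; probe-level normalization is upstream and out of
scope.

**Threshold.** The null is the ratio distribution of a self-self
hybridization (reference vs itself). The change threshold is *k* sample
standard deviations (n−1 denominator; *k* = 3 default), centered at 0;
the null mean is reported for QC only. A null SD of 0.22 gives ±0.66
log₂ at full precision; the widely quoted ±0.65 / 1.57-fold figures come
from rounding the SD before multiplying. The package never chains
rounded values — summaries display 2 decimal places, computation keeps
full precision. At least 100 finite null values are required; fewer is
an error, not a warning.

**Averaging and mutant effects.** Replicates are averaged in log₂ space
with pairwise NaN exclusion, recording per-cell n. Mutant-effect ratios
are mutant minus wild-type averages at the matched timepoint, isolating
the genotype effect from the shared stress response. Significance at
time 0 is read from the averaged ratios themselves; at later timepoints
from the mutant-effect ratios — the two presentations answer different
questions (baseline state vs stress-response deviation) and both use the
same inclusive-boundary threshold filter.

**Telomere proximity.** A gene is telomere-proximal when
min(start − 1, chromosome length − end) ≤ 25 kb. The 25 kb default is an
operational choice for subtelomeric regulation (configurable, echoed in
output metadata); coordinates are 1-based inclusive internally, BED
output converts to 0-based half-open.

**Aneuploidy scan.** A copy-number gain shows as a contiguous run of
genes uniformly elevated in one strain regardless of timepoint. A gene
qualifies when (a) its mean log₂ ratio over all of the strain's arrays
exceeds the elevation cutoff and (b) its replicate-mean is above 0 at
*every* timepoint — the constitutive signature that distinguishes
aneuploidy from stress-responsive induction. Maximal qualifying runs of
≥ 5 genes (min_run) on one chromosome are reported and their genes
removed from downstream analysis. The per-timepoint-mean formulation
(rather than requiring every single array above 0) keeps the rule's
meaning while making exact boundary recovery robust: with replicate SD
0.22 and a +0.8 shift, a single-array rule would stochastically break
~2% of 20-gene segments. The pipeline's default elevation cutoff is
2 × null SD (`aneuploid_k = 2`): a +0.8 shift clears it by > 4 SE per
gene, while a run of 5 consecutive null genes above 2 SD has probability
≈ (0.023)⁵ per window and never occurred in 100 null simulations; 3 ×
null SD sits too close to the shift (1.6 SE) and truncates true
segments.

**Clustering.** Average-linkage agglomeration under the uncentered
correlation Σxy/√(Σx²Σy²) (cosine similarity; no mean-centering, so
vectors sharing sign structure but different baselines still score
high). The average inter-cluster similarity is maintained by the
size-weighted Lance–Williams update, which is algebraically identical to
re-averaging all cross-pairs; the test suite verifies this against an
O(n³) re-averaging oracle. Ties break deterministically on the lowest
(left, right) cluster-id pair; merge heights are 1 − similarity.
Output is TreeView-compatible CDT/GTR.

## Inclusion quantification

The microscopy protocol being emulated scores, per field, the fraction
of cells with at least one visible inclusion, then reports mean ± SD of
that fraction across fields (the field, not the cell, is the statistical
unit; six fields of ≥ 40 cells is the reference design). Human scoring
is replaced by an explicit, reproducible detector:

- **Background flattening.** Within each cell, the pixel median of each
  compartment (nucleus, cytoplasm) is subtracted. Per-compartment
  flattening is essential: nuclei carry a genuinely higher baseline
  (nuclear enrichment), and against a single whole-cell median every
  nucleus would register as one large blob.
- **Robust scale.** The residual is divided by 1.4826 × MAD over the
  cell (falling back to the SD when the MAD is 0). Both steps are
  linear, so the detection is exactly invariant to a global gain change.
- **Detection.** Multiscale LoG blobs (σ 1–4 px) on the normalized
  residual; a blob counts when its peak is ≥ `min_prominence` = 5
  robust-scale units. Five rather than four: Gaussian pixel noise makes
  a 4σ single-pixel excursion in roughly 1 cell in 100 (≈ 270 px/cell),
  whereas 5σ pushes the per-cell false-positive rate to ~10⁻⁴ —
  negligible against the ≥ 5% inclusion fractions of interest. No
  intensity/size criterion exists in manual scoring; these defaults are
  operational choices and are echoed in all output metadata.

Summaries flag (but still compute) conditions below 6 fields or 40
cells/field as underpowered. Condition comparisons use the two-tailed
Welch t-test on per-field fractions (unequal variances,
Welch–Satterthwaite df). Nuclear/cytoplasmic ratios divide the mean over
nuclear pixels by the mean over cell-minus-nucleus pixels; a zero or
empty cytoplasm flags the cell rather than raising. Colocalization uses
the Manders *overlap coefficient* r = Σ(R·G)/√(ΣR²·ΣG²) over masked
pixels — the single-coefficient variant, not the split M1/M2 pair —
which is invariant to scaling either channel. Line profiles sample
bilinear interpolations at evenly spaced points, endpoints inclusive,
(row, col) 0-based coordinates. Only 2-D planes (or precomputed
projections) are supported.

## Synthetic-data generators

All generators are pure functions of a truth dataclass carrying its own
seed; ground truth is returned with every dataset.

**Spectral counts.** Per-protein summed counts are Poisson with mean 20
(baseline) and 20 × fold for planted proteins at 15 minutes; three
replicates per timepoint by default. Poisson is the minimal model for
semi-quantitative count data; negative-binomial overdispersion is
available but off by default. Sums are split uniformly (multinomially)
across 3 peptides per protein — only sums matter downstream — and 10% of
records are decoys with probability below the 0.55 cutoff, so the filter
is load-bearing in round-trip tests. What this does *not* emulate:
shared peptides between proteins, probability-abundance correlation,
saturation of spectral counts for very abundant proteins.

**Expression arrays.** Values are planted effect + optional
aneuploid-segment shift + Gaussian(0, 0.22) noise, the noise level
matching the self-self null. The synthetic genome has 3 chromosomes with
evenly spaced 1.5 kb genes every 2 kb (1-based inclusive), chosen so
telomere-distance and segment-contiguity arithmetic is exact and
deterministic. Not emulated: gene-length/GC biases, spatial array
artifacts, dye bias, correlated noise between neighboring genes — so
passing tests demonstrate correctness of the analysis arithmetic and
detection logic, not robustness to those artifacts.

**Image fields.** Cells are non-overlapping random ellipses (semi-axes
7–10 px) with concentric nuclear ellipses at 0.45 scale; placement
failure after a bounded retry budget raises rather than overlapping.
Intensity = background 5 + cytoplasmic baseline 100 + (enrichment − 1) ×
baseline inside the nucleus + Gaussian spots (amplitude 150, σ 2 px) in
Bernoulli-chosen positive cells + Gaussian noise (SD 5), clipped at 0.
Spot centers are verified to lie inside their cell mask. Two-channel
fields share geometry; each spot appears in channel 2 with a set overlap
probability. Not emulated: out-of-focus light, photobleaching, uneven
illumination, touching cells — segmentation is therefore tested only on
well-separated cells, and real data should use the mask-injection path.

Time courses derive one seed per field from the template seed via a
single `default_rng` draw sequence in timepoint-sorted order, so a whole
experiment is reproducible from one integer.

## Orchestration and problem sizes

`run_pipeline` derives four stage seeds from the master seed, runs the
selected stages, and writes a manifest with all parameters, metrics and
SHA-256 output checksums; outputs are byte-identical for identical
(config, seed). The default synthetic reproduction uses 500 proteins ×
3 + 3 replicates, 600 genes × 3 strains × 3 timepoints × 2 replicates
with a 20-gene +0.8 aneuploid segment and planted +2.0 log₂ effects
(16 up-genes for one mutant, 15 of them subtelomeric, and 21 for the
other, mirroring a realistic derepression screen), and 6 fields × 40
cells per imaging timepoint — sizes at which every planted signal is
recovered with high margin while a full run completes in seconds.
Simulation-based checks in the test suite use 50–200 replicate
simulations, enough to bound Monte-Carlo error well below the tested
tolerances.

## Known limitations

- Protein inference is taken as given; shared peptides are not modeled.
- The microarray stage consumes gene-level ratios; nothing upstream of
  normalization is reproduced.
- The inclusion detector's prominence criterion is an operational stand-
  in for "visible by eye"; absolute fractions on real data will depend
  on its settings (always recorded in output metadata).
- 3-D stacks, deconvolution and time-lapse tracking are out of scope;
  images are 2-D planes or projections.
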