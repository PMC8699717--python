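# Methods

This note documents the modeling choices, defaults, numerical conventions,
and the scope of the synthetic data used to validate the package.

## Coordinates and input handling

All coordinates are 0-based half-open (BED convention) internally; SAM's
1-based POS is converted at the boundary by pysam. A fragment is the full
sequenced insert, spanned from the leftmost mate start to leftmost start +
|template length| (robust to clipped alignments). Only properly-paired,
primary, mapped reads contribute; duplicates are excluded by default and
included only for pseudo-bulk single-nucleus analyses (`keep_duplicates`).
No mapping-quality filter is applied by default. A plain fragments-BED
dialect (chrom, start, end, barcode, dup-flag) is accepted alongside
SAM/BAM so that pipelines and tests need no alignment writer; in that mode
base calls are taken as the reference base under each fragment span, which
is exactly equivalent to alignment mode when reads match the reference.

Personalized genomes are supported by pointing the encoder at a consensus
FASTA for the individual; no VCF machinery is involved.

## The peak encoding

Window: 600 bp centered on the peak center, defined as
`floor((start + end) / 2)` — deterministic for even- and odd-length peaks.
Windows overhanging a contig are N-padded; an N reference base with
sub-threshold coverage yields an all-zero sequence column.

- **Rows 1–4 (base frequencies).** Depth for the `min_depth = 10` test
  counts only A/C/G/T read bases at aligned match positions; indels, skips
  and N calls are excluded, since a base frequency is only defined over
  called bases. Below threshold the column is the reference one-hot.
- **Row 5 (insert pileup).** Counts fragment *spans* (an insert is the
  sequenced fragment), not per-read coverage.
- **Rows 6–7 (cut counts).** +1 at each fragment's left end and at its
  right-end base (`end − 1`). The widely used Tn5 +4/−5 offset is *not*
  applied by default; it is exposed as `tn5_shift` for users who want it.
- **Rows 8–9 (median fragment length per cut).** Positions with no cuts
  carry raw 0 before smoothing. Smoothing a median track smears values into
  cut-free neighborhoods; this is a known, documented artifact of the
  construction.
- **Smoothing.** Savitzky–Golay, window 15 positions, polynomial order 3
  (order is configurable; 3 is the conventional default for cubic
  smoothing). Edges use `mode="interp"`: the terminal window's polynomial
  fit is evaluated at the edge positions. Interior values agree with an
  independent sliding least-squares polynomial fit to < 1e-9.
- **Order of operations.** Tracks are smoothed first (smoothing is part of
  track construction), then z-standardized per column across all peaks of
  the dataset. Standardizing last keeps the column moments exactly 0/1,
  which is also what the tests assert. The reverse order would yield
  slightly different matrices; the choice is documented here and exercised
  by the idempotence test (re-applying stored stats reproduces the matrices
  bit for bit).
- **Standardization.** Population (not sample) standard deviation;
  zero-variance columns map to 0. Stats are fitted once per dataset and
  stored with the model; at predict time the *model's* stats are applied,
  never re-fitted.

## The 19-feature auxiliary vector

The companion feature extractor that historically accompanies this kind of
model fixes the vector length at 19 but its exact membership is not
enumerated in public descriptions. The registry here is therefore a
documented, configurable stand-in drawn from the feature families the
method family names: signed distance to nearest TSS (bp), peak length,
−log10 FDR q-value, fragment count, mean/SD insert size, sub-nucleosomal
(< 147 bp) and mono-nucleosomal (147–294 bp) fragment fractions, 5′/3′
cut-count asymmetry, GC fraction, CpG count, CTCF motif count, four
configurable additional motif counts (defaults: TATA box, GC box, E-box,
AP-1), mean conservation (0 when no track is supplied), summit-offset
fraction, and duplicate fraction. The length-19 contract and the branch
interface are fixed; membership is config. Missing optional annotations map
to neutral values, never to a shorter vector.

CTCF matching uses a JASPAR-style IUPAC consensus (`CCGCGNGGNGGCAG`) with
exact IUPAC matching on both strands; overlapping matches count, sequence N
never matches, and a position matching both strands counts once. This is
reproducible without a motif-database download.

## Ground truth

State labels are first merged into the four classes, then the unanimity
filter is applied to the *dominant class* (not a single state label):
a peak is retained iff the best class covers ≥ 90% of the peak length, with
the boundary inclusive (exactly 90% is kept). Peak length — not
segmentation-covered length — is the denominator when the segmentation has
gaps. Coverage is an exact interval-intersection sum, so splitting a
segmentation record into adjacent same-state pieces changes nothing.

The shipped `roadmap18` and `endoc` maps are the published end-product
mappings; neither contains CTCF-insulator states, so insulators in data
labeled with these references will be mislabeled as other classes — a
limitation of the references, not of the classifier. The concordance-based
example-selection pipeline that produced those maps requires consortium
ChIP-seq and is out of scope; a `custom` two-column TSV scheme covers
in-house models with insulator states.

Non-peak "other" augmentation draws from consensus regions absent from the
sample's own calls, with n ≤ P·cap/(1−cap) for P peak-derived examples
(cap 0.25), uniformly subsampled under a seed.

## Classifier

Input orientation: the 600 positions are the convolution axis and the 10
rows are channels — the only orientation for which a 1-D convolution over
the matrix is meaningful. Convolutions are stride 1, valid padding; max
pooling uses stride = pool size (2). ReLU activations follow each
convolution; batch normalization keeps running statistics (momentum 0.9),
so inference is batch-composition independent and prediction results do not
depend on batch order or size. Output probabilities come from the standard
normalized-exponential (softmax) transform. Weights use Glorot-uniform
initialization; everything is float64 numpy with analytically derived
gradients, deterministic given the config seed.

Staged training: each branch is trained separately under a temporary
softmax head (defaults: 20 epochs, early-stopping patience 5 on validation
loss), then the unified model is trained in a final round in which *all*
parameters — branches included — remain trainable. Whether branch weights
should be frozen during the joint round is genuinely open; fine-tuning
everything is the default here and is flagged as an interpretation.
Best-validation-loss weights are restored after each stage.

Model persistence is a directory with a JSON manifest (config, config
digest, history, standardization stats) plus an `.npz` parameter blob;
loading validates the config digest.

`small_config()` is a reduced architecture (2 blocks, 16/32 filters,
kernel 9, 64-unit branch heads) for CPU-scale experiments on synthetic
data; the default `ModelConfig()` is the full tuned architecture. The
tuning grid (kernel {9, 11, 19, 21}, blocks {3, 4, 5}, dense {1024, 2048,
4096}, base filters {32, 128, 256}) is expressible in config; an automated
search loop is not implemented.

## Evaluation and baselines

Micro-averaging pools all (class, example) decisions. MCC uses the
generalized multiclass (Gorodkin) formula. Average precision is the
precision-recall step integral with equal scores treated as one threshold
step (deterministic across library versions). Per-class ROC AUC is reported
as `None` (not a number) when the truth is degenerate for that class. The
naive baseline's priority is total: promoter (|TSS distance| ≤ threshold),
then insulator (CTCF count > threshold), then enhancer vs. other by peak
q-value; emitted probabilities are hard 0/1. Two conventions exist in the
wild for the best enhancer q-value threshold (0.001 and 0.0001); 0.001 is
the default and both are in the menu. q-values are accepted raw or as
−log10 with an explicit flag; the canonical internal form is raw q. Fisher
overlap tests are two-sided exact tests on peak-identifier sets against an
explicit background; odds ratios use the Haldane 0.5 correction only when a
contingency cell is zero.

## Genotype gain/loss screen

The activity score is the sum of promoter and enhancer probabilities. The
point-biserial correlation uses the classical t transform
t = r√((n−2)/(1−r²)) with n−2 df (not a Welch-style variant — the classical
form is the documented choice). The reported one-tailed p is taken in the
direction of the observed correlation (equivalently min(p, 1−p) of the
upper-tail form), with the direction recorded, which reproduces the
separation of significant loci into negative/positive-correlation groups.
Pairing selection by max |r| happens *before* the significance threshold;
|r| ties break toward the pairing with larger combined n. Constant scores
define r = 0, p = 0.5. Genotypes are read from a TSV (locus, sample,
genotype); VCF parsing is deliberately out of scope.

## Synthetic data: what it emulates and what it does not

The simulator generates what the encoder and classifier consume, with
class-specific structure:

| class | depth amplitude | center spread (bp) | sub-nucleosomal weight | extras |
|---|---|---|---|---|
| promoter | 1.00 | 80 | 0.75 | TSS + TATA at center |
| enhancer | 0.70 | 130 | 0.55 | — |
| insulator | 0.55 | 100 | 0.62 | CTCF consensus at center |
| other | 0.30 | 260 | 0.25 | — |

Fragment sizes come from a two-component lognormal mixture (sub-nucleosomal
mode ≈ 85 bp, mono-nucleosomal ≈ 205 bp), reproducing the qualitative size
structure of transposase libraries without claiming any empirical
distribution. Loci are planted every 2 kb on chromosomes chosen to populate
the train (chr1/4/5/6), validation (chr2/10) and test (chr3/11) splits;
~220 fragments per peak at amplitude 1. The default study size for the
recovery experiment is 2000/400/400 peaks — large enough for stable
training statistics while keeping a single-CPU run in minutes.

The genotyped cohort defaults to 19 samples and 100 loci with allele
frequency 0.3: per locus, a planted direction and an activity shift of
1 population SD per alternative allele over Gaussian sample noise
(SD 0.1 on a 0.5 baseline), plus a matched reporter log fold change
(±1.0 ± 0.5). Loci are resampled until at least two genotype groups are
present, since a monomorphic locus is untestable. A fragment-level variant
(`cohort_fragments`, depth scaled by dosage; `fragments_to_sam` with
alt-base substitution at the SNP) exercises the encoder-level genotype
response.

Passing tests on these fixtures demonstrate that the implementation is
internally correct — the encoders are exact, the statistics match
independent oracles, the staged optimizer recovers planted, separable
structure, and the screen recovers planted effect directions. They do *not*
demonstrate real-data performance: real chromatin has overlapping elements,
GC and mappability bias, noisy and gapped segmentations, and class
signatures far less separable than the planted archetypes.

## Known limitations

- Insulator labels depend on CTCF-containing references; the shipped public
  schemes have none.
- Predictions at the single-cell level are out of scope; single-nucleus
  data is handled only as pseudo-bulk aggregates.
- The full-scale architecture (256/512 filters) trains impractically slowly
  in pure numpy; it is built, introspected and forward-passed in tests, but
  training experiments use the reduced configuration.
- Smoothed median-length rows smear into cut-free regions (see above).
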