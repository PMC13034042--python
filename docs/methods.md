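# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data tests do and do not
establish about real data.

## Intensity model and normalization

The pipeline starts from protein-group iBAQ tables. A recorded 0 and an
absent cell are treated identically as "not detected" (MaxQuant writes 0 for
missing protein groups), which is consistent with medians being taken over
nonzero values only. Normalization divides each run by the median of its
observed values; because the median is equivariant under positive scaling,
every downstream log2 enrichment is invariant (to floating-point precision)
to multiplying any run by c > 0. The per-run divisor is recorded and the
post-normalization observed median is re-checked against 1 within 1e-12 (the
"normalization certificate").

Median normalization assumes the bulk of the proteome is unaffected
background: an effect on a protein can only bias the statistic if it moves a
value across the run median. The synthetic generator respects this regime by
construction (below).

## Left-censored imputation

Missing values in designated runs (by default the controls; bait runs are
never imputed — a protein undetected with the bait is simply not scored) are
drawn per run from `Normal(mu - d*sigma, (w*sigma)^2)` in log2 space, where
mu and sigma are the mean and SD (denominator n−1; small-sample convention)
of that run's observed log2 intensities. Defaults are w = 0.3 and d = 1.8,
the canonical "width"/"down shift" settings of the Perseus software family;
the exact settings behind any given published analysis are usually
unrecorded, so both are configurable and carried in the output metadata. A
single integer seed drives one dedicated generator; runs are processed in
matrix column order and cells in protein order, so imputed matrices are
bit-reproducible across platforms. With w = 0 every imputed value equals
`mu - d*sigma` exactly, which the tests exploit as a degenerate-case oracle.

## Enrichment scoring

Three reference schemes are implemented; the aggregator is tied to the
scheme:

* paired controls — mean of the two controls' log2 values. The mean is taken
  on the log2 scale (the subtraction happens on log2 values); a linear-mean
  variant exists through the replicate-averaged path.
* pooled median — median over controls plus the other baits of the series,
  with configurable reciprocal exclusions (two cooperating baits that label
  the same neighbourhood would otherwise suppress each other's genuine
  hits). The median is computed on the log2 scale. For an odd number of
  reference values this is identical to the log2 of the linear median
  (order statistic); for an even count the interpolated median averages the
  two middle log2 values, i.e. interpolates geometrically on the linear
  scale, which keeps the aggregator scale-consistent with the subtraction.
* replicate averaged — linear means over non-missing bait replicates and
  over control replicates are computed first, then differenced on the log2
  scale; averaging {1, 4} therefore scores log2(2.5), not 1.

Cross-assay summaries use linear-interpolation quantiles and the Tukey
1.5×IQR outlier rule (the conventional boxplot default). Candidate ranking
sorts by enrichment, ties by abundance then id, so outputs are
deterministic.

## Gradient occupancy

Profiles have 20 fractions (top to bottom); each profile is divided by its
mean intensity in the polysomal anchor fractions {13, 14}. The anchoring
assumption is biological: 60S subunits inside translating ribosomes carry
both marker proteins, so both anchored profiles equal 1 there and the
per-fraction ratio reads as an occupancy. The ratio is exactly invariant to
per-profile scaling (blot exposure). Group summaries (60S = {9}, 80S =
{10, 11}, polysomes = {13, 14, 15}) pool all replicate×fraction values
before mean/SD (n−1; SD = 0 for n = 1); averaging per-fraction means first
is available as an option. Zero-denominator fractions are excluded and
counted, never imputed.

The group-mean ratio is a ratio of noisy quantities and is therefore not
unbiased: at 10% band noise its expectation sits ~0.02 above the true
occupancy at theta = 0.75, and a single two-replicate experiment has a
sampling SD near 0.09. Recovery tests therefore check estimator calibration
— the mean estimate over a few dozen independently simulated experiments
must fall within ±0.05 of the truth — rather than gating on one noisy draw,
whose dispersion is a property of the design (n = 2), not of the
implementation.

## Sequence computations

Charge uses the Henderson–Hasselbalch sum (positive groups: N-terminus, K,
R, H; negative: C-terminus, D, E, C, Y; cysteine and tyrosine are treated as
ionizable). The default pKa set is Bjellqvist's, the set behind the common
pI/MW web services; it is swappable via `PkaSet`. pI is found by bisection
on [0, 14] to |charge| < 1e-6 or interval < 1e-4; the charge is strictly
decreasing in pH so the root is unique. Masses are sums of average residue
masses plus one water (18.0153 Da), delegated to Biopython's tables.

The classical NLS scanner matches `K-[KR]-x-[KR]` exhaustively (overlaps
reported). The basic PY-NLS scanner requires an `[RKH]` anchor, a 2–5
residue gap, `P`, then `Y` or a hydrophobic residue (phi = {L, I, V, F, M,
W}, the usual PY-NLS reading), preceded by a basic-enriched stretch. The
literature never quantifies "basic-enriched"; the defaults here — at least
B = 4 of {K, R, H} within the W = 20 residues before the anchor — accept
documented bPY-NLS segments (e.g. a 26-residue C-terminal segment with 11
basic residues) while rejecting signatures embedded in neutral context, and
both parameters are exposed. Hits record the anchor, the P/Y positions, the
basic count and the distance to the C-terminus (bPY-NLSs are characteristically
C-terminal; "near" means within 3 residues). All coordinates are 1-based
inclusive.

Amplicon prediction is exact-match only (the modelled qRT-PCR primers are
exact designs; mismatch tolerance is out of scope): every forward occurrence
is paired with every downstream reverse-complement occurrence of the reverse
primer, products are primer-inclusive and sorted by length, and an absent
primer yields an empty list rather than an error.

## Synthetic data

The TurboID generator draws protein base abundances log-normal (log2 mean
20, SD 2.5 — iBAQ-like magnitudes spanning several orders), per-run scale
factors log2-uniform in ±1, cell values `base × scale × 2^effect ×
2^noise`, and applies logistic left-censoring `P(missing | x) = 1/(1 +
exp((log2 x − tau)/s))` with tau = 14.8, s = 1, giving ~5% missingness at
the default design (one run per bait plus two controls, mirroring a
single-replicate yeast series; the replicated variant uses the
replicate-averaged scoring path). Missingness is intensity-dependent, not
MCAR — the regime that makes down-shifted imputation meaningful. Bait,
proximal and endogenous-biotin roles are assigned to proteins whose base
abundance is above the cohort median: effects then never cross the run
median, the normalization anchor is identical in every run, and the
configured log2 effects are recovered exactly (to ~1e-15) in the noise-free
case — the property the exactness tests rely on. The generator's truth
object records the expected enrichment of every (protein, bait) pair; the
endogenous-biotin boost applies to all runs equally and so expects 0.

The gradient generator uses four component templates with disjoint fraction
support (free pool 1–4, 60S 8–9, 80S 10–11, polysomes 12–20), per-component
occupancies (polysomes default to 1, encoding the anchoring assumption),
multiplicative log-normal band noise of configurable CV (mean-1
parameterization) and a per-profile exposure factor.

What passing these tests shows: the estimators are correct, calibrated and
scale-invariant under the stated generative assumptions. What they do not
show: robustness to features of real data the generator omits — correlated
noise between proteins, shared-peptide protein inference artefacts,
background that shifts the run median (e.g. a bait dominating the
purification), non-logistic censoring, or gradient fractions where particle
classes overlap.

## Problem sizes

Default test and acceptance runs use 2000 proteins × 5 baits (enrichment),
~770 imputed cells (imputation), 10 pipeline replicates (ranking), 25–100
simulated two-replicate experiments (occupancy), 100 random peptides (pI)
and 1000 random sequences (scanners) — sizes at which every Monte-Carlo
check has comfortable statistical margin while the whole suite stays fast.
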