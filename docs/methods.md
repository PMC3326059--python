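# Methods

This note documents the models, conventions and design choices behind
clinetile, in the order the pipeline runs them.

## Synthetic data: what is emulated, and what is not

The generator emulates an Affymetrix-style genome tiling experiment on a
clinal design. Log2 intensity of probe p on array j is

    y_pj = mu_p + alpha_p + (c_j / 2) * delta_p + eps_pj

where `mu_p` is the per-gene expression level for exonic probes
(Normal(9, 1) on the log2 scale) or a genomic baseline of 6 for intronic and
intergenic probes; `alpha_p ~ Normal(0, probe_affinity_sd)` is the probe
affinity (hybridization-efficiency) offset, constant across arrays;
`c_j = +1` for North arrays and −1 for South; `delta_p` equals the planted
log2 fold change for exonic probes of differentially expressed genes (sign
drawn per gene, the same effect at both larval stages) and 0 otherwise; and
`eps_pj ~ Normal(0, sigma_p)` is replicate noise. The per-probe true noise
variances `sigma_p^2` follow a scaled inverse chi-square distribution with
`noise_prior_df` (default 4) degrees of freedom about
`replicate_noise_sd^2` — the probe-to-probe variance heterogeneity
(cross-hybridization, sequence effects, polymorphism between populations)
that makes empirical-Bayes moderation meaningful; setting the df to infinity
gives homoskedastic noise, under which the moderation prior degenerates
(estimated d0 → large) and the moderated tests inherit the transform's
intensity-variance trend.

The raw intensity is `2**y_pj` plus a smooth spatial background that is
additive on the raw scale: one sinusoid cycle per chromosome with a
per-array random phase, plus a per-array offset, both scaled by
`background_trend_amplitude` (default 50, the same order as the 2^6 raw
baseline). Additive-on-raw is the deliberate choice: it is how optical
background behaves on a scanned array, and it is the structure the
windowed-percentile background subtraction is designed to remove — a
log-scale (multiplicative) trend could not be removed by that procedure and
would masquerade as spatially coherent differential expression.

Genome layout defaults (2 chromosomes x 200 kb, 80 genes of 1.5–3 kb with
3 exons each, 25-mer probes at step 40, 5 North + 5 South replicates at each
of two stages, 10% DE genes at |log2FC| = 2) are chosen so tests run in
seconds while at least one chromosome still exceeds the 1001-probe background
window. Gene placement enforces a minimum intergenic gap of 300 bp so that
the long calling scenario (reach ~3–4 probes ≈ 160 bp beyond a DE probe run)
cannot leak calls into a neighbouring gene; this keeps planted-gene identity
well defined in the truth table. All randomness flows from a single
`numpy.random.Generator` seed; identical seeds give byte-identical outputs.

What the generator does **not** emulate: sequence-composition (GC) affinity,
cross-hybridization between specific probe pairs, isoform structure (a DE
gene's exonic probes all shift uniformly), scanner saturation, and spatial
artifacts beyond a smooth low-frequency trend. Passing tests therefore show
that the analysis chain is correct and calibrated under this generative
model, not that it is robust to every artifact of real arrays.

## Probe mapping and labelling

"One alignment error" is interpreted as one substitution (Hamming distance
<= 1), not an indel, which would change the probe-length semantics of a
tiling array. Matching is exhaustive over both strands; the production path
uses a pigeonhole seed index (one of k+1 probe chunks must match exactly
when at most k substitutions are allowed), verified against a per-base
brute-force scan in the tests. Probes containing N are rejected loudly
rather than wildcard-matched. Only single-location probes are retained.

Labels follow the precedence exon > gene body > intergenic: a probe is
exonic if it overlaps >= 1 bp of any exon (attributed to the exon with the
largest overlap), else intronic if it overlaps any gene body (including a
probe that pokes past a gene end without touching an exon), else intergenic.
Intergenic regions are the maximal per-chromosome complements of the merged
gene intervals, including chromosome ends. Coordinates are 1-based inclusive
(GFF3 convention) everywhere except BED output (0-based half-open).

## Background and normalization

Background is computed independently per (array, chromosome) block on
position-sorted probes. The raw background at probe i is the nearest-rank
5th percentile — the value at rank ceil(0.05·m) — of the window of up to
1001 intensities centred on i, truncated without padding at chromosome ends.
Nearest-rank is used because it is exactly reproducible and oracle-checkable.
The raw background is then smoothed along the chromosome by tricube-weighted
local linear regression (statsmodels lowess, single pass, default span 0.3
of the block's probes, with a small interpolation delta for speed) and
subtracted; negative corrected intensities are preserved, since the
generalized log is defined on all reals. Blocks with fewer than three probes
return the raw background unchanged.

Normalization maps each array through `h_j(x) = arsinh((x − a_j)/b_j)`. The
reference transform's parameters come from a robust (Theil–Sen) fit of the
per-probe sd-vs-mean relation: if `sd ≈ c0 + c1·x` then
`a = −c0/c1, b = c0/c1` makes `h'(x) ∝ 1/sd(x)`, which is the
variance-stabilization condition; when the fit is degenerate the reference
falls back to median/MAD standardization. Every other array's `(a_j, b_j)`
are then calibrated so its transformed median and MAD equal the reference
array's. Because arsinh is monotone, the median constraint is exact
(`a_j = median(x_j) − b_j·sinh(m_ref)`), reducing the calibration to a 1-D
Brent root find in `log b_j`. This preserves the two contracts downstream
statistics need — approximate homoskedasticity across the intensity range
and between-array calibration — without reproducing any particular published
implementation's numerics. A scan over the glog scale on simulated data
shows the fitted scale sits at the flattest achievable
variance-by-decile profile (ratio ≈ 1.4 across deciles, versus ≈ 40 before
the transform); perfect flatness is unattainable with a global affine-arsinh
family because the transform is linear near zero.

## Probe-wise moderated tests

Each stage is a two-group comparison: effect = North − South mean difference
on the normalized scale, pooled variance s² on d = n_N + n_S − 2 df. The
hierarchical model places a scaled inverse chi-square prior (d0, s0²) on the
true variances, estimated by matching moments of z = log s²:
Var[z] = trigamma(d/2) + trigamma(d0/2) identifies d0 (Newton inversion of
the trigamma), and E[z] = log s0² + digamma(d/2) − digamma(d0/2) − log(d/d0)
identifies s0². When the observed spread of z does not exceed the chi-square
sampling term, d0 = ∞ and all moderated variances equal s0². The moderated
variance is the posterior mean (d0·s0² + d·s²)/(d0 + d); t̃ is referred to
Student t with d0 + d df (Normal when d0 = ∞). Probes with exactly zero
moderated variance are flagged degenerate with p = 0 rather than silently
passed downstream; the caller refuses p = 0 inputs, so degenerate probes
must be resolved explicitly. This constant-prior moderation is numerically
identical to the standard R implementation on shared inputs (checked against
limma's lmFit/eBayes in the test suite); intensity-trend and robust variants
are deliberately out of scope.

## Region calling

Scenario thresholds are the published constants: short p < 1e-5; medium,
unweighted geometric mean over the probe and one flanking probe on each side
< 0.01 (a 5-probe variant is exposed via `medium_flank=2` but not default);
long, geometric mean over 21 probes weighted by exp(−i²/(2·5)) on
probe-index distance i, < 0.1. Windows truncate at chromosome ends with
weights renormalized. Genes are called through their exonic or intronic
called probes; direction is the sign of the mean effect of the gene's called
probes; intergenic calls are reported per intergenic region, separately from
genes.

A caveat quantified by the acceptance suite: the long scenario has an
intrinsic false-call rate of ~2.9e-3 per probe on iid uniform null p-values
(the left skew of log p makes the weighted geometric mean far heavier-tailed
than a normal approximation suggests). On the default desk-scale fixture
(~45 genic probes per gene, 72 null genes) this admits a handful of false
genes per stage alongside full recovery of the planted genes, so the called
list's false fraction runs ~30–50% — dominated entirely by long-scenario
calls with no short-scenario support. Consumers who need a purer list can
restrict to short/medium calls or intersect stages (the between-stage
overlap test exists precisely because single-stage lists are noisy).

The overlap test is the exact hypergeometric upper tail
P(K >= k | N, |A|, |B|); the universe defaults to the number of genes with at
least one retained probe.

## Enrichment

The per-gene ranking statistic is the probe t with the largest absolute
value (max-|t|; mean-t available), signed, ranked separately for the
up-in-North and up-in-South directions with ties broken by gene id. A
category's score is the rank sum W of its members; the one-sided p is
P(W' <= W) under uniform sampling of m ranks from 1..N without replacement —
exact by a subset-sum convolution when N·m·W fits a fixed work budget,
otherwise the normal approximation with continuity correction
(mean m(N+1)/2, variance m(N−m)(N+1)/12). The FDR is estimated by gene-rank
permutation with category memberships fixed: per permutation all category
p-values are recomputed with the same scoring method, and
FDR(c) = E[#null p <= p(c)] / #observed p <= p(c), capped at 1; the default
is 1000 permutations (200 in the fast pipeline config). Chromosomal-window
categories are built from the annotation with the same >= 1 bp overlap rule
used for probe labelling.

## Clinal statistics

Latitude regressions are ordinary least squares of the population value on
signed degrees latitude (southern latitudes negative; an absolute-latitude
convention is a trivial relabelling of the input). Outliers are screened
with externally Studentized residuals — the leave-one-out form, t with
n − 3 df — multiplied by n (Bonferroni) and capped at 1, flagging adjusted
p < 0.05; this is the standard single-outlier regression test, and the
implementation (statsmodels OLSInfluence) is verified against an explicit
delete-refit-predict oracle to 1e-10. Refits excluding flagged populations
are reported alongside the full fit. ΔΔCt uses amplification efficiency
exactly 2; efficiency-corrected variants are out of scope.

## Pipeline and reproducibility

`clinetile run` executes simulate → annotate → preprocess → teststats →
call → overlap → enrich → cline, writing every intermediate as TSV
(GFF3/FASTA/GMT/JSON where appropriate) plus a manifest with the config,
per-stage seeds and sha256 checksums of every output; a rerun with the same
config is byte-identical. Stage seeds are small fixed offsets from the
config seed. Config validation constructs all parameter objects and checks
input-file existence before any computation runs.

## Known limitations

- The affine-arsinh normalization cannot achieve perfect variance flatness
  near zero intensity; residual heterogeneity (~1.4x in sd across deciles)
  slightly tilts constant-prior moderation when probe-level variance
  heterogeneity is weak.
- The long calling scenario is intrinsically permissive at desk scale (see
  above); its published threshold is kept as-is rather than recalibrated.
- The mapper is exhaustive-exact for <= 1 substitution but makes no attempt
  at genome-scale speed (no BWT/suffix index) or spliced alignment.
- Enrichment categories are treated as flat sets; ontology structure is not
  propagated.
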