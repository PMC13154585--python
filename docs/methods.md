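# Methods

## Count model and differential testing

Counts are modelled as negative binomial (NB2): for gene *g*, sample *j*,
`Var = mu + alpha * mu^2`, with `alpha = 0` the Poisson limit.  Depth
differences between libraries are handled by median-of-ratios size
factors — per sample, the median over genes of count / geometric-mean —
restricted to genes with no zero count; a sample's factor is defined up
to the common reference, so only factor *ratios* are meaningful.  If no
gene is positive in every sample the normalization raises rather than
silently switching reference.

Gene-wise dispersions are method-of-moments estimates
`max(0, (s^2 - m)/m^2)` on normalized counts, pooled across condition
groups with degrees-of-freedom weights, then shrunk toward a trend
`a0 + a1/mu` fitted by least squares with one 3-sigma trimming pass.
The shrinkage weight is `df / (df + prior_df)` with `prior_df = 10`:
with 10 samples per group this leaves ~64% of the weight on the
gene-wise estimate.  This is a deliberately simplified stand-in for
full empirical-Bayes dispersion machinery; its adequacy is assessed by
calibration (below), not by numerical identity to any external tool.

GLM fitting is Fisher scoring (IRLS) on the log link with fixed
dispersion, offsets `log s_j`, convergence at `max|dbeta| < 1e-8` or 100
iterations, and linear predictors clipped to ±30 to guard against
separation.  Wald standard errors come from the expected information
`X' W X`, `w = mu/(1 + alpha*mu)`.  An all-zero response is reported
with `p = 1`, `log2FC = 0` and a non-convergence flag rather than
dropped.  The engine is verified against a brute-force likelihood grid
search (deviance gap < 1e-4 on 6-sample designs), the closed-form
Poisson two-group MLE, and an independent GLM implementation.

Differential TE uses one NB GLM per gene on the stacked RNA+Ribo counts
with design `~ condition + assay + condition:assay`, per-assay size
factors as offsets, and the dispersion shared between the two assays of
a gene (the average of the per-assay shrunk estimates); sharing
stabilizes the small-sample interaction test.  Calibration on a
2000-gene null simulation (alpha = 0.1, n = 10+10) puts the empirical
type-I error of both Wald tests at 4.8–5.8% for a nominal 5%.

Raw p-values at 0.05 define significance by default — no
multiple-testing correction — because the regulatory classes are defined
on per-test significance; a Benjamini–Hochberg option (`fdr=True`)
reclassifies on adjusted p-values.  The tumour/normal design treats
condition as the only fixed effect; patient pairing is not modelled.

## Regulatory classes

Classification is a total function of (p_rna, log2FC_rna, p_te,
log2FC_te): *forwarded* = RNA-significant only, *exclusive* =
TE-significant only, *intensified* = both significant with equal signs,
*buffered* = both significant with opposing signs, else
*not_significant*.  With planted |log2FC| = 2 at n = 10+10 and
dispersion 0.1, the exclusive class is recovered for >= 85% of its
planted genes and the five-class confusion matrix keeps > 90% of its
mass on the diagonal.

## ORF catalog

An ORF is detected in a sample if any caller reports it.  Retention
requires detection in >= 2 samples of the tumour group **or** >= 2 of
the normal group (the thresholds are per group, not pooled).  Among
retained ORFs sharing a start coordinate — and, in a second pass, an end
coordinate — on the same transcript and strand, only the longest is
kept; ties break by smaller start, then lexicographic id, so the result
is independent of input order and idempotent.

Categories relative to the host transcript: exact CDS match =
`annotated`; on a coding transcript, `(start - cds_start) mod 3 == 0` =
`in_frame`, else `out_of_frame`; lncRNA host = `lncORF`.

Specificity uses Ribo-seq TPM (`rate_i = count_i/length_i`, scaled to
1e6 per sample).  Each ORF's group-mean TPM becomes a percentile rank
among all catalog ORFs with ties taking the maximum rank (so the
smallest attainable rank is 1/n and a fully tied catalog is uniformly
"expressed").  "Expressed" in a group means rank > q_low (default 0.10,
i.e. in the top 90%); the bottom decile is rank <= q_low.  The
complementary reading — expressed = top decile — is one `q_low` change
away.  Tumour-specific = expressed in tumours, bottom decile in
normals; the other classes follow symmetrically.  The upregulated set
is the union of the tumour-specific ORFs and the "both" ORFs with
Ribo-level p < 0.05 and log2FC > 0.  The C1–C4 expression clusters mark
ORFs significant at exactly one level: C1/C3 = RNA up/down only, C2/C4
= Ribo up/down only.

## Footprint QC

Coordinates are 0-based half-open transcript coordinates; GTF input
(1-based closed, genomic) is projected at the boundary by walking the
exon chain in transcription order.  Only each gene's canonical
transcript (longest CDS, ties by lexicographic id) is counted.  The
P-site is the 5' end plus a per-length offset; when calibration is
skipped the default offset is 12 nt, the canonical geometry of ~30 nt
footprints.  Calibration picks, per read length, the distance d (1–18)
maximizing the metagene count of 5' ends at `start_codon - d`, ties to
the smaller d.  Periodicity is the frame distribution of in-CDS
P-sites; region metrics assign each P-site to utr5/cds/utr3 by position
alone.  Reads outside the 25–50 nt window are discarded up front.

## 5'UTR features

Binary features (uORF flag, TOP flag, predicted IRES = probability >=
0.5 by default, m6A site present) are compared as gene ratios with the
two-sided Fisher exact test under the minimum-likelihood rule (sum of
all table probabilities <= the observed one) — stated explicitly because
two-sided Fisher conventions differ.  Continuous features (AU content,
IRES probability, cumulative m6A score = plain sum of site scores) use
the two-sided Wilcoxon rank-sum test: exact null for combined n <= 25
and tie-free data, otherwise the normal approximation with tie and
continuity corrections.  Genes without feature annotation are excluded;
if more than half of a gene set lacks coverage the comparison errors
instead of reporting a biased ratio.  uORF and TOP flags, IRES
probabilities and m6A site scores are inputs from upstream resources;
the package does not rescan sequence (a convenience A+U-fraction helper
exists but is not part of the comparison path).

## Co-expression modules

On TE profiles of the tumour samples: genes pass a mean-TE >= 1 filter,
then a variance filter keeping the top 70% of the survivors (ties by
gene id).  Adjacency is `|cor|^power` (power 9; a signed variant
`((1+cor)/2)^power` is a flag), transformed to topological overlap
`TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)`.
Average-linkage clustering of 1 − TOM is cut statically at height 0.8
(clusters of planted blocks sit well below, background pairs near 1);
clusters smaller than 35 genes go to the reserved `grey` label; modules
whose eigengenes correlate above 1 − 0.26 merge iteratively, most
correlated pair first, which makes module count monotone in the merge
cut.  The eigengene is the first principal component of the module's
standardized expression, signed so its mean gene correlation is
positive.  Static cut + eigengene merging replaces dynamic tree
cutting: far simpler, and the accuracy contract here is planted-module
recovery (>= 90% label purity on r = 0.9 blocks at 30 samples), not
numerical identity with any reference implementation.

Module–trait association is the Pearson correlation of eigengene and
(binary-coded) trait with the two-sided t-test; GS is the gene–trait
correlation, MM the gene–eigengene correlation.  Hubs satisfy |GS| >
0.4 and |MM| > 0.7 (strict inequalities) inside modules with trait
p < 0.05.  Age would be dichotomized at 60 and stage as advanced
(III/IV) vs early, coded 0/1.

## Peptide cross-referencing

Peptides of length 7–16 aa are matched to ORF translations by exact
contiguous substring search; shorter or longer peptides are dropped
before matching.  An optional flag collapses I/L on both sides, since
mass spectrometry cannot distinguish the two.  A peptide matching ORFs
of several categories takes the label of precedence canonical >
in_frame > out_of_frame > lncORF — a documented choice, since
multi-mapping resolution is genuinely open.  Tumour-specific peptides
are present in >= 1 tumour sample and absent from every normal sample.

## Synthetic data

The generator produces every input the pipeline consumes, with planted
truth.  A single global seed feeds hierarchical per-stage RNG streams,
so adding a stage never perturbs earlier draws; identical configurations
give bit-identical outputs.

Defaults are the study conditions of the emulated design: 19 tumour /
15 normal samples, NB dispersion 0.1, baseline mean 100 with gene
baselines log-uniform over a 100-fold range, planted |log2FC| = 2 at
both regulation levels, class fractions 0.70 null / 0.12 forwarded /
0.08 exclusive / 0.04 intensified / 0.06 buffered, ORF detection
dropout 0.1.  Buffered genes get an RNA change with an opposing TE
change, intensified a same-direction pair.  Library sizes are
multiplicative factors log-uniform in [0.5, 2], so size-factor
estimation is nontrivial.  The dispersion distribution and library-size
spread are the package's own choices of realistic values; the emulated
study does not publish them.

Details that matter for the tests:

- *ORF specificity* is planted with exact counts (8% tumour-specific,
  8% normal-specific, rest "both").  The group-specific fractions must
  stay below `q_low`: the bottom-decile rank rule can label at most 10%
  of the catalog as absent in a group, so planting more would make full
  recovery impossible by construction, and i.i.d. draws occasionally
  crossed that line at small catalog sizes.
- *P-site reads* place a `start_peak` fraction (default 0.2) of signal
  reads with the P-site exactly on the start codon, mimicking the
  initiation-site enrichment real footprint data shows.  Without it, a
  uniform-codon generator makes the metagene argmax ambiguous
  (distances 12, 9, 6, ... tie in expectation) and offset calibration
  would be exact only by luck.
- *Peptides* are exact substrings of ORF translations; per-group
  dropout keeps at least one sample per planted group so realized group
  presence always matches the planted truth.  Candidates are drawn one
  unit beyond the 7–16 window on both sides; out-of-window candidates
  are recorded in the truth but never emitted.
- *Module blocks* share a latent factor with loading sqrt(r);
  trait-associated factors correlate with the balanced binary trait at
  0.8.  Block genes get a larger log-scale amplitude (0.5) than
  background (0.3) — co-regulated modules vary more across samples —
  which is what lets the top-70% variance filter retain planted blocks
  intact; a fifth of background genes are scaled below mean TE 1 to
  exercise the mean filter.

What the generator does *not* emulate: raw reads and alignment noise,
isoform structure (one transcript per gene/ORF), batch effects, paired
patient structure, correlated gene-gene expression outside planted
modules, and real MS identification noise.  Green tests therefore show
the analysis rules and inference machinery behave as specified under NB
sampling with planted effects — not that real cohorts meet the model's
assumptions.

Null simulations and recovery runs use 2000 genes at n = 10+10, QC
mixtures 50k reads, and feature-enrichment replicates 200 draws at 50
genes per set — sizes at which the Monte-Carlo error is well inside the
asserted bands while the whole suite stays fast.

## Known limitations

- Dispersion shrinkage is moment-based with a fixed prior weight; very
  small cohorts (2–3 per group) will be less well calibrated than the
  tested n = 10 regime.
- Wald tests use the normal reference; at the tested sizes this is
  calibrated, but extremely low counts with large dispersion can
  inflate type-I error, as for any Wald-based NB test.
- The static tree cut assumes planted-block-like separation; on real
  data with nested module structure a dynamic cut would resolve more
  modules, at the cost of the simplicity contract above.
- Peptide matching is exact substring only: no missed-cleavage logic,
  no mass-based ambiguity beyond the optional I/L collapse.
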