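# translatome

Paired RNA-seq / Ribo-seq profiling of translational regulation, from raw
count matrices and per-sample ORF calls to a consolidated de novo ORF
catalog, differential-translation-efficiency calls with a four-class
regulatory categorization, 5'UTR feature enrichment, co-expression hub
genes, and immunopeptide-to-ORF cross-referencing.  It is aimed at
analysts working with tumour/normal ribosome-profiling cohorts who want
the whole chain reproducible and testable on synthetic data with planted
ground truth.

## The model

Counts for gene *g* in sample *j* are negative binomial with mean
μ<sub>gj</sub> and dispersion α<sub>g</sub> (variance μ + αμ²).
Sequencing depth enters as a log offset from median-of-ratios size
factors, computed per assay.  Translation efficiency is
TE = (mean normalized Ribo count) / (mean normalized RNA count).

Differential expression at the RNA (or Ribo) level is a Wald test on the
condition coefficient of the log-link NB GLM

    log mu = beta0 + beta_cond * condition + log s_j .

Differential TE is the Wald test on the interaction of the stacked
two-assay model

    log mu = beta0 + beta_c * condition + beta_a * assay
             + beta_ca * (condition x assay) + log s_j ,

so a fold-change shared by both assays cancels and only a change in the
Ribo/RNA ratio loads on β<sub>ca</sub> (log2FC_TE = β<sub>ca</sub>/ln 2).
Genes with p < 0.05 at the RNA level only are *forwarded*; at the TE
level only, *exclusive*; at both levels with concordant signs,
*intensified*; with opposing signs, *buffered*.

Around this core: ORF call sets are consolidated by a
detected-in-≥2-samples-per-group rule with longest-ORF deduplication and
TPM-rank specificity classes; 5'UTR features (uORF, TOP, AU content,
IRES probability, cumulative m6A score) are compared by Fisher exact and
Wilcoxon rank-sum tests; co-expression modules come from a soft-threshold
(|cor|^9) topological-overlap network with eigengene merging, and hub
genes satisfy |GS| > 0.4 and |MM| > 0.7 inside trait-associated modules;
peptides are matched to ORF translations by exact substring search
within the 7–16 aa window.

## Worked example

Generate a synthetic cohort (10 tumour / 8 normal samples, 400 genes,
planted fold-changes of 4x at each regulation level) and run every
stage:

```bash
translatome simulate --seed 11 --n-genes 400 --n-tumour 10 --n-normal 8 bundle/
translatome run bundle/ out/
```

The run prints a JSON summary (abridged):

```json
{
  "stages": {
    "dte": {
      "n_genes": 400,
      "n_deg": 103, "n_deg_up": 50, "n_deg_down": 53,
      "n_dteg": 78, "n_dteg_up": 46, "n_dteg_down": 32,
      "by_class": {
        "forwarded": 64, "exclusive": 39, "intensified": 12,
        "buffered": 27, "not_significant": 258
      }
    },
    "catalog": {
      "catalog_size": 120,
      "by_category": {"annotated": 99, "in_frame": 18, "out_of_frame": 1, "lncORF": 2},
      "by_specificity": {"both": 96, "tumour_specific": 12, "normal_specific": 12},
      "n_upregulated": 24
    },
    "qc": {"frame_fractions": [1.0, 0.0, 0.0]},
    "modules": {"n_modules": 2, "n_hubs": 53},
    "peptides": {"n_unique_peptides": 44, "n_tumour_specific": 19}
  }
}
```

Reading it: 103 of 400 genes are differentially expressed at the RNA
level and 78 change translation efficiency; 39 genes are regulated at
the translational level *exclusively* — the class that nominates
translation-dependent candidates.  The ORF catalog retains 120 of the
planted ORFs (the single-sample ORF and the shorter duplicate twins are
filtered), splits them by category and group specificity, and flags 24
as tumour-upregulated.  Frame fractions of (1.0, 0, 0) on noise-free
reads confirm the P-site offsets were calibrated exactly.  Two planted
co-expression modules are recovered with 53 hub genes in the
trait-associated one, and 19 of the 44 matched peptides are found only
in tumour samples.

Per-gene tables (`dte_results.tsv`, `orf_catalog.tsv`,
`module_assignments.tsv`, `peptides_annotated.tsv`, ...) are written to
`out/`.  Each stage is also callable on its own (`translatome dte`,
`orfcat`, `riboqc`, `utrcmp`, `modules`, `pepxref`) or from Python via
`translatome.dte.run_dte`, `translatome.catalog.build_catalog`, etc.

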