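"""Synthetic paired RNA-seq/Ribo-seq data with planted ground truth.

Every input the analysis pipeline consumes can be generated here: paired
negative-binomial count matrices with planted transcriptional and
translational fold-changes, per-sample ORF call sets with detection
dropout, P-site-level reads for QC, 5'UTR feature tables with planted
enrichment, peptide lists that are substrings of ORF translations, and
block-correlated TE matrices for module detection.

A single global seed feeds a hierarchical per-stage RNG stream
(``SimConfig.rng(stage)``) so that adding a stage never perturbs the
draws of earlier stages.  Library-size variation is simulated as
per-sample multiplicative factors drawn log-uniformly from [0.5, 2], so
size-factor estimation downstream is nontrivial.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation, Transcript
from .dte import CountMatrix

GENE_CLASSES = ("null", "forwarded", "exclusive", "intensified", "buffered")

DEFAULT_CLASS_FRACTIONS = {
    "null": 0.70,
    "forwarded": 0.12,
    "exclusive": 0.08,
    "intensified": 0.04,
    "buffered": 0.06,
}

ORF_CATEGORY_FRACTIONS = {
    "annotated": 0.80,
    "in_frame": 0.15,
    "out_of_frame": 0.01,
    "lncORF": 0.04,
}

ORF_SPECIFICITY_FRACTIONS = {
    "tumour_specific": 0.08,
    "normal_specific": 0.08,
    "both": 0.84,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class ModuleSpec:
    """One planted co-expression block."""

    size: int
    r: float = 0.9
    trait_assoc: bool = False
    trait_r: float = 0.8


@dataclass
class SimConfig:
    """Simulation conditions.

    Defaults mirror the profiled cohort: 19 tumour and 15 control
    samples, negative-binomial counts with dispersion 0.1, planted
    log2 fold-change magnitude 2 at both the transcriptional and the
    translational level.
    """

    n_tumour: int = 19
    n_normal: int = 15
    n_genes: int = 2000
    class_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    lfc_rna: float = 2.0
    lfc_te: float = 2.0
    dispersion: float = 0.1
    baseline_mean: float = 100.0
    seed: int = 0
    orf_dropout: float = 0.1
    n_orfs: int = 120
    n_dedup_pairs: int = 2
    plant_rare_orf: bool = True
    module_spec: list[ModuleSpec] = field(
        default_factory=lambda: [
            ModuleSpec(50, 0.9, True, 0.8),
            ModuleSpec(60, 0.9, False),
        ]
    )
    libsize_range: tuple = (0.5, 2.0)

    def validate(self) -> None:
        if self.n_tumour < 1 or self.n_normal < 1 or self.n_genes < 1:
            raise ConfigError("sample and gene counts must be >= 1")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_fractions sum to {total}, expected 1")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ConfigError(f"unknown regulatory classes: {sorted(unknown)}")
        if np.any(np.asarray(self.dispersion) < 0):
            raise ConfigError("dispersion must be >= 0")
        if not 0 <= self.orf_dropout < 1:
            raise ConfigError("orf_dropout must be in [0, 1)")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible RNG stream for one simulation stage."""
        key = zlib.crc32(stage.encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))

    @property
    def sample_ids(self) -> tuple[list[str], list[str]]:
        tum = [f"T{i + 1:02d}" for i in range(self.n_tumour)]
        nor = [f"N{i + 1:02d}" for i in range(self.n_normal)]
        return tum, nor


@dataclass
class TruthTable:
    """Planted ground truth for every simulated entity."""

    genes: pd.DataFrame | None = None
    orfs: pd.DataFrame | None = None
    peptides: pd.DataFrame | None = None
    modules: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean, alpha) -> np.ndarray:
    """Negative binomial with mean/dispersion parameterization.

    variance = mean + alpha * mean**2; alpha == 0 is the Poisson limit.
    """
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / alpha[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def _lib_factors(rng, n, lo, hi):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, CountMatrix, TruthTable]:
    """Paired RNA/RIBO count matrices with planted regulatory classes.

    For a gene with a planted TE change, the Ribo-seq mean in the tumour
    group equals the RNA-derived mean times ``2**lfc_te`` (before the
    per-sample library factor).
    """
    config.validate()
    rng = config.rng("counts")
    tum, nor = config.sample_ids
    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]

    classes = sorted(config.class_fractions)
    probs = np.array([config.class_fractions[c] for c in classes])
    gene_class = rng.choice(classes, size=config.n_genes, p=probs)

    base = config.baseline_mean * np.exp(
        rng.uniform(np.log(0.1), np.log(10.0), size=config.n_genes)
    )
    sign_rna = rng.choice([-1.0, 1.0], size=config.n_genes)
    sign_te_free = rng.choice([-1.0, 1.0], size=config.n_genes)

    has_rna = np.isin(gene_class, ["forwarded", "intensified", "buffered"])
    has_te = np.isin(gene_class, ["exclusive", "intensified", "buffered"])
    lfc_rna = np.where(has_rna, sign_rna * config.lfc_rna, 0.0)
    te_sign = np.where(
        gene_class == "intensified",
        sign_rna,
        np.where(gene_class == "buffered", -sign_rna, sign_te_free),
    )
    lfc_te = np.where(has_te, te_sign * config.lfc_te, 0.0)

    n_t, n_n = config.n_tumour, config.n_normal
    rna_mean = np.concatenate(
        [
            np.repeat((base * 2.0 ** lfc_rna)[:, None], n_t, axis=1),
            np.repeat(base[:, None], n_n, axis=1),
        ],
        axis=1,
    )
    te_mult = np.concatenate(
        [
            np.repeat((2.0 ** lfc_te)[:, None], n_t, axis=1),
            np.ones((config.n_genes, n_n)),
        ],
        axis=1,
    )
    ribo_mean = rna_mean * te_mult

    lo, hi = config.libsize_range
    f_rna = _lib_factors(rng, n_t + n_n, lo, hi)
    f_ribo = _lib_factors(rng, n_t + n_n, lo, hi)

    alpha = np.asarray(config.dispersion, dtype=float)
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    rna_counts = _nb_draw(rng, rna_mean * f_rna[None, :], alpha)
    ribo_counts = _nb_draw(rng, ribo_mean * f_ribo[None, :], alpha)

    samples = tum + nor
    design = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": ["tumour"] * n_t + ["normal"] * n_n,
        }
    )
    rna = CountMatrix(
        pd.DataFrame(rna_counts, index=genes, columns=samples),
        design.assign(assay="rna"),
        assay="rna",
    )
    ribo = CountMatrix(
        pd.DataFrame(ribo_counts, index=genes, columns=samples),
        design.assign(assay="ribo"),
        assay="ribo",
    )
    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "gene_id": genes,
                "class": gene_class,
                "lfc_rna": lfc_rna,
                "lfc_te": lfc_te,
                "baseline_mean": base,
            }
        ).set_index("gene_id")
    )
    return rna, ribo, truth


# ---------------------------------------------------------------------------
# ORF call sets, counts and translations
# ---------------------------------------------------------------------------

@dataclass
class OrfBundle:
    """Everything the ORF-catalog stage consumes, plus its truth table."""

    callsets: dict  # sample_id -> DataFrame of calls
    groups: dict  # sample_id -> 'tumour' | 'normal'
    annotation: Annotation
    rna_counts: CountMatrix
    ribo_counts: CountMatrix
    lengths: pd.Series
    proteins: dict  # orf_id -> amino-acid string
    truth: pd.DataFrame  # per-ORF planted truth


def _orf_coordinates(rng, category, cds_start, cds_end):
    """Transcript coordinates of one ORF consistent with its category."""
    if category == "annotated":
        return cds_start, cds_end
    if category == "lncORF":
        length = 3 * int(rng.integers(20, 80))
        return 10, 10 + length
    max_len = cds_end - cds_start
    if category == "in_frame":
        shift = 3 * int(rng.integers(1, 10))
    else:
        shift = 3 * int(rng.integers(1, 10)) + int(rng.integers(1, 3))
    start = cds_start + shift
    n_codons = int(rng.integers(15, max(16, (cds_end - start) // 3)))
    end = min(start + 3 * n_codons, cds_end)
    return start, end


def simulate_orf_bundle(config: SimConfig) -> OrfBundle:
    """Per-sample ORF call sets with planted categories and specificity.

    Tumour-specific ORFs are expressed (hence detectable) only in tumour
    samples; detection within the expressed group fails independently per
    sample with probability ``orf_dropout``.  Shared-start duplicate
    pairs and, optionally, a single-sample 'rare' ORF are planted so that
    downstream consolidation rules can be exercised.
    """
    config.validate()
    rng = config.rng("orfs")
    tum, nor = config.sample_ids
    groups = {s: "tumour" for s in tum} | {s: "normal" for s in nor}

    n = config.n_orfs
    cats = sorted(ORF_CATEGORY_FRACTIONS)
    cat_p = np.array([ORF_CATEGORY_FRACTIONS[c] for c in cats])
    # exact planted counts: the group-specific fractions must stay below
    # the q_low rank cut or the bottom-decile rule cannot recover them
    spec_pool = []
    for name in ("tumour_specific", "normal_specific"):
        spec_pool += [name] * int(np.floor(ORF_SPECIFICITY_FRACTIONS[name] * n))
    spec_pool += ["both"] * (n - len(spec_pool))
    spec_assign = rng.permutation(np.array(spec_pool))

    rows = []
    transcripts = []
    for i in range(n):
        orf_id = f"orf{i + 1:04d}"
        category = str(rng.choice(cats, p=cat_p))
        specificity = str(spec_assign[i])
        tid, gid = f"t_{orf_id}", f"gene_{orf_id}"
        if category == "lncORF":
            biotype, cds = "lncRNA", (None, None)
            tlen = 900
        else:
            biotype = "protein_coding"
            cds = (100, 100 + 3 * int(rng.integers(100, 200)))
            tlen = cds[1] + 200
        start, end = _orf_coordinates(rng, category, *(cds if cds[0] is not None else (None, None)))
        transcripts.append(
            Transcript(tid, gid, tlen, cds[0], cds[1], biotype)
        )
        rows.append(
            {
                "orf_id": orf_id,
                "transcript_id": tid,
                "gene_id": gid,
                "start": start,
                "end": end,
                "strand": "+",
                "category": category,
                "specificity": specificity,
                "dedup_winner": True,
                "rare": False,
            }
        )

    # shared-start duplicate pairs: shorter twin must lose deduplication
    for j in range(config.n_dedup_pairs):
        host = rows[j]
        twin = dict(host)
        twin["orf_id"] = host["orf_id"] + "_short"
        twin["end"] = host["start"] + max(
            30, (host["end"] - host["start"]) // 2 // 3 * 3
        )
        twin["dedup_winner"] = False
        rows.append(twin)

    if config.plant_rare_orf:
        rare = {
            "orf_id": "orf_rare",
            "transcript_id": "t_orf_rare",
            "gene_id": "gene_orf_rare",
            "start": 100,
            "end": 190,
            "strand": "+",
            "category": "lncORF",
            "specificity": "tumour_specific",
            "dedup_winner": True,
            "rare": True,
        }
        transcripts.append(
            Transcript("t_orf_rare", "gene_orf_rare", 400, None, None, "lncRNA")
        )
        rows.append(rare)

    truth = pd.DataFrame(rows).set_index("orf_id")
    annotation = Annotation(transcripts)

    # detection: expressed group(s) only, independent dropout per sample
    callsets = {s: [] for s in groups}
    for orf_id, row in truth.iterrows():
        if row["rare"]:
            samples = [tum[0]]
        else:
            samples = []
            if row["specificity"] in ("tumour_specific", "both"):
                samples += tum
            if row["specificity"] in ("normal_specific", "both"):
                samples += nor
            keep = rng.random(len(samples)) >= config.orf_dropout
            samples = [s for s, k in zip(samples, keep) if k]
        for s in samples:
            caller = str(rng.choice(["orfquant", "ribotricer", "both"]))
            callers = ["orfquant", "ribotricer"] if caller == "both" else [caller]
            for c in callers:
                callsets[s].append(
                    {
                        "orf_id": orf_id,
                        "transcript_id": row["transcript_id"],
                        "gene_id": row["gene_id"],
                        "start": row["start"],
                        "end": row["end"],
                        "strand": row["strand"],
                        "caller": c,
                    }
                )
    cols = ["orf_id", "transcript_id", "gene_id", "start", "end", "strand", "caller"]
    callsets = {
        s: pd.DataFrame(calls, columns=cols) for s, calls in callsets.items()
    }

    # ORF-level counts: specificity sets the group means; a planted
    # per-ORF regulatory pattern drives the C1-C4 cluster assignment
    orf_ids = truth.index.to_list()
    n_all = len(orf_ids)
    base = config.baseline_mean * np.exp(
        rng.uniform(np.log(0.5), np.log(5.0), size=n_all)
    )
    low = base / 50.0
    spec_arr = truth["specificity"].to_numpy()
    tum_mean = np.where(spec_arr == "normal_specific", low, base)
    nor_mean = np.where(spec_arr == "tumour_specific", low, base)
    # keep planted tumour-specific ORFs clearly expressed in tumours
    tum_mean = np.where(spec_arr == "tumour_specific", 2.0 * base, tum_mean)
    nor_mean = np.where(spec_arr == "normal_specific", 2.0 * nor_mean, nor_mean)

    reg = rng.choice(
        ["none", "rna_up", "ribo_up", "rna_down", "ribo_down"],
        size=n_all,
        p=[0.6, 0.1, 0.1, 0.1, 0.1],
    )
    reg = np.where(spec_arr == "both", reg, "none")
    fold = 4.0
    rna_t = tum_mean * np.where(reg == "rna_up", fold, 1.0)
    rna_t = rna_t / np.where(reg == "rna_down", fold, 1.0)
    ribo_t = tum_mean * np.where(reg == "ribo_up", fold, 1.0)
    ribo_t = ribo_t / np.where(reg == "ribo_down", fold, 1.0)

    n_t, n_n = config.n_tumour, config.n_normal
    rna_mean = np.concatenate(
        [np.repeat(rna_t[:, None], n_t, 1), np.repeat(nor_mean[:, None], n_n, 1)], 1
    )
    ribo_mean = np.concatenate(
        [np.repeat(ribo_t[:, None], n_t, 1), np.repeat(nor_mean[:, None], n_n, 1)], 1
    )
    lo, hi = config.libsize_range
    f_rna = _lib_factors(rng, n_t + n_n, lo, hi)
    f_ribo = _lib_factors(rng, n_t + n_n, lo, hi)
    alpha = float(np.mean(config.dispersion))
    rna_counts = _nb_draw(rng, rna_mean * f_rna[None, :], alpha)
    ribo_counts = _nb_draw(rng, ribo_mean * f_ribo[None, :], alpha)

    samples = tum + nor
    design = pd.DataFrame(
        {"sample_id": samples, "condition": ["tumour"] * n_t + ["normal"] * n_n}
    )
    rna_cm = CountMatrix(
        pd.DataFrame(rna_counts, index=orf_ids, columns=samples),
        design.assign(assay="rna"),
        "rna",
    )
    ribo_cm = CountMatrix(
        pd.DataFrame(ribo_counts, index=orf_ids, columns=samples),
        design.assign(assay="ribo"),
        "ribo",
    )
    lengths = pd.Series(
        (truth["end"] - truth["start"]).to_numpy(), index=truth.index, name="length"
    )

    proteins = {}
    for orf_id, row in truth.iterrows():
        n_aa = max((row["end"] - row["start"]) // 3 - 1, 8)
        proteins[orf_id] = "".join(
            rng.choice(list(AMINO_ACIDS), size=n_aa)
        )

    truth = truth.assign(reg_pattern=reg)
    return OrfBundle(
        callsets=callsets,
        groups=groups,
        annotation=annotation,
        rna_counts=rna_cm,
        ribo_counts=ribo_cm,
        lengths=lengths,
        proteins=proteins,
        truth=truth,
    )


def simulate_orf_callsets(config: SimConfig):
    """Per-sample ORF call sets and the planted per-ORF truth table."""
    bundle = simulate_orf_bundle(config)
    return bundle.callsets, bundle.truth


# ---------------------------------------------------------------------------
# P-site reads
# ---------------------------------------------------------------------------

def simulate_psite_reads(
    annotation: Annotation,
    n_reads: int = 10_000,
    read_length: int | tuple[int, int] = 30,
    offset: int = 12,
    noise: float = 0.0,
    start_peak: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Reads whose 5' ends sit ``offset`` nt upstream of in-frame codons.

    A ``start_peak`` fraction of the signal reads is placed with the
    P-site exactly on the start codon, mimicking the initiation-site
    enrichment real footprint data shows; this is what makes the
    start-codon metagene peak unambiguous for offset calibration.  A
    ``noise`` fraction of reads instead gets a P-site uniform over CDS
    positions (all three frames equally).  ``read_length`` may be a fixed
    length or an inclusive (min, max) range sampled uniformly.
    """
    coding = [t for t in annotation.transcripts.values() if t.coding]
    if not coding:
        raise ConfigError("annotation contains no CDS")
    lengths = (
        (read_length, read_length) if isinstance(read_length, int) else read_length
    )
    if offset >= lengths[0]:
        raise ConfigError(f"offset {offset} >= minimum read length {lengths[0]}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(b"psites")]))

    recs = []
    for _ in range(n_reads):
        t = coding[int(rng.integers(len(coding)))]
        n_codons = (t.cds_end - t.cds_start) // 3
        if rng.random() < noise:
            psite = t.cds_start + int(rng.integers(t.cds_end - t.cds_start))
        elif rng.random() < start_peak:
            psite = t.cds_start
        else:
            psite = t.cds_start + 3 * int(rng.integers(n_codons))
        five_prime = psite - offset
        if five_prime < 0:
            continue
        rl = int(rng.integers(lengths[0], lengths[1] + 1))
        recs.append((t.transcript_id, five_prime, rl))
    return pd.DataFrame(recs, columns=["transcript_id", "five_prime", "length"])


# ---------------------------------------------------------------------------
# 5'UTR features and peptides
# ---------------------------------------------------------------------------

@dataclass
class FeatureEnrichment:
    """Planted prevalences/shifts of 5'UTR features (target vs control)."""

    uorf: tuple = (0.6, 0.3)
    top: tuple = (0.3, 0.3)
    m6a: tuple = (0.8, 0.2)
    au_content: tuple = (0.65, 0.45)  # Beta means, concentration 20
    ires_prob: tuple = (0.45, 0.35)
    m6a_sites_lambda: tuple = (3.0, 3.0)  # sites per m6A-positive gene


def simulate_features(
    target_genes: list[str],
    control_genes: list[str],
    enrichment: FeatureEnrichment | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """5'UTR feature table with planted target-set enrichment."""
    if not target_genes or not control_genes:
        raise ConfigError("gene sets must be non-empty")
    if set(target_genes) & set(control_genes):
        raise ConfigError("target and control gene sets overlap")
    enr = enrichment or FeatureEnrichment()
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(b"features")]))

    rows = []
    conc = 20.0
    for genes, idx in ((target_genes, 0), (control_genes, 1)):
        for g in genes:
            has_m6a = rng.random() < enr.m6a[idx]
            if has_m6a:
                n_sites = 1 + rng.poisson(enr.m6a_sites_lambda[idx])
                sites = [
                    (int(rng.integers(0, 200)), float(np.round(rng.exponential(1.0), 4)))
                    for _ in range(n_sites)
                ]
            else:
                sites = []
            mean_au = enr.au_content[idx]
            mean_ires = enr.ires_prob[idx]
            rows.append(
                {
                    "gene_id": g,
                    "has_uorf": bool(rng.random() < enr.uorf[idx]),
                    "has_top": bool(rng.random() < enr.top[idx]),
                    "au_content": float(
                        rng.beta(mean_au * conc, (1 - mean_au) * conc)
                    ),
                    "ires_prob": float(
                        rng.beta(mean_ires * conc, (1 - mean_ires) * conc)
                    ),
                    "m6a_sites": sites,
                    "cumulative_m6a": float(sum(s for _, s in sites)),
                }
            )
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_peptides(
    proteins: dict,
    n_tumour_samples: int = 4,
    n_normal_samples: int = 2,
    n_peptides: int = 60,
    tumour_only_fraction: float = 0.4,
    sample_dropout: float = 0.2,
    length_range: tuple = (7, 16),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide lists whose sequences are substrings of ORF translations.

    Returns ``(peptide table, truth)``.  Candidate peptides are drawn
    with lengths spanning one unit beyond the retained window on either
    side; out-of-window candidates are recorded in the truth with
    ``emitted == False`` but never appear in the emitted lists.
    Tumour-only peptides never appear in a normal sample.
    """
    if not proteins:
        raise ConfigError("no ORF translations supplied")
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(b"peptides")]))
    orf_ids = sorted(proteins)
    tum = [f"MT{i + 1}" for i in range(n_tumour_samples)]
    nor = [f"MN{i + 1}" for i in range(n_normal_samples)]

    truth_rows = []
    emitted = []
    seen = set()
    lo, hi = length_range
    for k in range(n_peptides):
        orf = orf_ids[int(rng.integers(len(orf_ids)))]
        prot = proteins[orf]
        length = int(rng.integers(lo - 1, hi + 2))
        if length > len(prot):
            length = min(hi, len(prot))
        start = int(rng.integers(0, len(prot) - length + 1))
        seq = prot[start : start + length]
        if seq in seen:
            continue
        seen.add(seq)
        tumour_only = rng.random() < tumour_only_fraction
        in_window = lo <= length <= hi
        truth_rows.append(
            {
                "peptide": seq,
                "source_orf": orf,
                "tumour_only": tumour_only,
                "emitted": in_window,
            }
        )
        if not in_window:
            continue
        # per-group dropout with a guard: a peptide always keeps >= 1
        # sample in every group it is planted in, so realized group
        # presence matches the planted truth exactly
        group_samples = [tum] if tumour_only else [tum, nor]
        for samples in group_samples:
            keep = rng.random(len(samples)) >= sample_dropout
            if not keep.any():
                keep[int(rng.integers(len(samples)))] = True
            for s, kept in zip(samples, keep):
                if kept:
                    emitted.append(
                        {
                            "sample_id": s,
                            "group": "tumour" if s in tum else "normal",
                            "peptide": seq,
                        }
                    )
    return (
        pd.DataFrame(emitted, columns=["sample_id", "group", "peptide"]),
        pd.DataFrame(truth_rows).set_index("peptide"),
    )


def simulate_features_and_peptides(
    target_genes: list[str],
    control_genes: list[str],
    proteins: dict,
    enrichment: FeatureEnrichment | None = None,
    seed: int = 0,
    **peptide_kwargs,
):
    """Convenience wrapper bundling feature and peptide simulation."""
    features = simulate_features(target_genes, control_genes, enrichment, seed)
    peptides, pep_truth = simulate_peptides(proteins, seed=seed, **peptide_kwargs)
    return features, peptides, pep_truth


# ---------------------------------------------------------------------------
# module data
# ---------------------------------------------------------------------------

def simulate_module_data(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """TE matrix with planted correlated blocks and a binary trait.

    Genes of a planted block share a latent factor with loading
    ``sqrt(r)``; trait-associated blocks draw their factor correlated
    with the (balanced, binary) trait at ``trait_r``.  Values are mapped
    to a TE scale with block means >= 1.  Block genes get a larger
    log-scale amplitude than background genes (co-regulated modules vary
    more across samples), and a fifth of the background genes are scaled
    below mean TE 1, so both the mean-TE and the variance-rank filters
    are nontrivial.
    """
    config.validate()
    if not config.module_spec:
        raise ConfigError("module_spec is empty")
    total = sum(m.size for m in config.module_spec)
    if max(m.size for m in config.module_spec) > config.n_genes or total > config.n_genes:
        raise ConfigError(
            f"module sizes (sum {total}) exceed n_genes={config.n_genes}"
        )
    rng = config.rng("modules")
    n_samples = config.n_tumour
    samples = [f"T{i + 1:02d}" for i in range(n_samples)]

    trait = np.zeros(n_samples)
    trait[rng.permutation(n_samples)[: n_samples // 2]] = 1.0
    t_std = (trait - trait.mean()) / max(trait.std(), 1e-12)

    blocks = []
    labels = []
    for m_idx, spec in enumerate(config.module_spec, start=1):
        z = rng.standard_normal(n_samples)
        if spec.trait_assoc:
            f = spec.trait_r * t_std + np.sqrt(1 - spec.trait_r**2) * z
        else:
            f = z
        eps = rng.standard_normal((spec.size, n_samples))
        x = np.sqrt(spec.r) * f[None, :] + np.sqrt(1 - spec.r) * eps
        blocks.append(x)
        labels += [f"planted_{m_idx}"] * spec.size
    amp = np.full(total, 0.5)
    n_bg = config.n_genes - total
    if n_bg:
        blocks.append(rng.standard_normal((n_bg, n_samples)))
        labels += ["background"] * n_bg
        amp = np.concatenate([amp, np.full(n_bg, 0.3)])
    x = np.vstack(blocks)

    te = 2.0 * np.exp(amp[:, None] * x)
    if n_bg:
        n_low = n_bg // 5
        low_rows = total + rng.permutation(n_bg)[:n_low]
        te[low_rows] *= 0.2
    genes = [f"mg{i + 1:04d}" for i in range(config.n_genes)]
    te_df = pd.DataFrame(te, index=genes, columns=samples)
    traits = pd.DataFrame({"sample_id": samples, "trait": trait.astype(int)})
    truth = pd.DataFrame({"gene_id": genes, "module": labels}).set_index("gene_id")
    return te_df, traits, truth


# ---------------------------------------------------------------------------
# fixture bundle on disk
# ---------------------------------------------------------------------------

def write_bundle(config: SimConfig, outdir: str | Path) -> Path:
    """Write a complete, self-contained input bundle for the pipeline.

    Layout: counts and design as TSV, ORF calls as per-sample TSV plus a
    sidecar, annotation as GTF, ORF translations as FASTA, peptides and
    features as TSV, truth tables under ``truth/``, plus a manifest.
    """
    from . import io as tio
    from .annotation import write_gtf

    out = Path(outdir)
    (out / "callsets").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    rna, ribo, truth = simulate_counts(config)
    tio.write_counts(rna.counts, out / "rna_counts.tsv")
    tio.write_counts(ribo.counts, out / "ribo_counts.tsv")
    design = pd.concat([rna.design, ribo.design], ignore_index=True)
    design.to_csv(out / "design.tsv", sep="\t", index=False)

    bundle = simulate_orf_bundle(config)
    for sample, calls in bundle.callsets.items():
        calls.to_csv(out / "callsets" / f"{sample}.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": list(bundle.groups), "group": list(bundle.groups.values())}
    ).to_csv(out / "callset_groups.tsv", sep="\t", index=False)
    tio.write_counts(bundle.rna_counts.counts, out / "orf_rna_counts.tsv")
    tio.write_counts(bundle.ribo_counts.counts, out / "orf_ribo_counts.tsv")
    bundle.lengths.to_frame().to_csv(out / "orf_lengths.tsv", sep="\t")
    write_gtf(bundle.annotation, out / "annotation.gtf")
    tio.write_fasta(bundle.proteins, out / "orf_proteins.fasta")
    sidecar = bundle.truth.reset_index()[
        ["orf_id", "transcript_id", "gene_id", "category"]
    ]
    sidecar.to_csv(out / "orf_sidecar.tsv", sep="\t", index=False)

    reads = simulate_psite_reads(
        bundle.annotation, n_reads=5000, seed=config.seed
    )
    reads.to_csv(out / "psite_reads.tsv", sep="\t", index=False)

    gene_truth = truth.genes
    target = gene_truth.index[
        (gene_truth["class"] == "exclusive") & (gene_truth["lfc_te"] > 0)
    ].tolist()[:50]
    control = gene_truth.index[gene_truth["class"] == "null"].tolist()[:50]
    features = simulate_features(target, control, seed=config.seed)
    tio.write_features(features, out / "utr_features.tsv")
    with open(out / "target_genes.txt", "w") as fh:
        fh.write("\n".join(target) + "\n")
    with open(out / "control_genes.txt", "w") as fh:
        fh.write("\n".join(control) + "\n")

    peptides, pep_truth = simulate_peptides(bundle.proteins, seed=config.seed)
    peptides.to_csv(out / "peptides.tsv", sep="\t", index=False)

    te_df, traits, mod_truth = simulate_module_data(config)
    tio.write_counts(te_df, out / "te_matrix.tsv")
    traits.to_csv(out / "traits.tsv", sep="\t", index=False)

    truth.genes.to_csv(out / "truth" / "genes.tsv", sep="\t")
    bundle.truth.drop(columns=[], errors="ignore").to_csv(
        out / "truth" / "orfs.tsv", sep="\t"
    )
    pep_truth.to_csv(out / "truth" / "peptides.tsv", sep="\t")
    mod_truth.to_csv(out / "truth" / "modules.tsv", sep="\t")

    manifest = {
        "config": asdict(config),
        "files": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
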