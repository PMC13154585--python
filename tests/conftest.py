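import numpy as np
import pandas as pd
import pytest

from translatome.annotation import Annotation, Transcript
from translatome.simulate import SimConfig, simulate_counts, simulate_orf_bundle, write_bundle


@pytest.fixture(scope="session")
def toy_annotation():
    """Three coding transcripts plus one lncRNA, transcript coordinates."""
    return Annotation(
        [
            Transcript("tx1", "geneA", 500, 100, 400, "protein_coding"),
            Transcript("tx2", "geneB", 600, 60, 540, "protein_coding"),
            Transcript("tx3", "geneB", 300, 60, 240, "protein_coding"),
            Transcript("lnc1", "geneL", 400, None, None, "lncRNA"),
        ]
    )


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_genes=300, n_tumour=8, n_normal=6)


@pytest.fixture(scope="session")
def paired_counts(small_config):
    return simulate_counts(small_config)


@pytest.fixture(scope="session")
def orf_bundle(small_config):
    return simulate_orf_bundle(small_config)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    config = SimConfig(seed=5, n_genes=400, n_tumour=10, n_normal=8)
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(config, out)
    return out


@pytest.fixture(scope="session")
def null_sim():
    """2000-gene null simulation (no planted effects), n = 10 + 10."""
    config = SimConfig(
        seed=11,
        n_genes=2000,
        n_tumour=10,
        n_normal=10,
        class_fractions={"null": 1.0},
        dispersion=0.1,
    )
    return simulate_counts(config)


@pytest.fixture(scope="session")
def planted_sim():
    """2000-gene simulation with |log2FC| = 2 planted effects, n = 10 + 10."""
    config = SimConfig(
        seed=13,
        n_genes=2000,
        n_tumour=10,
        n_normal=10,
        lfc_rna=2.0,
        lfc_te=2.0,
        dispersion=0.1,
    )
    return simulate_counts(config)
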