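import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from omnigwas import datasets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def urate_published() -> pd.DataFrame:
    return datasets.load_urate_opposite_snps()


@pytest.fixture(scope="session")
def urate_paired(urate_published) -> pd.DataFrame:
    return datasets.paired_from_published(urate_published)


@pytest.fixture(scope="session")
def testosterone_published() -> pd.DataFrame:
    return datasets.load_testosterone_loci()


@pytest.fixture(scope="session")
def testosterone_paired(testosterone_published) -> pd.DataFrame:
    return datasets.paired_from_published(testosterone_published)


def write_neale_style(path, rows):
    """Write a minimal Neale-style per-sex sumstat TSV from row dicts."""
    cols = ["variant", "chr", "pos", "major_allele", "minor_allele", "info",
            "n_complete_samples", "minor_AF", "beta", "se", "pval"]
    df = pd.DataFrame(rows)
    df = df[[c for c in cols if c in df.columns]]
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def neale_writer():
    return write_neale_style


def default_row(**kw):
    row = dict(variant="rs1", chr=1, pos=1000, major_allele="A",
               minor_allele="G", info=0.99, n_complete_samples=10000,
               minor_AF=0.3, beta=0.1, se=0.05)
    row.update(kw)
    return row


@pytest.fixture
def make_row():
    return default_row
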