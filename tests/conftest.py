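import numpy as np
import pytest

from mrtools.harmonize import HarmonizedSet
from mrtools.summary_io import GwasRecord


def make_record(
    snp_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pvalue=1e-10,
    eaf=None,
    chrom=None,
    pos=None,
):
    return GwasRecord(snp_id, effect_allele, other_allele, beta, se, pvalue, eaf, chrom, pos)


def make_hset(X, Y, se_Y, se_X=None, snp_ids=None, **kw):
    X = np.asarray(X, dtype=float)
    k = len(X)
    return HarmonizedSet(
        exposure_name=kw.get("exposure_name", "exp"),
        outcome_name=kw.get("outcome_name", "out"),
        snp_ids=snp_ids or [f"rs{i + 1}" for i in range(k)],
        X=X,
        se_X=np.asarray(se_X if se_X is not None else np.full(k, 0.01), dtype=float),
        Y=np.asarray(Y, dtype=float),
        se_Y=np.asarray(se_Y, dtype=float),
    )


def random_hset(rng, k):
    return make_hset(
        X=rng.uniform(0.02, 0.5, k) * rng.choice([-1, 1], k),
        Y=rng.normal(0, 0.2, k),
        se_Y=rng.uniform(0.01, 0.3, k),
        se_X=rng.uniform(0.001, 0.05, k),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_hset():
    """Five well-separated instruments, no special structure."""
    return make_hset(
        X=[0.12, -0.08, 0.25, 0.3, -0.15],
        Y=[-0.05, 0.04, -0.11, -0.13, 0.08],
        se_Y=[0.02, 0.03, 0.025, 0.04, 0.05],
        se_X=[0.005, 0.004, 0.008, 0.01, 0.006],
    )
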