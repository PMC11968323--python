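import numpy as np
import pytest

from glsim import (
    BaseObservation,
    ErrorModelConfig,
    ReadSimConfig,
    TruthCohort,
    TruthSite,
    generate_truth,
)


def make_obs(base, q, strand=0, tail=1, mq=60, p=None):
    """Hand-build a read observation; true error defaults to 10^(-q/10)."""
    if p is None:
        p = 10.0 ** (-q / 10.0)
    return BaseObservation(
        base=base, true_error_prob=p, reported_quality=q,
        strand=strand, tail_distance=tail, mapping_quality=mq,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_cohort():
    return generate_truth(
        n_samples=2, contig_length=1000, n_variant_sites=5,
        allele_freq_sampler=0.5, seed=1,
    )


@pytest.fixture
def err_exact():
    return ErrorModelConfig(mean_error=0.002, beta_variance=0.0)


@pytest.fixture
def err_beta():
    return ErrorModelConfig(mean_error=0.002, beta_variance=1e-5)


@pytest.fixture
def read_cfg():
    return ReadSimConfig(mean_depth=5.0)


@pytest.fixture
def hand_site():
    """One biallelic A/C site, two samples: het and hom-ref."""
    return TruthSite("chr1", 10, "A", ("C",), ((0, 1), (0, 0)))


@pytest.fixture
def hand_cohort(hand_site):
    return TruthCohort(["s1", "s2"], {"chr1": 100}, [hand_site])
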