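import numpy as np
import pandas as pd
import pytest

import epinet as ep


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_snp_panel():
    return ep.PanelSpec(pd.DataFrame({
        "snp_id": ["s1", "s2"],
        "gene": ["GENE_A", "GENE_B"],
        "allele_freq": [0.5, 0.5],
    }))


@pytest.fixture
def three_class_scenario(two_snp_panel):
    """Well-separated 3-class cohort with logit gating on two covariates."""
    def _make(seed, n=800):
        return ep.Scenario(
            two_snp_panel, n,
            class_means=[[70.0, 110.0], [85.0, 135.0], [100.0, 160.0]],
            class_sds=[[4.0, 6.0]] * 3,
            gating=np.array([[0.0, 0.0, 0.0],
                             [0.3, 1.0, 0.0],
                             [0.1, 0.0, 1.0]]),
            indicator_names=["diastolic", "systolic"],
            covariate_names=["c1", "c2"],
            seed=seed)
    return _make


def exact_hwe_genotypes(p, n_units):
    """Dosage vector with counts exactly proportional to (q^2, 2pq, p^2).

    n_units scales the smallest integer HWE table for rational p.
    """
    from fractions import Fraction
    fp = Fraction(p).limit_denominator(100)
    q = 1 - fp
    d = fp.denominator ** 2
    counts = [int(q * q * d * n_units), int(2 * fp * q * d * n_units),
              int(fp * fp * d * n_units)]
    return np.repeat([0, 1, 2], counts)
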