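import numpy as np
import pytest

import svharvest as sv


@pytest.fixture(scope="session")
def ref():
    return sv.simulate_reference([10_000_000], seed=11)


@pytest.fixture(scope="session")
def annotation(ref):
    return sv.simulate_annotation(ref, seed=12)


@pytest.fixture(scope="session")
def cohort(ref, annotation):
    """Small multi-omics cohort shared by the downstream-module tests."""
    spec = sv.CohortSpec(n_samples=23, seed=7)
    return sv.simulate_cohort_omics(
        ref, spec, annotation, seed=7, h2=0.6, n_env=3, n_rep=2,
        rates={"A": 3e-6, "B": 1.5e-6, "INDEL": 1e-6})


def make_del(start, end, sample="s1", caller="X", **kw):
    return sv.SVRecord(chrom="chr1H", start=start, end=end, sv_type="DEL",
                       length=end - start, sample=sample, caller=caller, **kw)


@pytest.fixture
def del_factory():
    return make_del
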