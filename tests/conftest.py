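import numpy as np
import pandas as pd
import pytest

from methcrosstalk.meth_io import MethCohort, SampleMeta


def make_cohort(positions, meth, total, n_case, n_ctrl, chrom="chr1"):
    """Cohort from explicit count matrices (n_sites x n_samples)."""
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    samples = [SampleMeta(f"T{i}", "case") for i in range(n_case)] + [
        SampleMeta(f"N{i}", "control") for i in range(n_ctrl)
    ]
    sites = pd.DataFrame({"chrom": chrom, "pos": np.asarray(positions, dtype=int)})
    return MethCohort(sites, meth, total, samples)


def make_beta_cohort(positions, case_betas, ctrl_betas, depth=100, chrom="chr1"):
    """Cohort whose per-sample betas are exact (counts = beta * depth)."""
    case_betas = np.asarray(case_betas, dtype=float)
    ctrl_betas = np.asarray(ctrl_betas, dtype=float)
    betas = np.hstack([case_betas, ctrl_betas])
    total = np.full(betas.shape, float(depth))
    meth = betas * depth
    return make_cohort(positions, meth, total, case_betas.shape[1], ctrl_betas.shape[1], chrom)


@pytest.fixture
def cohort_factory():
    return make_cohort


@pytest.fixture
def beta_cohort_factory():
    return make_beta_cohort
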