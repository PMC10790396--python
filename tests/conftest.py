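import numpy as np
import pytest

import kipquant as kq


@pytest.fixture
def gaussian_trace_group():
    """Eight concordant noiseless Gaussian transitions of one peptide."""
    areas = np.array([[10.0, 20, 30, 40, 50, 60, 70, 80]])
    spec = kq.ChromSpec(
        n_peptides=1,
        transitions_per_peptide=8,
        apex_rt=[10.0],
        true_transition_areas=areas,
        noise_sd=0.0,
        seed=0,
    )
    traces, truth = kq.gen_chromatograms(spec)
    return traces, truth


@pytest.fixture
def pdx_cohort():
    """Synthetic basal-vs-luminal cohort at the study's conditions."""
    spec = kq.CohortSpec(
        n_basal=8, n_luminal=8, n_kinases=100, n_differential=36,
        log2_effect=2.0, n_up_basal=13, technical_cv=0.10,
        technical_replicates=2, seed=11,
    )
    matrix, replicate_map, truth = kq.gen_cohort_matrix(spec)
    return matrix, replicate_map, truth
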