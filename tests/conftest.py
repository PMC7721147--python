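import logging

import pandas as pd
import pytest

from natalaxis import syndata, trajectories as traj

logging.getLogger("natalaxis").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def imaging_cohort():
    """Small term+preterm cohort with planted axis and group effects."""
    table, truth = syndata.generate_imaging_cohort(n_term=60, n_preterm=20, seed=11)
    return table, truth


@pytest.fixture(scope="session")
def atlas():
    """16-specimen atlas, 80 genes with 10+10 planted, preprocessed."""
    expr, truth = syndata.generate_expression_atlas(
        n_specimens=16, n_genes=80, n_planted_pos=10, n_planted_neg=10, seed=21)
    pre = traj.preprocess_expression(expr, min_obs=10)
    return pre, truth


@pytest.fixture(scope="session")
def universe_truth():
    """Large gene universe (no fits needed) for catalog / ORA tests."""
    _, truth = syndata.generate_expression_atlas(
        n_specimens=4, n_genes=300, n_planted_pos=30, n_planted_neg=30, seed=31)
    return truth


@pytest.fixture(scope="session")
def atlas_fits(atlas):
    """Nonlinear+linear trajectory fits for every atlas gene (shared, slow)."""
    pre, truth = atlas
    fits = traj.fit_all_genes(pre, fit_linear=True)
    return fits


@pytest.fixture(scope="session")
def atlas_residuals(atlas, atlas_fits):
    pre, _ = atlas
    return traj.age_corrected_expression(atlas_fits, pre)


@pytest.fixture(scope="session")
def axis_scores(atlas):
    _, truth = atlas
    return pd.Series(truth.axis_region_scores)
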