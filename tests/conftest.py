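import numpy as np
import pandas as pd
import pytest

from mqtrans.synthetic import (
    TruthSpec,
    build_program,
    generate_cohort,
    gene_feature_id,
    reference_config,
    tf_feature_id,
)


@pytest.fixture(scope="session")
def reference():
    """The documented reference program/spec pair."""
    return reference_config()


@pytest.fixture(scope="session")
def small_config():
    """A light-weight program for fast end-to-end tests: 20 TFs (4 shifted),
    40 genes (8 dark / 8 bright / 8 passenger / 16 null)."""
    spec = TruthSpec(
        n_shifted_tf=4, n_dark=8, n_bright=8, n_passenger=8, n_null=16
    )
    program = build_program(spec, n_tf=20, program_seed=0)
    return program, spec


@pytest.fixture(scope="session")
def small_cohort(small_config):
    program, spec = small_config
    matrix, annotations, truth = generate_cohort(
        program, spec, n_primary=80, n_metastatic=20, seed=7
    )
    return matrix, annotations, truth


def tf_ids(n):
    return [tf_feature_id(i) for i in range(n)]


def gene_ids(n):
    return [gene_feature_id(i) for i in range(n)]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
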