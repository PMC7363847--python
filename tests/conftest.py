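"""Shared fixtures: synthetic standards and trained classifiers.

The heavier artifacts (the five-replicate ensemble on the canned
five-standard fixture) are session-scoped so that the end-to-end tests
share one training run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cellcognize as cc
from cellcognize.fcm import LOG10, PARAMETERS


@pytest.fixture
def filter_spec():
    return cc.FilterSpec()


@pytest.fixture
def raw_table():
    """Four in-bounds raw events over all seven parameters."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.uniform(200, 5000, size=(4, 7)), columns=list(PARAMETERS)
    )
    return cc.EventTable(data=data, scale="raw")


def log_events(values: np.ndarray, **kw) -> cc.EventTable:
    return cc.EventTable(
        data=pd.DataFrame(values, columns=list(PARAMETERS)), scale=LOG10, **kw
    )


@pytest.fixture
def two_separated_standards(filter_spec):
    """Two synthetic standards 8 pooled SD apart, 2000 events each."""
    sd = 0.15
    c1 = np.full(7, 4.0)
    c2 = c1.copy()
    c2[0] += 8 * sd
    a = cc.generate_standard(
        cc.SyntheticStandardSpec("A", c1, sd, 2000), seed=11, filter_spec=filter_spec
    )
    b = cc.generate_standard(
        cc.SyntheticStandardSpec("B", c2, sd, 2000), seed=12, filter_spec=filter_spec
    )
    return a, b


@pytest.fixture(scope="session")
def session_filter_spec():
    return cc.FilterSpec()


@pytest.fixture(scope="session")
def trained_two_class(session_filter_spec):
    """A classifier trained on the 8-SD two-standard problem."""
    sd = 0.15
    c1 = np.full(7, 4.0)
    c2 = c1.copy()
    c2[0] += 8 * sd
    a = cc.generate_standard(cc.SyntheticStandardSpec("A", c1, sd, 2000), seed=21)
    b = cc.generate_standard(cc.SyntheticStandardSpec("B", c2, sd, 2000), seed=22)
    assembly = cc.assemble_training_set([a, b], 2000, session_filter_spec, seed=5)
    model = cc.train_classifier(assembly, cc.TrainingConfig(seed=5))
    return model, assembly, (a, b)


@pytest.fixture(scope="session")
def paperlike_ensemble(session_filter_spec):
    """Five-replicate ensemble on the canned five-standard fixture.

    Standards carry 12,000 events so that the training subsample
    (10,000 per standard) leaves held-out material; fresh evaluation
    data are generated separately in the tests.
    """
    specs = cc.paperlike_standards(n_events=12_000)
    standards = [cc.generate_standard(s, seed=100 + i) for i, s in enumerate(specs)]
    ensemble = cc.train_ensemble(
        standards, 10_000, session_filter_spec, cc.TrainingConfig(seed=1),
        n_replicates=5,
    )
    return ensemble, specs


@pytest.fixture(scope="session")
def paperlike_heldout():
    """Freshly generated evaluation events for each canned standard."""
    specs = cc.paperlike_standards(n_events=5_000)
    return [cc.generate_standard(s, seed=900 + i) for i, s in enumerate(specs)]
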