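"""Shared fixtures: seeded synthetic cohorts reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

from gcmli.features import compute_train_features
from gcmli.synth import StimulusProtocol, make_cohort

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

#: master seed for every deterministic test fixture
SEED = 1234


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def wt_cohort(protocol):
    """Default four-archetype wild-type cohort: 24 synapses/class, 10 trains."""
    return make_cohort({"C1": 24, "C2": 24, "C3": 24, "C4": 24}, "WT",
                       protocol, seed=SEED)


@pytest.fixture(scope="session")
def ko_cohort(protocol):
    """Knockout cohort skewed toward C3/C4, as in the knockout experiments."""
    return make_cohort({"C1": 1, "C2": 3, "C3": 12, "C4": 12}, "KO",
                       protocol, seed=SEED + 1_000_003)


def extract_profiles(cohort):
    """(profile matrix of across-train mean charges, true labels, features)."""
    feats = {rec.synapse_id:
             compute_train_features([s.to_recording() for s in rec.sweeps])
             for rec in cohort.synapses}
    X = np.array([feats[rec.synapse_id].mean_charges
                  for rec in cohort.synapses])
    labels = [rec.class_label for rec in cohort.synapses]
    return X, labels, feats


@pytest.fixture(scope="session")
def wt_profiles(wt_cohort):
    return extract_profiles(wt_cohort)


@pytest.fixture(scope="session")
def ko_profiles(ko_cohort):
    return extract_profiles(ko_cohort)
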