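"""Shared fixtures: a small synthetic corpus and a fast trained bundle."""

import pytest

from phycysid.pipeline import train_bundle
from phycysid.simulate import SyntheticSpec, generate_dataset

#: cheap classifier subset used wherever ensemble plumbing (not accuracy)
#: is under test
FAST_MEMBERS = ("LR", "GNB", "RC", "KNN")


@pytest.fixture(scope="session")
def small_corpus():
    """Balanced labeled corpus, small but big enough for 20-fold CV."""
    spec = SyntheticSpec(
        n_per_class={"I1": 30, "I2": 30, "IwI": 30, "II": 30, "NEG": 120},
        seed=11)
    records, truth = generate_dataset(spec)
    return records, truth


@pytest.fixture(scope="session")
def mini_bundle(small_corpus):
    """Both stages trained with four cheap members (threshold 2 of 4)."""
    records, _ = small_corpus
    bundle, tables = train_bundle(
        records, seed=11, specs=FAST_MEMBERS, tf8m_members=FAST_MEMBERS,
        subtype_members=FAST_MEMBERS, vote_threshold=2)
    return bundle, tables
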