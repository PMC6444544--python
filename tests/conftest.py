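"""Shared fixtures: synthetic families and profiles built once per session."""

import pytest

from hsfkit.profile_search import build_profile
from hsfkit.synthetic_data import FamilySpec, generate_family


@pytest.fixture(scope="session")
def clean_family():
    """Noise-free family: 12 members across six subclasses, no decoys."""
    spec = FamilySpec(
        counts={"A1": 2, "A2": 2, "B1": 2, "B2": 2, "C1": 2, "C2": 2},
        substitution_rate=0.0, decoy_count=0, seed=42,
    )
    return generate_family(spec)


@pytest.fixture(scope="session")
def noisy_family():
    """12 planted Hsfs + 100 shuffled decoys at the default mutation rate."""
    spec = FamilySpec(
        counts={"A1": 2, "A2": 2, "B1": 2, "B2": 2, "C1": 2, "C2": 2},
        decoy_count=100, seed=7,
    )
    return generate_family(spec)


@pytest.fixture(scope="session")
def dbd_profile(clean_family):
    return build_profile(
        clean_family.seed_alignment, pseudocount_weight=1.0,
        column_labels=list(clean_family.seed_labels),
    )
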