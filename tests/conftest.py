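"""Shared fixtures: synthetic chip datasets processed to labeled peptides."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from earkit import peptide_io as pio

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")
from earkit.synthetic import SyntheticConfig, generate_dataset, position_effect_config


def assignable_from_chip(chip):
    """Chip table -> labeled peptides with the unassigned band removed."""
    records = pio.records_from_frame(chip)
    labeled = pio.assign_classes(pio.preprocess_records(records))
    return [p for p in labeled if p.label != pio.UNASSIGNED]


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions at n = 4,000 (fixed seed)."""
    chip, truth = generate_dataset(SyntheticConfig(n_peptides=4000, seed=1))
    return chip, truth


@pytest.fixture(scope="session")
def assignable_peptides(default_dataset):
    chip, _ = default_dataset
    return assignable_from_chip(chip)


@pytest.fixture(scope="session")
def truth_by_id(default_dataset):
    _, truth = default_dataset
    return truth.set_index("peptide_id")


@pytest.fixture(scope="session")
def position_effect_peptides():
    """Position-only signal: identical class compositions, swapped positional
    preferences at peptide positions 3 and 9."""
    chip, _ = generate_dataset(position_effect_config(2000, seed=9))
    return assignable_from_chip(chip)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_labeled(sequences, label, start=0):
    net = 20_000.0 if label == "binding" else 50.0
    return [
        pio.LabeledPeptide(f"p{start + i:05d}", seq, label, net)
        for i, seq in enumerate(sequences)
    ]


def toy_separable_peptides(n_per_class=30, seed=0):
    """Poly-Y-ish binders vs poly-E-ish non-binders: linearly separable."""
    rng = np.random.default_rng(seed)
    binders, nonbinders = [], []
    for _ in range(n_per_class):
        b = ["Y"] * 15
        nb = ["E"] * 15
        for pos in rng.choice(15, size=4, replace=False):
            b[pos] = "AGLSTV"[rng.integers(6)]
            nb[pos] = "AGLSTV"[rng.integers(6)]
        binders.append("".join(b))
        nonbinders.append("".join(nb))
    return make_labeled(binders, "binding") + make_labeled(
        nonbinders, "non-binding", start=n_per_class
    )
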