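"""Shared fixtures: small, fast synthetic datasets."""

from __future__ import annotations

import pytest

from vigorspec.synthetic_data import BandSpec, GeneratorConfig, generate_dataset

# One narrow band covering Mn/Fe/Mg/Si lines: fast to render, still realistic.
TINY_BAND = BandSpec("UV", 250.0, 300.0, 0.05)


def tiny_config(**overrides) -> GeneratorConfig:
    """A 16-sample, 6-replicate, single-band config for fast tests."""
    base = dict(
        composition=(
            ("Marandu", "HV", 4),
            ("Paiaguás", "HV", 4),
            ("Marandu", "LV", 4),
            ("Paiaguás", "LV", 4),
        ),
        replicates_per_sample=6,
        bands=(TINY_BAND,),
        seed=11,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Clean (outlier-free) tiny dataset, shared read-only across tests."""
    return generate_dataset(tiny_config())
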