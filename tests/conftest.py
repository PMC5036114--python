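import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import picolib as pl

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> pl.MockCommunitySpec:
    """Four-member community on deliberately large-ish genomes (0.5 Mb) so
    that coordinate collisions between distinct templates are negligible."""
    return pl.build_mock_spec(
        4, (0.30, 0.65), (0.05, 0.5), seed=101, genome_length_range=(450_000, 550_000)
    )


@pytest.fixture(scope="session")
def small_genomes(small_spec) -> dict[str, str]:
    return pl.synthesize_genomes(small_spec, 202)


def make_preset(effective_templates: int, **overrides) -> pl.LibraryPreset:
    """A low-complexity library preset for fast, collision-free round trips."""
    base = dict(
        name="test",
        input_mass=1_000.0,
        atm_dilution=10.0,
        pcr_cycles=12,
        insert_mean=250.0,
        insert_sd=60.0,
        retention=0.1,
        effective_templates=effective_templates,
        error_rate=0.0,
    )
    base.update(overrides)
    return pl.LibraryPreset(**base)


@pytest.fixture(scope="session")
def default_spec() -> pl.MockCommunitySpec:
    return pl.default_mock_spec()


@pytest.fixture(scope="session")
def default_genomes(default_spec) -> dict[str, str]:
    """Synthetic stand-in genomes for the packaged 54-member community."""
    return pl.synthesize_genomes(default_spec, 404)
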