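"""Shared fixtures: deterministic RNG and a small synthetic study bundle."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vitismir import annotate as annot
from vitismir import preprocess as prep
from vitismir import simulate as sim

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced study: 6 hairpins, light background, quick to simulate."""
    return sim.SimulationSpec(
        seed=11,
        genome_length=20_000,
        n_hairpins=6,
        response_plan=(
            "up",
            "down",
            "treatment_only",
            "control_only",
            "unchanged",
            "up",
        ),
        background_reads=3_000,
        contaminants={"rRNA": (2, 300), "tRNA": (2, 80)},
        contaminant_mean_reads=150,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    genome, truth = sim.generate_genome(small_spec)
    libraries = sim.simulate_libraries(small_spec, genome, truth)
    return small_spec, genome, truth, libraries


@pytest.fixture(scope="session")
def small_tag_libraries(small_bundle):
    spec, _, _, libraries = small_bundle
    return {
        label: prep.preprocess_reads(reads, spec.adapter, label)
        for label, reads in libraries.items()
    }


@pytest.fixture(scope="session")
def small_unannotated(small_bundle, small_tag_libraries):
    """Tag -> per-library counts for tags not hitting a contaminant class."""
    _, genome, truth, _ = small_bundle
    index = annot.AnnotationIndex.build(truth.contaminant_sequences(), genome)
    counts: dict[str, dict[str, int]] = {}
    for label, lib in small_tag_libraries.items():
        for tag, c in lib.tags.items():
            counts.setdefault(tag, {})[label] = c
    return {
        tag: c
        for tag, c in counts.items()
        if annot.classify_tag(tag, index) == "unann"
    }
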