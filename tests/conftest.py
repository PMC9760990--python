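import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eboxnet as eb
from eboxnet.dataset import build_dataset, extract_positive_examples, select_top_peaks

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared by read-only tests: genome, planted
    peaks, ground truth, and target sets."""
    spec = eb.SyntheticSpec(chrom_sizes={"chr1": 60_000, "chr2": 40_000},
                            n_peaks=150, seed=7)
    genome = eb.generate_genome(spec)
    peaks, truth = eb.plant_peaks(genome, spec)
    activation, repression = eb.generate_target_sets(spec, 12, 8)
    return {"spec": spec, "genome": genome, "peaks": peaks, "truth": truth,
            "activation": activation, "repression": repression}


@pytest.fixture(scope="session")
def small_dataset(small_study):
    positives = extract_positive_examples(small_study["genome"], small_study["peaks"])
    data, manifest = build_dataset(positives, seed=5)
    return data, manifest


@pytest.fixture(scope="session")
def trained_small(small_dataset):
    """A briefly trained default-geometry CNN for geometry/IO tests."""
    data, _ = small_dataset
    cfg = eb.HyperConfig(architecture="cnn", max_epochs=2, patience=2,
                         learning_rate=5e-3, seed=3)
    return eb.train(eb.build_model(cfg), data, cfg)
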