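"""Shared fixtures: small hand-built systems and seeded synthetic instances."""

import numpy as np
import pytest

from grninfer import (
    ExperimentDesign,
    GroundTruth,
    NetworkModel,
    dataset_to_frame,
    simulate_dataset,
    standardize_dataset,
)

STUDY_TIMES = (0.0, 1.0, 2.0, 4.0, 12.0)


@pytest.fixture(scope="session")
def cascade():
    """Noise-free 3-gene cascade u1 -> g01 -> g02 -> g03 with self-decay."""
    design = ExperimentDesign(("u1",), STUDY_TIMES, 1, 3)
    A = np.array([[-1.0, 0.0, 0.0], [0.8, -0.7, 0.0], [0.0, 1.2, -0.5]])
    B = np.array([[1.0], [0.0], [0.0]])
    truth = GroundTruth(
        NetworkModel(A, B, ["g01", "g02", "g03"], ["u1"]), noise_sd=0.0, seed=0
    )
    sim = simulate_dataset(truth, design, noise_sd=0.0)
    dataset = standardize_dataset(dataset_to_frame(sim), design, truth.model.gene_order)
    return truth, design, dataset


@pytest.fixture(scope="session")
def bench10():
    """Seed-0 instance of the 10-gene / 2-stimulus recovery fixture."""
    from grninfer.benchmark import benchmark_design, make_benchmark_dataset

    design = benchmark_design()
    truth, dataset = make_benchmark_dataset(design, seed=0)
    return truth, design, dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
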