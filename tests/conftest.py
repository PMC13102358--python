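import numpy as np
import pytest

from introscan.demography import DemographicModel, Epoch, load_fixture_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def model_w1():
    """ILa-ELw fixture model 1 (fast shared instance)."""
    return load_fixture_model("ILa-ELw", 1)


@pytest.fixture
def tiny_model():
    """Small hand-built model for structural tests."""
    anc = DemographicModel.ANCESTRAL
    return DemographicModel(
        populations=("A", "B"),
        ancestral_epochs=[
            Epoch(duration=50_000, size_start={anc: 9_000}, size_end={anc: 9_000}),
            Epoch(duration=30_000, size_start={anc: 7_000}, size_end={anc: 7_000}),
        ],
        post_split_epochs=[
            Epoch(
                duration=20_000,
                size_start={"A": 5_000, "B": 8_000},
                size_end={"A": 5_000, "B": 8_000},
                migration={("A", "B"): 1e-6, ("B", "A"): 2e-6},
            ),
            Epoch(
                duration=6_000,
                size_start={"A": 5_000, "B": 8_000},
                size_end={"A": 5_000, "B": 8_000},
            ),
            Epoch(
                duration=4_000,
                size_start={"A": 5_000, "B": 8_000},
                size_end={"A": 2_000, "B": 8_000},
                change_mode="exponential",
                migration={("B", "A"): 5e-6},
            ),
        ],
        divergence_time=30_000,
        name="tiny",
    )


def separable_tensors(n, shape=(2, 16, 32), seed=0):
    """Linearly separable 4-class toy tensors (class-specific constant blocks)."""
    rng = np.random.default_rng(seed)
    x = np.zeros((n, *shape), dtype=np.uint8)
    y = rng.integers(0, 4, n)
    h = shape[1] // 2
    for i, lab in enumerate(y):
        x[i, int(lab) // 2, (int(lab) % 2) * h : (int(lab) % 2) * h + h, :] = 1
    return x, y
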