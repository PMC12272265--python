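import numpy as np
import pytest

from connage.cohort_io import (
    BehaviorMatrix,
    Cohort,
    Connectome,
    RegionAtlas,
    Subject,
    TraitVector,
    rank_normalize_connectome,
)
from connage.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def atlas4() -> RegionAtlas:
    return RegionAtlas(("L_a", "L_b", "R_a", "R_b"))


@pytest.fixture
def tiny_cohort(atlas4) -> Cohort:
    """Two handmade subjects with 4x4 connectomes."""
    rng = np.random.default_rng(42)
    subjects = []
    for i in range(2):
        raw = rng.integers(0, 50, size=(4, 4)).astype(float)
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 0.0)
        conn = rank_normalize_connectome(Connectome(raw, atlas4))
        behav = BehaviorMatrix(rng.uniform(0, 1, size=(5, 3)),
                               ("time_a", "dist", "wind"))
        subjects.append(
            Subject(
                id=f"m{i}",
                age_days=400.0 + 100 * i,
                traits=TraitVector(sex=float(i), diet=0.0, nos2=1.0, apoe=0.5),
                behavior=behav,
                connectome=conn,
                raw_traits={"sex": "MF"[i], "diet": "control",
                            "nos2": "hNOS2", "apoe": "APOE3"},
            )
        )
    return Cohort(subjects, atlas4)


@pytest.fixture(scope="session")
def small_sim():
    """A small but trainable simulated cohort with ground truth."""
    cfg = SimConfig(n_subjects=24, n_regions=8, planted_edge_count=4, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def small_truth(small_sim):
    return small_sim[1]
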