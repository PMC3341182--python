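import numpy as np
import pytest

from radcm import CaseTable, chd_like_preset, simulate


def make_random_table(rng: np.random.Generator, n=20, s=5, k=2) -> CaseTable:
    """Random binary case table with generic names."""
    return CaseTable(
        case_ids=[str(i) for i in range(1, n + 1)],
        symptom_names=[f"sympt_{j}" for j in range(s)],
        syndrome_names=[f"syndr_{j}" for j in range(k)],
        F=rng.integers(0, 2, size=(n, s)),
        L=rng.integers(0, 2, size=(n, k)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_table():
    """3 cases, 2 symptoms, 1 syndrome; hand-checkable."""
    return CaseTable(
        case_ids=["a", "b", "c"],
        symptom_names=["chills", "palpitation"],
        syndrome_names=["blood_stasis"],
        F=[[1, 0], [0, 0], [1, 1]],
        L=[[1], [0], [1]],
    )


@pytest.fixture(scope="session")
def preset_table():
    """One simulated CHD-shaped cohort shared across tests."""
    table, truth = simulate(chd_like_preset(seed=11))
    return table, truth
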