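import numpy as np
import pandas as pd
import pytest

from herit import PedigreeTable, SimulationSpec, simulate_pedigree


def make_family_pedigree() -> PedigreeTable:
    """Hand-built pedigree containing every classical relationship class:
    parent-offspring, full sibs, half sibs (A1 mated to both A2 and A3),
    grandparent-grandchild, avuncular, and unrelated founders."""
    rows = [
        # id, sire, dam, sex, cohort
        ("A1", "0", "0", "M", 1),
        ("A2", "0", "0", "F", 1),
        ("A3", "0", "0", "F", 1),
        ("A4", "0", "0", "M", 1),
        ("A5", "0", "0", "F", 1),
        ("B1", "A1", "A2", "M", 2),
        ("B2", "A1", "A2", "F", 2),
        ("B3", "A1", "A3", "F", 2),
        ("B4", "A4", "A5", "F", 2),
        ("B5", "A4", "A5", "M", 2),
        ("C1", "B1", "B4", "M", 3),
        ("C2", "B1", "B4", "F", 3),
    ]
    return PedigreeTable.from_frame(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "cohort"])
    )


@pytest.fixture(scope="session")
def family_pedigree() -> PedigreeTable:
    return make_family_pedigree()


def random_pedigree(seed: int, max_n: int = 200) -> PedigreeTable:
    """Random multi-generation pedigree capped at max_n individuals."""
    rng = np.random.default_rng(seed)
    spec = SimulationSpec(
        n_founders=int(rng.integers(4, 24)) * 2,
        n_generations=int(rng.integers(2, 5)),
        offspring_per_mating=int(rng.integers(1, 4)),
        n_snps=1,
        seed=seed,
    )
    ped = simulate_pedigree(spec)
    if ped.n > max_n:
        spec = SimulationSpec(n_founders=10, n_generations=3,
                              offspring_per_mating=2, n_snps=1, seed=seed)
        ped = simulate_pedigree(spec)
    return ped
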