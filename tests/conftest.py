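import numpy as np
import pandas as pd
import pytest

from breedkit import BreedTable, GenotypeMatrix, SimulationConfig, simulate_breeds


def genotype_matrix(dosages, ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array (ref=A, alt=G)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = ids or [f"S{i + 1}" for i in range(n)]
    snps = pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": [1000 * (j + 1) for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return GenotypeMatrix(ids, snps, dosages)


def breed_table(ids, labels) -> BreedTable:
    return BreedTable(pd.DataFrame({"ID": list(ids), "breed": list(labels)}))


@pytest.fixture(scope="session")
def three_breed_dataset():
    """Strongly differentiated 3-breed dataset with some missingness."""
    cfg = SimulationConfig(
        n_breeds=3, n_per_breed=10, n_snps=300, fst=0.3, seed=7, missing_rate=0.05
    )
    return simulate_breeds(cfg)
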