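import numpy as np
import pytest

from ddigrade.records import DrugRecord, LabeledPair
from ddigrade.grades import GradeLabel


@pytest.fixture(scope="session")
def drug_records():
    """Hand-built micro drug table: 3 ARVs (one combination), 4 comedications."""
    return [
        DrugRecord("arv1", "Alphavir", "ARV", ("CCO",), "NNRTI"),
        DrugRecord("arv2", "Betavir", "ARV", ("CCN",), "PI"),
        DrugRecord("arv3", "Combovir", "ARV", ("CCO", "CCCN"), "PI"),
        DrugRecord("com1", "Comed-1", "comedication", ("c1ccccc1",)),
        DrugRecord("com2", "Comed-2", "comedication", ("c1ccccc1C",)),
        DrugRecord("com3", "Comed-3", "comedication", ("CC(=O)O",)),
        DrugRecord("com4", "Comed-4", "comedication", ("CCCCO",)),
    ]


@pytest.fixture(scope="session")
def labeled_pairs(drug_records):
    arvs = [d for d in drug_records if d.role == "ARV"]
    comeds = [d for d in drug_records if d.role != "ARV"]
    rng = np.random.default_rng(7)
    pairs = []
    for a in arvs:
        for c in comeds:
            pairs.append(
                LabeledPair(a.drug_id, c.drug_id, GradeLabel(int(rng.integers(4))))
            )
    return pairs


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but learnable synthetic dataset (shared across tests)."""
    from ddigrade.simulate import DatasetConfig, make_benchmark_dataset

    config = DatasetConfig(
        n_arvs=20, n_comedications=25, signal=1.0, seed=11, holdout_arv_count=4
    )
    drugs, pairs, holdout = make_benchmark_dataset(config)
    return config, drugs, pairs, holdout
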