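import pytest

from stereoscreen import packaged_interaction_table, packaged_score_table

# the 12 proteins every isomer passed both selection criteria for
SHARED_TARGETS = [
    "COX2", "Hsp90a", "Hsp90b", "cdc25A", "CDK2", "RagC",
    "CSF1R", "EGFR", "AKR1B1", "JAK3", "MNK2", "p38",
]


@pytest.fixture(scope="session")
def score_table():
    return packaged_score_table()


@pytest.fixture(scope="session")
def interaction_profiles():
    return packaged_interaction_table()


@pytest.fixture(scope="session")
def profile_map(interaction_profiles):
    return {(p.protein, p.ligand): p for p in interaction_profiles}
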