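"""Shared fixtures: toy models built by hand and synthetic databases."""

from pathlib import Path

import pytest

from aakmer.model import ClusterDatabase, KmerFrequencyModel, build_model
from aakmer.sequence import AminoAcidSequence
from aakmer.simulate import SyntheticDbSpec, generate_cluster_db

DATA_DIR = Path(__file__).parent / "data"


def make_db(clusters: dict) -> ClusterDatabase:
    """Build a ClusterDatabase from {cluster_id: [seq, ...]} with
    autogenerated protein ids and first-member representatives."""
    members = {
        cid: [AminoAcidSequence(f"{cid}_p{i}", s) for i, s in enumerate(seqs)]
        for cid, seqs in clusters.items()
    }
    reps = {cid: (m[0].id, f"annotation {cid}") for cid, m in members.items()}
    return ClusterDatabase(clusters=members, representatives=reps)


@pytest.fixture
def toy_db() -> ClusterDatabase:
    return make_db({
        "C1": ["MAAAAK", "MCCCCK"],
        "C2": ["MAAAAMAAAA"],
        "C3": ["WYWYWYWYWY"],
    })


@pytest.fixture
def toy_model(toy_db) -> KmerFrequencyModel:
    return build_model(toy_db, k=5)


@pytest.fixture(scope="session")
def fixture_20x5():
    """20 clusters x 5 proteins of 300 AA (the oracle-equivalence fixture)."""
    spec = SyntheticDbSpec(n_clusters=20, proteins_per_cluster=5,
                           protein_length=300, intra_cluster_identity=0.85, seed=11)
    return generate_cluster_db(spec)


@pytest.fixture(scope="session")
def model_20x5(fixture_20x5) -> KmerFrequencyModel:
    db, _ = fixture_20x5
    return build_model(db, k=5)


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard synthetic database: 50 clusters x 20 proteins,
    300 AA, intra-cluster identity 0.8, fixed seed."""
    return generate_cluster_db(SyntheticDbSpec(seed=0))


@pytest.fixture(scope="session")
def standard_model(standard_fixture) -> KmerFrequencyModel:
    db, _ = standard_fixture
    return build_model(db, k=5)
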