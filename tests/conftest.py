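from pathlib import Path

import numpy as np
import pytest

from s1scape.registry import records_from_iterable
from s1scape.synthetic import FixtureSpec, make_toy_structure


@pytest.fixture(scope="session")
def toy_structure():
    s, truth = make_toy_structure(FixtureSpec(n_residues=70, seed=11))
    return s, truth


@pytest.fixture()
def toy_pdb_file(tmp_path):
    path = tmp_path / "toy.pdb"
    s, truth = make_toy_structure(
        FixtureSpec(n_residues=70, target_rg=12.0, flexible_fraction=0.3, seed=5),
        path=path,
    )
    return path, s, truth


@pytest.fixture(scope="session")
def synthetic_registry_dir(tmp_path_factory):
    """Six toy entries (2 per kingdom) with structure files on disk."""
    tmp = tmp_path_factory.mktemp("structures")
    kingdoms = ["bacteria", "bacteria", "eukaryota", "eukaryota", "archaea", "archaea"]
    rows = []
    for i, kingdom in enumerate(kingdoms):
        pdb_id = f"{i}tst"
        make_toy_structure(
            FixtureSpec(
                n_residues=70,
                target_rg=10.0 + 0.5 * i,
                flexible_fraction=0.1 + 0.02 * i,
                seed=100 + i,
            ),
            path=tmp / f"{pdb_id}.pdb",
        )
        rows.append((pdb_id, "A", 1, 70, kingdom, f"toy{i}"))
    return records_from_iterable(rows), tmp


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
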