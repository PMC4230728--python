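import numpy as np
import pytest

from cago.structure_io import (
    CAlphaStructure,
    Contact,
    ContactMap,
    DomainPartition,
    compute_contact_map,
)
from cago.sbm import build_wt_model


def make_pdb_text(coords, chain="A", resnames=None, skip_ca_for=()):
    """Minimal PDB ATOM records, one CA per residue."""
    lines = []
    serial = 1
    for k, (x, y, z) in enumerate(coords, start=1):
        name = "CB" if k in skip_ca_for else "CA"
        res = (resnames or {}).get(k, "ALA")
        lines.append(
            f"ATOM  {serial:5d}  {name:<3s}{res:>4s} {chain}{k:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def random_compact_chain(n, seed=0, bond=3.8, min_dist=3.6):
    """Self-avoiding centroid-biased chain used as a small test structure."""
    rng = np.random.default_rng(seed)
    xyz = [np.zeros(3)]
    d = rng.standard_normal(3)
    xyz.append(bond * d / np.linalg.norm(d))
    while len(xyz) < n:
        for _ in range(200):
            d = rng.standard_normal(3)
            cand = xyz[-1] + bond * d / np.linalg.norm(d)
            cand += 0.2 * (np.mean(xyz, axis=0) - cand)
            cand = xyz[-1] + bond * (cand - xyz[-1]) / np.linalg.norm(cand - xyz[-1])
            if all(np.linalg.norm(cand - p) >= min_dist for p in xyz[:-1]):
                xyz.append(cand)
                break
        else:
            raise RuntimeError("chain growth failed")
    return np.array(xyz)


@pytest.fixture(scope="session")
def small_structure():
    xyz = random_compact_chain(20, seed=42)
    return CAlphaStructure(np.arange(1, 21), xyz, source="test-chain")


@pytest.fixture(scope="session")
def small_cmap(small_structure):
    return compute_contact_map(small_structure)


@pytest.fixture(scope="session")
def small_topology(small_structure, small_cmap):
    return build_wt_model(small_structure, small_cmap)
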