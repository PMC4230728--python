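"""Synthetic toy proteins and time series with known ground truth.

The generators realize the structural situation the analysis assumes — a
small, marginally stable domain whose termini either are (inserted
topology) or are not (singly-linked topology) constrained by a larger,
more stable domain — as compact self-avoiding bead chains, plus
telegraph-style reaction-coordinate series with planted transitions and
contact-correlation blocks for testing transition detection and foldon
clustering.  Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cago.structure_io import (
    CAlphaStructure,
    Contact,
    ContactMap,
    DomainPartition,
    classify_contacts,
    compute_contact_map,
)
from cago.foldons import ContactFormationMatrix
from cago.thermo import QSeries

BOND_LENGTH = 3.8        # A, virtual C-alpha bond
MIN_NB_DIST = 3.6        # A, self-avoidance floor for non-bonded beads
DEFAULT_COMPACTNESS = 0.9
TARGET_RHO = 1.5         # contacts per residue contract at default compactness
INTERFACE_GAP = 10.0     # A, small-domain centroid offset from the host surface

__all__ = [
    "ToyProteinSpec",
    "make_toy_domain",
    "make_two_domain_protein",
    "make_telegraph_qseries",
]


@dataclass(frozen=True)
class ToyProteinSpec:
    """Two-domain toy protein: a large stable host and a small insert.

    ``stability_ratio`` is the contact-strength ratio eps_small/eps_large;
    ``insertion_point`` (inserted mode) is the host residue after which
    the small domain's sequence is embedded and must be interior to the
    host.
    """

    n_large: int = 36
    n_small: int = 16
    topology_mode: str = "inserted"   # "inserted" | "singly_linked"
    stability_ratio: float = 0.5
    insertion_point: int = 18
    seed: int = 0

    def __post_init__(self):
        if self.n_large < 8 or self.n_small < 8:
            raise ValueError("domain sizes must be >= 8 beads")
        if self.stability_ratio <= 0:
            raise ValueError("stability_ratio must be positive")
        if self.topology_mode not in ("inserted", "singly_linked"):
            raise ValueError("topology_mode must be 'inserted' or 'singly_linked'")
        if not 1 < self.insertion_point < self.n_large:
            raise ValueError("insertion_point must be interior to the large domain")


def _grow_chain(n: int, compactness: float, rng: np.random.Generator,
                n_candidates: int = 48) -> np.ndarray | None:
    """Grow one self-avoiding chain biased toward its own centroid."""
    xyz = np.zeros((n, 3))
    d0 = rng.standard_normal(3)
    xyz[1] = BOND_LENGTH * d0 / np.linalg.norm(d0)
    for k in range(2, n):
        dirs = rng.standard_normal((n_candidates, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        cand = xyz[k - 1][None, :] + BOND_LENGTH * dirs
        # self-avoidance against all beads except the bonded predecessor
        d = np.linalg.norm(cand[:, None, :] - xyz[None, : k - 1, :], axis=2)
        valid = np.flatnonzero(d.min(axis=1) >= MIN_NB_DIST)
        if valid.size == 0:
            return None
        centroid = xyz[:k].mean(axis=0)
        if rng.random() < compactness:
            pick = valid[np.argmin(np.linalg.norm(cand[valid] - centroid, axis=1))]
        else:
            pick = valid[rng.integers(valid.size)]
        xyz[k] = cand[pick]
    return xyz


def make_toy_domain(n: int, compactness: float = DEFAULT_COMPACTNESS,
                    seed: int = 0, max_retries: int = 50,
                    min_rho: float | None = None
                    ) -> tuple[CAlphaStructure, ContactMap]:
    """Compact self-avoiding bead chain with its cutoff contact map.

    Bond length 3.8 A, no non-bonded pair closer than 3.5 A, and at least
    1.5 contacts per residue at the default compactness (retrying with
    derived sub-seeds up to ``max_retries`` times before erroring).
    """
    if n < 8:
        raise ValueError("n must be >= 8")
    if min_rho is None:
        min_rho = TARGET_RHO if compactness >= DEFAULT_COMPACTNESS else 0.0
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        xyz = _grow_chain(n, compactness, rng)
        if xyz is None:
            continue
        structure = CAlphaStructure(np.arange(1, n + 1), xyz,
                                    source=f"toy(n={n},seed={seed})")
        cmap = compute_contact_map(structure)
        if len(cmap) / n >= min_rho:
            return structure, cmap
    raise RuntimeError(
        f"could not reach {min_rho} contacts/residue in {max_retries} attempts "
        f"(n={n}, compactness={compactness}, seed={seed})"
    )


def _rotation_from_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees about any axis perpendicular to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def make_two_domain_protein(spec: ToyProteinSpec
                            ) -> tuple[CAlphaStructure, ContactMap, DomainPartition]:
    """Two-domain toy protein in inserted or singly-linked chain topology.

    The two modes share the same 3-D arrangement (same per-domain
    geometry, same inter-domain placement) and differ only in chain
    connectivity, so intra-domain contact sets coincide and interface
    contact counts agree closely between modes.  Small-domain contact
    strengths are scaled by ``stability_ratio``; interface contacts keep
    strength 1.
    """
    large, _ = make_toy_domain(spec.n_large, seed=spec.seed)
    small, _ = make_toy_domain(spec.n_small, seed=spec.seed + 1)

    lxyz = large.coords
    sxyz = small.coords - small.coords.mean(axis=0)
    centroid = lxyz.mean(axis=0)
    anchor = lxyz[spec.insertion_point - 1]
    d = anchor - centroid
    if np.linalg.norm(d) < 1e-9:
        d = np.array([1.0, 0.0, 0.0])
    d /= np.linalg.norm(d)
    # face the small domain's termini back toward the host insertion site
    term_mid = 0.5 * (sxyz[0] + sxyz[-1])
    if np.linalg.norm(term_mid) > 1e-9:
        sxyz = sxyz @ _rotation_from_to(term_mid / np.linalg.norm(term_mid), -d).T
    offset = float(np.max((lxyz - centroid) @ d))  # host surface along d
    place = centroid + d * (offset + INTERFACE_GAP)
    sxyz = sxyz + place
    # push outward until no steric clash between domains
    for _ in range(40):
        dmin = np.min(np.linalg.norm(lxyz[:, None, :] - sxyz[None, :, :], axis=2))
        if dmin >= MIN_NB_DIST:
            break
        sxyz = sxyz + 0.5 * d

    ip = spec.insertion_point
    nl, ns = spec.n_large, spec.n_small
    if spec.topology_mode == "inserted":
        coords = np.vstack([lxyz[:ip], sxyz, lxyz[ip:]])
        partition = DomainPartition({
            "large": ((1, ip), (ip + ns + 1, nl + ns)),
            "small": ((ip + 1, ip + ns),),
        })
    else:
        coords = np.vstack([lxyz, sxyz])
        partition = DomainPartition({
            "large": ((1, nl),),
            "small": ((nl + 1, nl + ns),),
        })
    structure = CAlphaStructure(
        np.arange(1, nl + ns + 1), coords,
        source=f"toy2dom({spec.topology_mode},seed={spec.seed})",
    )
    cmap = classify_contacts(compute_contact_map(structure), partition)
    scaled = []
    for c in cmap.contacts:
        eps = spec.stability_ratio if c.label == "intra:small" else 1.0
        scaled.append(Contact(c.i, c.j, c.sigma, eps, c.label))
    return structure, ContactMap(tuple(scaled), cmap.n_residues), partition


def make_telegraph_qseries(n_frames: int, switch_rate: float = 0.01,
                           noise: float = 0.02, planted_blocks: int = 3,
                           seed: int = 0, block_size: int = 12,
                           coupling: float = 0.95):
    """Two-state telegraph Q series with planted transitions and
    block-correlated contact columns.

    Block 0's latent telegraph drives Q (levels 0.1 / 0.9 plus Gaussian
    noise, clipped to [0, 1]); every block has its own independent latent
    and each of its ``block_size`` contact columns copies that latent,
    flipped with probability ``1 - coupling`` per frame.  Returns
    ``(QSeries, ContactFormationMatrix, truth)`` where ``truth`` holds
    the planted transition count and block assignment.
    """
    if not 0 < switch_rate < 1 or noise < 0 or not 0.5 < coupling <= 1:
        raise ValueError("invalid telegraph parameters")
    rng = np.random.default_rng(seed)
    latents = np.empty((planted_blocks, n_frames), dtype=np.uint8)
    for b in range(planted_blocks):
        flips = rng.random(n_frames) < switch_rate
        flips[0] = False
        state = (np.cumsum(flips) + (0 if b else 0)) % 2
        latents[b] = state
    s = latents[0]
    q = 0.1 + 0.8 * s + noise * rng.standard_normal(n_frames)
    q = np.clip(q, 0.0, 1.0)

    cols = []
    block_of = []
    pairs = []
    for b in range(planted_blocks):
        for k in range(block_size):
            flip = rng.random(n_frames) < (1.0 - coupling)
            cols.append(latents[b] ^ flip.astype(np.uint8))
            block_of.append(b)
            base = b * (block_size + 10) + 1
            pairs.append((base + k, base + k + 4))
    matrix = np.stack(cols, axis=1)
    constant = matrix.min(axis=0) == matrix.max(axis=0)
    fm = ContactFormationMatrix(matrix, np.array(pairs, dtype=int), constant)
    truth = {
        "n_transitions": int(np.sum(np.abs(np.diff(s.astype(int))) > 0)),
        "block_of": np.array(block_of, dtype=int),
        "latents": latents,
    }
    return QSeries(q), fm, truth
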