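"""C-alpha structure-based (Go) potentials and their engineered variants.

The wild-type topology encodes the native structure: harmonic bonds and
angles and a periodic dihedral term take their minima at the native
geometry, each native contact is a 10-12 Lennard-Jones-type well of depth
epsilon at the native distance sigma, and all other pairs repel with an
excluded-volume r^-12 term.  Variants:

* ``delete_interface`` removes the contacts of one inter-domain interface
  and rescales the surviving contacts of every affected residue so that
  its total contact stabilization is conserved;
* ``circular_permute`` rewires chain connectivity (old termini joined by
  a glycine-like linker, new termini cut elsewhere) while preserving the
  native contact set;
* ``build_dual_model`` adds closed-state-specific contacts from a second
  conformation, producing a model with both open and closed basins.

Reduced units throughout: epsilon_0 = 1, k_B = 1, lengths in Angstrom,
uniform bead mass 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from cago.structure_io import (
    CAlphaStructure,
    Contact,
    ContactMap,
    compute_contact_map,
)

# standard C-alpha Go parameterization (reduced units)
K_BOND = 100.0     # epsilon_0 / A^2, V = k (r - r0)^2
K_ANGLE = 20.0     # epsilon_0 / rad^2, V = k (theta - theta0)^2
K_DIHEDRAL = 1.0   # epsilon_0
SIGMA_NN = 4.0     # A, excluded-volume diameter
EPS_NN = 1.0       # epsilon_0
RCUT_NN = 8.0      # A, excluded-volume truncation (potential shifted to 0)
NN_MIN_SEP = 3     # repulsion applies to pairs separated by >= 3 bonds

LINKER_SPACING = 4.0  # A per linker bond in circular permutants

__all__ = [
    "SBMTopology",
    "build_wt_model",
    "delete_interface",
    "circular_permute",
    "build_dual_model",
    "tune_closed_strength",
]


@dataclass(frozen=True)
class SBMTopology:
    """Full Go-model potential for one chain.

    Index arrays are 0-based for the force kernels; the ``contacts``
    ContactMap keeps the public 1-based view with labels.
    """

    n_beads: int
    bond_idx: np.ndarray       # (nb, 2) int
    bond_r0: np.ndarray        # (nb,)
    angle_idx: np.ndarray      # (na, 3) int
    angle_theta0: np.ndarray   # (na,)
    dih_idx: np.ndarray        # (nd, 4) int
    dih_phi0: np.ndarray       # (nd,)
    contacts: ContactMap
    native_coords: np.ndarray  # (n, 3)
    k_bond: float = K_BOND
    k_angle: float = K_ANGLE
    k_dih: float = K_DIHEDRAL
    sigma_nn: float = SIGMA_NN
    eps_nn: float = EPS_NN
    rcut_nn: float = RCUT_NN
    masses: np.ndarray | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        if self.masses is None:
            object.__setattr__(self, "masses", np.ones(self.n_beads))
        if self.contacts.n_residues != self.n_beads:
            raise ValueError("contact map size does not match bead count")

    # -- kernel-facing views ------------------------------------------------

    def contact_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """0-based pair indices, sigmas and epsilons of the native contacts."""
        pairs = self.contacts.pairs()
        return pairs - 1, self.contacts.sigmas(), self.contacts.epsilons()

    def nn_exclusion_mask(self) -> np.ndarray:
        """(n, n) boolean mask, True where the excluded-volume repulsion
        acts: pairs separated by >= NN_MIN_SEP bonds that are not native
        open-state contacts.

        Closed-specific contacts of a dual-basin model keep their
        repulsion (their own 10-12 well core is negligible against it at
        open-state distances), so the dual potential decomposes exactly
        into the open potential plus the added closed wells."""
        n = self.n_beads
        idx = np.arange(n)
        mask = (idx[None, :] - idx[:, None]) >= NN_MIN_SEP
        for c in self.contacts.contacts:
            if c.label != "closed-specific":
                mask[c.i - 1, c.j - 1] = False
        return mask

    def with_contacts(self, cmap: ContactMap, note: str) -> "SBMTopology":
        return replace(self, contacts=cmap, provenance=self.provenance + (note,))

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "n_beads": self.n_beads,
            "beads": {"masses": self.masses.tolist(),
                      "native_coords": self.native_coords.tolist()},
            "bonds": {"idx": self.bond_idx.tolist(), "r0": self.bond_r0.tolist(),
                      "k": self.k_bond},
            "angles": {"idx": self.angle_idx.tolist(),
                       "theta0": self.angle_theta0.tolist(), "k": self.k_angle},
            "dihedrals": {"idx": self.dih_idx.tolist(),
                          "phi0": self.dih_phi0.tolist(), "k": self.k_dih},
            "contacts": [[c.i, c.j, c.sigma, c.epsilon, c.label]
                         for c in self.contacts.contacts],
            "excluded_volume": {"sigma_nn": self.sigma_nn, "epsilon_nn": self.eps_nn,
                                "rcut": self.rcut_nn},
            "provenance": list(self.provenance),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SBMTopology":
        d = json.loads(text)
        contacts = ContactMap(
            tuple(Contact(i, j, s, e, lab) for i, j, s, e, lab in d["contacts"]),
            d["n_beads"],
        )
        return cls(
            n_beads=d["n_beads"],
            bond_idx=np.asarray(d["bonds"]["idx"], dtype=int).reshape(-1, 2),
            bond_r0=np.asarray(d["bonds"]["r0"], dtype=float),
            angle_idx=np.asarray(d["angles"]["idx"], dtype=int).reshape(-1, 3),
            angle_theta0=np.asarray(d["angles"]["theta0"], dtype=float),
            dih_idx=np.asarray(d["dihedrals"]["idx"], dtype=int).reshape(-1, 4),
            dih_phi0=np.asarray(d["dihedrals"]["phi0"], dtype=float),
            contacts=contacts,
            native_coords=np.asarray(d["beads"]["native_coords"], dtype=float),
            k_bond=d["bonds"]["k"],
            k_angle=d["angles"]["k"],
            k_dih=d["dihedrals"]["k"],
            sigma_nn=d["excluded_volume"]["sigma_nn"],
            eps_nn=d["excluded_volume"]["epsilon_nn"],
            rcut_nn=d["excluded_volume"]["rcut"],
            masses=np.asarray(d["beads"]["masses"], dtype=float),
            provenance=tuple(d["provenance"]),
        )


def _angles(coords: np.ndarray, triples: np.ndarray) -> np.ndarray:
    a = coords[triples[:, 0]] - coords[triples[:, 1]]
    b = coords[triples[:, 2]] - coords[triples[:, 1]]
    cosang = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedrals(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    b1 = coords[quads[:, 1]] - coords[quads[:, 0]]
    b2 = coords[quads[:, 2]] - coords[quads[:, 1]]
    b3 = coords[quads[:, 3]] - coords[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    return np.arctan2(y, x)


def build_wt_model(structure: CAlphaStructure, cmap: ContactMap) -> SBMTopology:
    """Go topology whose bonded minima and contact wells sit exactly at the
    input native geometry; at the native coordinates the potential equals
    minus the summed contact strengths."""
    n = len(structure)
    if cmap.n_residues != n:
        raise ValueError(
            f"contact map is for {cmap.n_residues} residues, structure has {n}"
        )
    xyz = structure.coords
    bond_idx = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    bond_r0 = np.linalg.norm(xyz[1:] - xyz[:-1], axis=1)
    angle_idx = np.column_stack([np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)])
    dih_idx = np.column_stack([np.arange(n - 3), np.arange(1, n - 2),
                               np.arange(2, n - 1), np.arange(3, n)])
    return SBMTopology(
        n_beads=n,
        bond_idx=bond_idx,
        bond_r0=bond_r0,
        angle_idx=angle_idx,
        angle_theta0=_angles(xyz, angle_idx),
        dih_idx=dih_idx,
        dih_phi0=_dihedrals(xyz, dih_idx),
        contacts=cmap,
        native_coords=xyz.copy(),
        provenance=(f"built from {structure.source or 'structure'} with "
                    f"{len(cmap)} contacts",),
    )


def _residue_eps_sums(cmap: ContactMap) -> dict[int, float]:
    sums: dict[int, float] = {}
    for c in cmap.contacts:
        sums[c.i] = sums.get(c.i, 0.0) + c.epsilon
        sums[c.j] = sums.get(c.j, 0.0) + c.epsilon
    return sums


def delete_interface(
    topo: SBMTopology,
    interface_label: str,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> SBMTopology:
    """Remove one interface's contacts, conserving per-residue stabilization.

    Every residue that loses contacts keeps its wild-type total contact
    strength: the surviving contacts incident to affected residues are
    rescaled by iterative proportional fitting (multiplier sqrt(f_i f_j)
    per pass, f = WT sum / current sum for affected endpoints, 1
    otherwise) until all affected-residue sums match the WT sums.
    Residues whose only contacts were interface contacts are reported in
    the provenance (their stabilization cannot be preserved).
    """
    labels = topo.contacts.labels()
    if interface_label not in labels:
        present = sorted({l for l in labels if l})
        raise ValueError(
            f"no contacts labelled {interface_label!r}; labels present: {present}"
        )
    wt_sums = _residue_eps_sums(topo.contacts)
    kept = [c for c in topo.contacts.contacts if c.label != interface_label]
    deleted = [c for c in topo.contacts.contacts if c.label == interface_label]
    affected = sorted({r for c in deleted for r in (c.i, c.j)})

    eps = np.array([c.epsilon for c in kept])
    incident: dict[int, list[int]] = {r: [] for r in affected}
    for k, c in enumerate(kept):
        for r in (c.i, c.j):
            if r in incident:
                incident[r].append(k)

    orphans = [r for r in affected if not incident[r]]
    constrained = [r for r in affected if incident[r]]

    worst = 0.0
    for _ in range(max_iter):
        factors = {}
        worst = 0.0
        for r in constrained:
            cur = eps[incident[r]].sum()
            factors[r] = wt_sums[r] / cur
            worst = max(worst, abs(cur - wt_sums[r]))
        if worst < tol:
            break
        for k, c in enumerate(kept):
            fi = factors.get(c.i, 1.0)
            fj = factors.get(c.j, 1.0)
            if fi != 1.0 or fj != 1.0:
                eps[k] *= np.sqrt(fi * fj)
    unresolved = worst >= 1e-6

    new_contacts = tuple(replace(c, epsilon=float(e)) for c, e in zip(kept, eps))
    notes = [
        f"deleted {len(deleted)} contacts labelled {interface_label!r}; "
        f"rescaled contacts of {len(constrained)} affected residues"
    ]
    if orphans:
        notes.append(
            "warning: residues with no remaining contacts after interface "
            f"deletion (stabilization not preserved): {orphans}"
        )
    if unresolved:
        notes.append(
            "warning: per-residue sum constraints could not all be met "
            f"(worst residual {worst:.3g}); the constraint system is "
            "over-determined for this interface geometry"
        )
    out = topo.with_contacts(ContactMap(new_contacts, topo.n_beads), notes[0])
    if len(notes) > 1:
        out = replace(out, provenance=out.provenance + tuple(notes[1:]))
    return out


def _linker_positions(a: np.ndarray, b: np.ndarray, n_linker: int,
                      bulge_dir: np.ndarray) -> np.ndarray:
    """Positions of n_linker beads bridging a -> b.

    If the gap accommodates LINKER_SPACING bonds, beads go on the straight
    segment; a too-short gap instead uses a circular arc of total length
    (n_linker + 1) * LINKER_SPACING bulging along ``bulge_dir``, keeping
    near-native linker bond lengths.
    """
    if n_linker == 0:
        return np.empty((0, 3))
    gap = float(np.linalg.norm(b - a))
    need = (n_linker + 1) * LINKER_SPACING
    ts = np.arange(1, n_linker + 1) / (n_linker + 1)
    if gap >= need:
        return a[None, :] + ts[:, None] * (b - a)[None, :]
    # arc: chord gap, arc length `need`; solve sin(t/2)/(t/2) = gap/need
    from scipy.optimize import brentq

    ratio = max(gap / need, 1e-6)
    f = lambda t: np.sin(t / 2.0) / (t / 2.0) - ratio
    theta = brentq(f, 1e-9, 2.0 * np.pi - 1e-9)
    radius = need / theta
    chord = b - a
    u = chord / gap
    w = bulge_dir - np.dot(bulge_dir, u) * u
    if np.linalg.norm(w) < 1e-9:  # bulge direction parallel to chord
        w = np.cross(u, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(w) < 1e-9:
            w = np.cross(u, np.array([0.0, 1.0, 0.0]))
    w = w / np.linalg.norm(w)
    mid = 0.5 * (a + b)
    center = mid - w * radius * np.cos(theta / 2.0)
    # angles of a and b about the center in the (u, w) plane
    phi = theta * ts - theta / 2.0
    return center[None, :] + radius * (
        np.sin(phi)[:, None] * u[None, :] + np.cos(phi)[:, None] * w[None, :]
    )


def circular_permute(
    structure: CAlphaStructure,
    cmap: ContactMap,
    cut_after: int,
    linker_length: int = 4,
) -> tuple[CAlphaStructure, ContactMap, dict[int, int]]:
    """Circularly permute a chain: join the old termini through
    ``linker_length`` linker beads and cut after ``cut_after``.

    New chain order: old residues cut_after+1..N, linker beads, old
    residues 1..cut_after.  Every native contact survives with identical
    sigma and epsilon under the returned old->new index bijection; linker
    beads carry bonded terms only.
    """
    n = len(structure)
    if not 1 <= cut_after <= n:
        raise ValueError(f"cut_after must be in [1, {n}]")
    if linker_length < 0:
        raise ValueError("linker_length must be >= 0")
    if cut_after == n:
        if linker_length != 0:
            raise ValueError("cut_after = N is the identity permutation; "
                             "a linker cannot be attached there")
        return structure, cmap, {i: i for i in range(1, n + 1)}

    xyz = structure.coords
    tail = np.arange(cut_after, n)       # 0-based old indices cut_after..N-1
    head = np.arange(0, cut_after)       # 0-based old indices 0..cut_after-1
    centroid = xyz.mean(axis=0)
    a, b = xyz[n - 1], xyz[0]            # old C-terminus -> old N-terminus
    bulge = 0.5 * (a + b) - centroid
    linker = _linker_positions(a, b, linker_length, bulge)
    new_xyz = np.vstack([xyz[tail], linker, xyz[head]])

    index_map = {}
    for old0 in tail:
        index_map[old0 + 1] = int(old0 + 1 - cut_after)
    offset = (n - cut_after) + linker_length
    for old0 in head:
        index_map[old0 + 1] = int(old0 + 1 + offset)

    new_n = n + linker_length
    remapped = []
    for c in cmap.contacts:
        ni, nj = index_map[c.i], index_map[c.j]
        if ni > nj:
            ni, nj = nj, ni
        remapped.append(Contact(ni, nj, c.sigma, c.epsilon, c.label))
    remapped.sort(key=lambda c: (c.i, c.j))
    new_structure = CAlphaStructure(
        residue_ids=np.arange(1, new_n + 1),
        coords=new_xyz,
        chain_id=structure.chain_id,
        source=(structure.source +
                f" | CP cut_after={cut_after} linker={linker_length}"),
    )
    return new_structure, ContactMap(tuple(remapped), new_n), index_map


def build_dual_model(
    open_topo: SBMTopology,
    closed_structure: CAlphaStructure,
    epsilon_closed: float = 1.0,
    cutoff: float = 8.0,
    min_sep: int = 3,
) -> SBMTopology:
    """Add closed-state-specific contacts to an open-state topology.

    Closed-specific contacts are the pairs present in the closed
    structure's contact map and absent from the open map; each is added
    with sigma measured in the closed structure, strength
    ``epsilon_closed`` and label ``closed-specific``.  Open-state terms
    are untouched, so the dual potential decomposes exactly as
    E_dual(x) = E_open(x) + E_closed_contacts(x).
    """
    if len(closed_structure) != open_topo.n_beads:
        raise ValueError(
            f"closed structure has {len(closed_structure)} residues, "
            f"open topology has {open_topo.n_beads}"
        )
    closed_map = compute_contact_map(closed_structure, cutoff, min_sep)
    open_pairs = {(c.i, c.j) for c in open_topo.contacts.contacts}
    added = [
        Contact(c.i, c.j, c.sigma, epsilon_closed, "closed-specific")
        for c in closed_map.contacts
        if (c.i, c.j) not in open_pairs
    ]
    merged = ContactMap(open_topo.contacts.contacts + tuple(added), open_topo.n_beads)
    return open_topo.with_contacts(
        merged,
        f"dual-basin model: added {len(added)} closed-specific contacts "
        f"(epsilon_closed={epsilon_closed})",
    )


def _closed_scaled(dual_topo: SBMTopology, scale: float) -> SBMTopology:
    scaled = tuple(
        replace(c, epsilon=c.epsilon * scale) if c.label == "closed-specific" else c
        for c in dual_topo.contacts.contacts
    )
    return dual_topo.with_contacts(
        ContactMap(scaled, dual_topo.n_beads), f"closed contacts scaled x{scale:g}"
    )


def tune_closed_strength(
    dual_topo: SBMTopology,
    T: float,
    seed: int,
    grid: tuple[float, ...] = (0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0),
    n_steps: int = 200_000,
    dt: float = 0.003,
    friction: float = 1.0,
    save_every: int = 100,
    min_occupancy: float = 0.10,
) -> float:
    """Smallest closed-contact strength scale populating both basins.

    The grid is in multiples of the mean open-state contact strength.  A
    short simulation at each scale (ascending) measures the occupancy of
    the open (Q_closed < 0.3) and closed (Q_closed > 0.7) basins; the
    first scale giving both >= ``min_occupancy`` is returned.
    """
    from cago.dynamics import run_langevin
    from cago.thermo import compute_q

    closed_idx = dual_topo.contacts.indices_with_label("closed-specific")
    if len(closed_idx) == 0:
        raise ValueError("dual topology has no closed-specific contacts")
    open_eps = [c.epsilon for c in dual_topo.contacts.contacts
                if c.label != "closed-specific"]
    mean_open = float(np.mean(open_eps))
    occupancies = {}
    for scale in grid:
        topo_s = _closed_scaled(dual_topo, scale * mean_open)
        traj = run_langevin(topo_s, T=T, n_steps=n_steps, dt=dt,
                            friction=friction, seed=seed, save_every=save_every)
        closed_contacts = [topo_s.contacts.contacts[k] for k in closed_idx]
        q = compute_q(traj.frames, closed_contacts).values
        occ_open = float(np.mean(q < 0.3))
        occ_closed = float(np.mean(q > 0.7))
        occupancies[scale] = (occ_open, occ_closed)
        if occ_open >= min_occupancy and occ_closed >= min_occupancy:
            return float(scale)
    raise RuntimeError(
        "no scale in the grid populates both basins; "
        f"(open, closed) occupancies per scale: {occupancies}"
    )
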