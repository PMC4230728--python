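"""Structures, contact maps and domain partitions.

The geometric ground truth of a C-alpha Go model is a one-bead-per-residue
structure; the energetic ground truth is its native contact map.  This
module reads C-alpha coordinates from PDB text, computes or loads contact
maps, and labels contacts by the domain partition (intra-domain,
inter-domain interface, or outside all domains).

Conventions: residues are numbered 1..N after renumbering, intervals are
1-based and inclusive, contact pairs are stored with i < j, and the
default distance criterion is a C-alpha cutoff of 8.0 A with a minimum
sequence separation of 3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

DEFAULT_CUTOFF = 8.0
DEFAULT_MIN_SEP = 3

__all__ = [
    "CAlphaStructure",
    "DomainPartition",
    "Contact",
    "ContactMap",
    "read_calpha_structure",
    "compute_contact_map",
    "load_contact_list",
    "write_contact_list",
    "classify_contacts",
]


@dataclass(frozen=True)
class CAlphaStructure:
    """One bead per residue with 3-D coordinates in Angstrom.

    ``residue_ids`` are 1..N (gap-free, strictly increasing); ``source``
    records provenance free-text such as ``"4AKE:A"``.
    """

    residue_ids: np.ndarray
    coords: np.ndarray
    chain_id: str = "A"
    source: str = ""

    def __post_init__(self):
        rid = np.asarray(self.residue_ids, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "residue_ids", rid)
        object.__setattr__(self, "coords", xyz)
        if rid.ndim != 1 or xyz.shape != (rid.size, 3):
            raise ValueError("residue_ids and coords shapes are inconsistent")
        if rid.size < 4:
            raise ValueError("structure must have at least 4 residues")
        if not np.array_equal(rid, np.arange(1, rid.size + 1)):
            raise ValueError("residue_ids must be 1..N, gap-free")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return int(self.residue_ids.size)


@dataclass(frozen=True)
class DomainPartition:
    """Map from domain name to sorted, non-overlapping residue intervals.

    A domain is *discontinuous* iff it has two or more intervals; it is
    *inserted* iff its full span lies strictly inside the span of another
    domain (the situation of NMP and LID inside the CORE of adenylate
    kinase).
    """

    domains: dict[str, tuple[tuple[int, int], ...]]

    def __post_init__(self):
        norm: dict[str, tuple[tuple[int, int], ...]] = {}
        for name, ivs in self.domains.items():
            ivs = tuple(sorted((int(a), int(b)) for a, b in ivs))
            for a, b in ivs:
                if a > b or a < 1:
                    raise ValueError(f"bad interval [{a}, {b}] in domain {name!r}")
            for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
                if a1 <= b0:
                    raise ValueError(f"overlapping intervals in domain {name!r}")
            norm[name] = ivs
        seen: dict[int, str] = {}
        for name, ivs in norm.items():
            for a, b in ivs:
                for r in range(a, b + 1):
                    if r in seen:
                        raise ValueError(
                            f"residue {r} in both {seen[r]!r} and {name!r}"
                        )
                    seen[r] = name
        object.__setattr__(self, "domains", norm)
        object.__setattr__(self, "_owner", seen)

    def domain_of(self, residue: int) -> str | None:
        """Domain name covering ``residue``, or None if uncovered."""
        return self._owner.get(int(residue))

    def residues(self, name: str) -> list[int]:
        return [r for a, b in self.domains[name] for r in range(a, b + 1)]

    def span(self, name: str) -> tuple[int, int]:
        ivs = self.domains[name]
        return ivs[0][0], ivs[-1][1]

    def is_discontinuous(self, name: str) -> bool:
        return len(self.domains[name]) >= 2

    def is_inserted(self, name: str) -> bool:
        lo, hi = self.span(name)
        for other in self.domains:
            if other == name:
                continue
            olo, ohi = self.span(other)
            if olo < lo and hi < ohi:
                return True
        return False


@dataclass(frozen=True)
class Contact:
    """A native contact: pair (i < j), native distance sigma (A), strength
    epsilon (reduced energy), and a location label."""

    i: int
    j: int
    sigma: float
    epsilon: float = 1.0
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "i", int(self.i))
        object.__setattr__(self, "j", int(self.j))
        object.__setattr__(self, "sigma", float(self.sigma))
        object.__setattr__(self, "epsilon", float(self.epsilon))
        if not self.i < self.j:
            raise ValueError(f"contact ({self.i}, {self.j}) must have i < j")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class ContactMap:
    """Set of native contacts on a chain of ``n_residues`` beads."""

    contacts: tuple[Contact, ...]
    n_residues: int

    def __post_init__(self):
        contacts = tuple(self.contacts)
        object.__setattr__(self, "contacts", contacts)
        pairs = set()
        for c in contacts:
            if not (1 <= c.i < c.j <= self.n_residues):
                raise ValueError(f"contact ({c.i}, {c.j}) outside [1, {self.n_residues}]")
            if (c.i, c.j) in pairs:
                raise ValueError(f"duplicate contact pair ({c.i}, {c.j})")
            pairs.add((c.i, c.j))

    def __len__(self) -> int:
        return len(self.contacts)

    def pairs(self) -> np.ndarray:
        """(n, 2) integer array of 1-based (i, j) pairs."""
        if not self.contacts:
            return np.empty((0, 2), dtype=int)
        return np.array([(c.i, c.j) for c in self.contacts], dtype=int)

    def sigmas(self) -> np.ndarray:
        return np.array([c.sigma for c in self.contacts], dtype=float)

    def epsilons(self) -> np.ndarray:
        return np.array([c.epsilon for c in self.contacts], dtype=float)

    def labels(self) -> list[str]:
        return [c.label for c in self.contacts]

    def subset(self, label_prefix: str) -> "ContactMap":
        """Contacts whose label starts with ``label_prefix``."""
        kept = tuple(c for c in self.contacts if c.label.startswith(label_prefix))
        return ContactMap(kept, self.n_residues)

    def indices_with_label(self, label_prefix: str) -> np.ndarray:
        return np.array(
            [k for k, c in enumerate(self.contacts) if c.label.startswith(label_prefix)],
            dtype=int,
        )


def read_calpha_structure(pdb_text: str, chain: str) -> CAlphaStructure:
    """Parse C-alpha beads of one chain from PDB-format text.

    Only ATOM/CA records are used; alternate locations resolve to the
    first occurrence; residues renumber sequentially 1..N.  Raises
    ``ValueError`` naming available chains if the chain is missing, or
    naming the residue if a polymer residue lacks a CA atom.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB text")
    model = st[0]
    names = [ch.name for ch in model]
    found = None
    for ch in model:
        if ch.name == chain:
            found = ch
            break
    if found is None:
        raise ValueError(f"chain {chain!r} not found; available chains: {sorted(set(names))}")
    coords = []
    for res in found:
        if res.het_flag != "A":  # ATOM records only
            continue
        ca = None
        for atom in res:
            if atom.name == "CA":
                ca = atom
                break  # first altloc occurrence
        if ca is None:
            raise ValueError(
                f"residue {res.name} {res.seqid.num} in chain {chain!r} has no CA atom"
            )
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if len(coords) < 4:
        raise ValueError(f"chain {chain!r} has only {len(coords)} CA atoms (need >= 4)")
    n = len(coords)
    return CAlphaStructure(
        residue_ids=np.arange(1, n + 1),
        coords=np.asarray(coords, dtype=float),
        chain_id=chain,
        source=f"pdb:{chain}",
    )


def compute_contact_map(
    structure: CAlphaStructure,
    cutoff: float = DEFAULT_CUTOFF,
    min_sep: int = DEFAULT_MIN_SEP,
) -> ContactMap:
    """All residue pairs with j - i >= min_sep and C-alpha distance <= cutoff.

    sigma is the observed distance; epsilon defaults to 1.  This is the
    distance-cutoff stand-in for all-atom contact determination.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1")
    xyz = structure.coords
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")  # 0-based i<j
    contacts = []
    for a, b in sorted(map(tuple, pairs)):
        if b - a >= min_sep:
            d = float(np.linalg.norm(xyz[a] - xyz[b]))
            contacts.append(Contact(a + 1, b + 1, d, 1.0))
    return ContactMap(tuple(contacts), len(structure))


def load_contact_list(text: str, n_residues: int) -> ContactMap:
    """Parse a contact-list TSV: columns i, j, sigma[, epsilon[, label]].

    Lines starting with '#' are comments (the canonical header is
    ``# i j sigma epsilon``).  Pairs are canonically reordered to i < j;
    duplicates (in either order), out-of-range indices and non-positive
    sigma raise ``ValueError`` with the offending row number.
    """
    contacts = []
    pairs = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"row {lineno}: expected at least 3 columns, got {len(fields)}")
        try:
            i, j = int(fields[0]), int(fields[1])
            sigma = float(fields[2])
            eps = float(fields[3]) if len(fields) > 3 else 1.0
        except ValueError as exc:
            raise ValueError(f"row {lineno}: {exc}") from None
        label = fields[4] if len(fields) > 4 else ""
        if i == j:
            raise ValueError(f"row {lineno}: self-contact ({i}, {j})")
        if i > j:
            i, j = j, i
        if not (1 <= i and j <= n_residues):
            raise ValueError(f"row {lineno}: pair ({i}, {j}) outside [1, {n_residues}]")
        if sigma <= 0:
            raise ValueError(f"row {lineno}: non-positive sigma {sigma}")
        if (i, j) in pairs:
            raise ValueError(f"row {lineno}: duplicate pair ({i}, {j})")
        pairs.add((i, j))
        try:
            contacts.append(Contact(i, j, sigma, eps, label))
        except ValueError as exc:
            raise ValueError(f"row {lineno}: {exc}") from None
    return ContactMap(tuple(contacts), n_residues)


def write_contact_list(cmap: ContactMap) -> str:
    """Serialize a ContactMap to the TSV dialect read by load_contact_list."""
    lines = ["# i\tj\tsigma\tepsilon\tlabel"]
    for c in cmap.contacts:
        row = f"{c.i}\t{c.j}\t{c.sigma:.17g}\t{c.epsilon:.17g}"
        if c.label:
            row += f"\t{c.label}"
        lines.append(row)
    return "\n".join(lines) + "\n"


def classify_contacts(cmap: ContactMap, partition: DomainPartition) -> ContactMap:
    """Label contacts intra:<dom>, interface:<domA>-<domB> (names sorted),
    or "none" when either residue lies outside all domains (e.g. linker
    glycines of a circular permutant)."""
    labelled = []
    for c in cmap.contacts:
        da = partition.domain_of(c.i)
        db = partition.domain_of(c.j)
        if da is None or db is None:
            label = "none"
        elif da == db:
            label = f"intra:{da}"
        else:
            a, b = sorted([da, db])
            label = f"interface:{a}-{b}"
        labelled.append(replace(c, label=label))
    return ContactMap(tuple(labelled), cmap.n_residues)
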