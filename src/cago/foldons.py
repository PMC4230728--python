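"""Foldon identification by contact-formation correlation.

Over trajectory frames restricted to folding/unfolding transitions, each
native contact gives a binary formed/broken column; Pearson correlations
between columns are thresholded into a graph whose connected components
are the contact clusters ("foldons" — groups of contacts that form and
break together).  Clusters project onto residues for display on the
structure.  Constant columns (contacts formed or broken throughout, e.g.
intra-helical contacts) carry no correlation signal and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from cago.structure_io import Contact, ContactMap

FORMED_FACTOR = 1.2       # contact formed when r < 1.2 sigma
CORR_THRESHOLD = 0.5
MIN_CLUSTER_SIZE = 10

__all__ = [
    "ContactFormationMatrix", "ContactClusterSet",
    "formation_matrix", "correlation_matrix", "cluster_contacts",
    "project_to_residues",
]


@dataclass(frozen=True)
class ContactFormationMatrix:
    """Binary (frames x contacts) formation matrix over transition frames."""

    matrix: np.ndarray          # (F, C) uint8
    pairs: np.ndarray           # (C, 2) 1-based residue pairs
    constant_columns: np.ndarray  # (C,) bool

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.uint8)
        object.__setattr__(self, "matrix", m)
        if m.shape[1] != len(self.pairs):
            raise ValueError("column count must match contact count")


@dataclass(frozen=True)
class ContactClusterSet:
    """Cluster id per contact (-1 = unclustered) plus the parameters used."""

    labels: np.ndarray          # (C,) int
    pairs: np.ndarray           # (C, 2)
    threshold: float
    min_cluster_size: int

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def _contact_list(contacts) -> list[Contact]:
    if isinstance(contacts, ContactMap):
        return list(contacts.contacts)
    return list(contacts)


def formation_matrix(frames, contacts, segments=None,
                     formed_factor: float = FORMED_FACTOR) -> ContactFormationMatrix:
    """Binary contact-formation matrix over transition frames.

    ``frames`` is an (F, n, 3) stack or a Trajectory; ``segments`` (from
    ``detect_transitions``) restricts frames to the transition intervals
    and is required to be non-empty when given.  A contact is formed in a
    frame when its distance is below ``formed_factor`` times sigma.
    """
    from cago.dynamics import Trajectory

    if isinstance(frames, Trajectory):
        frames = frames.frames
    x = np.asarray(frames, dtype=float)
    if segments is not None:
        if not segments:
            raise ValueError("no transition segments supplied")
        keep = np.concatenate(
            [np.arange(s, e + 1) for s, e, _ in segments]
        )
        x = x[keep]
    cs = _contact_list(contacts)
    if not cs:
        raise ValueError("contact list must be non-empty")
    ii = np.array([c.i - 1 for c in cs])
    jj = np.array([c.j - 1 for c in cs])
    sigma = np.array([c.sigma for c in cs])
    r = np.linalg.norm(x[:, ii, :] - x[:, jj, :], axis=2)
    m = (r < formed_factor * sigma[None, :]).astype(np.uint8)
    constant = (m.min(axis=0) == m.max(axis=0))
    pairs = np.array([(c.i, c.j) for c in cs], dtype=int)
    return ContactFormationMatrix(m, pairs, constant)


def correlation_matrix(m: ContactFormationMatrix) -> np.ndarray:
    """Pearson correlation of contact formation for all contact pairs.

    Constant columns get correlation 0 to every other contact (and are
    thereby excluded from clustering).
    """
    live = ~m.constant_columns
    if live.sum() < 2:
        raise ValueError("need at least 2 non-constant contact columns")
    C = m.matrix.shape[1]
    corr = np.zeros((C, C))
    sub = np.corrcoef(m.matrix[:, live].astype(float), rowvar=False)
    corr[np.ix_(live, live)] = sub
    np.fill_diagonal(corr, 1.0)
    corr[m.constant_columns, :] = 0.0
    corr[:, m.constant_columns] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def cluster_contacts(corr: np.ndarray, threshold: float = CORR_THRESHOLD,
                     min_cluster_size: int = MIN_CLUSTER_SIZE,
                     pairs: np.ndarray | None = None) -> ContactClusterSet:
    """Deterministic contact clustering: connected components of the
    graph with an edge wherever correlation > threshold; components
    smaller than ``min_cluster_size`` are marked unclustered (-1).
    Cluster ids are ordered by their first contact index.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    corr = np.asarray(corr, dtype=float)
    C = corr.shape[0]
    adj = csr_matrix((corr > threshold).astype(np.int8))
    _, comp = connected_components(adj, directed=False)
    labels = np.full(C, -1, dtype=int)
    next_id = 0
    seen: dict[int, int] = {}
    for k in range(C):
        c = comp[k]
        if c in seen:
            labels[k] = seen[c]
            continue
        size = int(np.sum(comp == c))
        if size >= min_cluster_size:
            seen[c] = next_id
            labels[k] = next_id
            next_id += 1
        else:
            seen[c] = -1
    if pairs is None:
        pairs = np.zeros((C, 2), dtype=int)
    return ContactClusterSet(labels, np.asarray(pairs, dtype=int),
                             float(threshold), int(min_cluster_size))


def project_to_residues(clusters: ContactClusterSet):
    """Residue sets per cluster plus a majority assignment.

    A residue belongs to every cluster containing at least one of its
    contacts; residues in several clusters are additionally assigned to
    the cluster holding the majority of their contacts.
    Returns ``(per_cluster, majority)``.
    """
    if clusters.n_clusters == 0:
        raise ValueError("cluster set is empty")
    per_cluster: dict[int, set[int]] = {}
    counts: dict[int, dict[int, int]] = {}
    for (i, j), lab in zip(clusters.pairs, clusters.labels):
        if lab < 0:
            continue
        per_cluster.setdefault(int(lab), set()).update((int(i), int(j)))
        for r in (int(i), int(j)):
            counts.setdefault(r, {})
            counts[r][int(lab)] = counts[r].get(int(lab), 0) + 1
    majority = {
        r: max(sorted(cnt), key=lambda lab: cnt[lab]) for r, cnt in counts.items()
    }
    return per_cluster, majority
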