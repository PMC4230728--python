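"""Structural metrics of the domain-insertion analysis.

Absolute contact order (ACO, the mean sequence separation of contacting
residue pairs), chain length and packing fraction (contacts per residue)
are computed per domain and compared between an inserted domain and the
discontinuous domain that hosts it.  A higher ACO / length / packing
fraction in the discontinuous domain marks the insertion geometry that
stabilizes the insert and promotes cooperative folding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cago.structure_io import Contact, ContactMap, DomainPartition

__all__ = [
    "DomainMetrics",
    "InsertComparison",
    "absolute_contact_order",
    "packing_fraction",
    "domain_metrics",
    "compare_insert_pair",
    "interface_function_flag",
]


@dataclass(frozen=True)
class DomainMetrics:
    name: str
    aco: float
    length: int
    rho: float


@dataclass(frozen=True)
class InsertComparison:
    inserted: DomainMetrics
    discontinuous: DomainMetrics
    aco_higher: bool
    length_higher: bool
    rho_higher: bool
    all_three: bool


def _as_contacts(contacts) -> list[Contact]:
    if isinstance(contacts, ContactMap):
        return list(contacts.contacts)
    return list(contacts)


def absolute_contact_order(contacts) -> float:
    """Mean sequence separation |j - i| over a non-empty contact subset."""
    cs = _as_contacts(contacts)
    if not cs:
        raise ValueError("ACO of an empty contact subset is undefined")
    return float(np.mean([c.j - c.i for c in cs]))


def packing_fraction(contacts, n_residues: int) -> float:
    """Number of contacts per residue (2.0-3.0 is typical at C-alpha level)."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return len(_as_contacts(contacts)) / n_residues


def _intra_contacts(cmap: ContactMap, partition: DomainPartition, name: str) -> list[Contact]:
    """Contacts with BOTH residues inside the named domain's intervals."""
    return [
        c
        for c in cmap.contacts
        if partition.domain_of(c.i) == name and partition.domain_of(c.j) == name
    ]


def domain_metrics(cmap: ContactMap, partition: DomainPartition, name: str) -> DomainMetrics:
    """ACO, chain length and packing fraction for one domain.

    Chain length is the total residue count of the domain's intervals,
    not the span; ACO and rho use only contacts internal to the domain.
    """
    if name not in partition.domains:
        raise KeyError(f"domain {name!r} not in partition")
    intra = _intra_contacts(cmap, partition, name)
    length = sum(b - a + 1 for a, b in partition.domains[name])
    aco = absolute_contact_order(intra) if intra else float("nan")
    return DomainMetrics(name, aco, length, packing_fraction(intra, length))


def compare_insert_pair(
    cmap: ContactMap,
    partition: DomainPartition,
    inserted: str,
    discontinuous: str,
) -> InsertComparison:
    """Compare metrics of an inserted domain (x) against its discontinuous
    host (y); each flag is the strict inequality y > x."""
    if not partition.is_inserted(inserted):
        raise ValueError(f"domain {inserted!r} is not inserted within another domain")
    mi = domain_metrics(cmap, partition, inserted)
    md = domain_metrics(cmap, partition, discontinuous)
    aco_higher = bool(md.aco > mi.aco)
    length_higher = bool(md.length > mi.length)
    rho_higher = bool(md.rho > mi.rho)
    return InsertComparison(
        mi, md, aco_higher, length_higher, rho_higher,
        aco_higher and length_higher and rho_higher,
    )


def interface_function_flag(
    functional_sites: list[set[int]],
    partition: DomainPartition,
    dom_a: str,
    dom_b: str,
    n_residues: int | None = None,
) -> tuple[list[bool], bool]:
    """Flag functional sites spanning two domains.

    A site spans iff it contains at least one residue in each of the two
    named domains; the overall flag is True iff any site spans.
    """
    if not functional_sites:
        raise ValueError("functional_sites must be non-empty")
    res_a = set(partition.residues(dom_a))
    res_b = set(partition.residues(dom_b))
    flags = []
    for site in functional_sites:
        site = set(int(r) for r in site)
        if n_residues is not None:
            bad = [r for r in site if not 1 <= r <= n_residues]
            if bad:
                raise ValueError(f"site residues {sorted(bad)} outside chain [1, {n_residues}]")
        flags.append(bool(site & res_a) and bool(site & res_b))
    return flags, any(flags)
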