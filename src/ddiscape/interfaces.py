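"""Inter-domain contact maps and interface residue sets.

Two residues from different domains are in contact when any heavy atom of
one lies within the contact cutoff (default 4.5 Å, inclusive) of a heavy
atom of the other. All residues participating in at least one contact form
the domain-domain interface; its size L counts both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import DomainInstance, Residue

DEFAULT_CONTACT_CUTOFF = 4.5  # Å, heavy atom to heavy atom, inclusive


@dataclass(frozen=True)
class Contact:
    """A contacting residue pair: ordinals into each domain's residue list."""

    res_a: int
    res_b: int
    min_heavy_distance: float


@dataclass
class DomainInterface:
    """The two interfacial residue sets of a domain pair plus contacts.

    ``side_a``/``side_b`` hold ordinals into the respective domain's residue
    list, ordered by position. ``L`` counts interfacial residues over both
    sides.
    """

    pair_id: str
    domain_a: DomainInstance
    domain_b: DomainInstance
    contacts: list[Contact]
    side_a: list[int] = field(init=False)
    side_b: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.side_a = sorted({c.res_a for c in self.contacts})
        self.side_b = sorted({c.res_b for c in self.contacts})

    @property
    def L(self) -> int:
        return len(self.side_a) + len(self.side_b)

    @property
    def is_empty(self) -> bool:
        return not self.contacts

    @property
    def contact_pairs(self) -> set[tuple[int, int]]:
        return {(c.res_a, c.res_b) for c in self.contacts}

    @property
    def per_residue_contact_counts(self) -> dict[tuple[str, int], int]:
        """Contacts per interfacial residue, keyed by (side, ordinal)."""
        counts: dict[tuple[str, int], int] = {}
        for c in self.contacts:
            counts[("a", c.res_a)] = counts.get(("a", c.res_a), 0) + 1
            counts[("b", c.res_b)] = counts.get(("b", c.res_b), 0) + 1
        return counts

    def residues_of(self, domain: DomainInstance) -> list[Residue]:
        """Interfacial residues belonging to the given domain."""
        if domain is self.domain_a:
            return [self.domain_a.residues[i] for i in self.side_a]
        if domain is self.domain_b:
            return [self.domain_b.residues[i] for i in self.side_b]
        raise ValueError("domain is not part of this interface")

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates of interfacial residues (side a then side b)."""
        coords = []
        for i in self.side_a:
            r = self.domain_a.residues[i]
            if r.ca is not None:
                coords.append(r.ca.coord)
        for i in self.side_b:
            r = self.domain_b.residues[i]
            if r.ca is not None:
                coords.append(r.ca.coord)
        return np.array(coords) if coords else np.empty((0, 3))


def heavy_atom_contacts(
    dom_a: DomainInstance,
    dom_b: DomainInstance,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[Contact]:
    """All residue pairs with a heavy-heavy atom distance ≤ cutoff.

    Uses a k-d tree over domain B's heavy atoms; results are identical to the
    all-pairs double loop (property-tested).
    """
    if not dom_a.residues or not dom_b.residues:
        raise ValueError("cannot compute contacts for an empty domain")
    shared = {id(r) for r in dom_a.residues} & {id(r) for r in dom_b.residues}
    if shared:
        raise ValueError("domains share residues; contacts undefined")

    coords_b, owner_b = [], []
    for j, res in enumerate(dom_b.residues):
        for coord in res.heavy_coords:
            coords_b.append(coord)
            owner_b.append(j)
    if not coords_b:
        return []
    tree = cKDTree(np.array(coords_b))
    owner_b_arr = np.array(owner_b)

    best: dict[tuple[int, int], float] = {}
    for i, res in enumerate(dom_a.residues):
        pts = res.heavy_coords
        if pts.size == 0:
            continue
        neighbor_lists = tree.query_ball_point(pts, cutoff)
        for pt, nbrs in zip(pts, neighbor_lists):
            if not nbrs:
                continue
            d = np.linalg.norm(np.array([tree.data[k] for k in nbrs]) - pt, axis=1)
            for k, dist in zip(nbrs, d):
                key = (i, int(owner_b_arr[k]))
                if dist <= cutoff and dist < best.get(key, np.inf):
                    best[key] = float(dist)
    return [
        Contact(res_a=i, res_b=j, min_heavy_distance=d)
        for (i, j), d in sorted(best.items())
    ]


def build_interface(
    dom_a: DomainInstance,
    dom_b: DomainInstance,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    pair_id: str | None = None,
) -> DomainInterface:
    """Build the domain-domain interface; zero contacts yields an empty
    (flagged) interface, not an error."""
    contacts = heavy_atom_contacts(dom_a, dom_b, cutoff)
    return DomainInterface(
        pair_id=pair_id or f"{dom_a.domain_id}|{dom_b.domain_id}",
        domain_a=dom_a,
        domain_b=dom_b,
        contacts=contacts,
    )


def is_interacting_pair(interface: DomainInterface, min_residues: int = 20) -> bool:
    """Interacting iff at least ``min_residues`` residues participate in
    interfacial contacts (both sides counted)."""
    return interface.L >= min_residues


def interface_planarity(interface: DomainInterface) -> float:
    """RMS deviation of interfacial Cα atoms from their least-squares plane.

    The plane passes through the centroid with normal along the smallest
    principal axis of the Cα cloud; flat interfaces score near 0 Å.
    """
    coords = interface.ca_coords()
    if coords.shape[0] < 3:
        raise ValueError("planarity needs >= 3 interfacial Calpha atoms")
    centered = coords - coords.mean(axis=0)
    # smallest right singular vector = normal of best-fit plane
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    dists = centered @ normal
    return float(np.sqrt(np.mean(dists**2)))
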