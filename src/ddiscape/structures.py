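"""Domain and chain data model.

Structural domains are delineated CATH-style: an entry (PDB id + chain)
carries one or more numbered domains, each composed of one or more sequence
segments. A domain made of a single segment is *continuous*; two or more
segments make it *discontinuous*. Two continuous domains separated only by an
inter-domain linker (no classified domain in between) are *consecutive*.

Residue identity uses author numbering plus insertion code, treated as an
ordered label; every computation works on 0-based ordinal positions within
the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_HYDROGENS = {"H", "D"}

#: three-letter -> one-letter amino-acid codes (standard 20 + common variants)
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


@dataclass(frozen=True)
class Atom:
    """A single atom: name, element and Cartesian coordinate in Å."""

    name: str
    element: str
    coord: np.ndarray
    is_heavy: bool = field(init=False)

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")
        object.__setattr__(self, "coord", coord)
        object.__setattr__(self, "is_heavy", self.element.upper() not in _HYDROGENS)


@dataclass(frozen=True)
class ResidueID:
    """Author residue number plus insertion code; orderable label."""

    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.number}{self.icode}"

    def sort_key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass
class Residue:
    chain_id: str
    seq_index: ResidueID
    aa: str
    atoms: list[Atom]
    ca: Atom | None = None

    def __post_init__(self) -> None:
        if self.ca is not None and self.ca not in self.atoms:
            raise ValueError("ca must be one of the residue's atoms")

    @property
    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.atoms if a.is_heavy]
        return np.array(coords) if coords else np.empty((0, 3))


@dataclass(frozen=True)
class Segment:
    """Inclusive author-numbering range [start, end] on one chain."""

    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, rid: ResidueID) -> bool:
        return self.start <= rid.number <= self.end


@dataclass
class DomainDefinition:
    """CATH-style domain delineation for one chain."""

    entry_id: str
    domain_number: int
    segments: list[Segment]
    fold_label: str
    resolution: float

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("domain definition needs >= 1 segment")
        spans = sorted((s.start, s.end) for s in self.segments)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.entry_id} domain {self.domain_number}: overlapping segments"
                )

    @property
    def domain_id(self) -> str:
        return f"{self.entry_id}.{self.domain_number:02d}"


@dataclass
class DomainInstance:
    """A domain materialized on a chain: its resolved residues and sequence."""

    definition: DomainDefinition
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def domain_id(self) -> str:
        return self.definition.domain_id

    @property
    def fold_label(self) -> str:
        return self.definition.fold_label

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates of residues that have one, (n, 3)."""
        return np.array([r.ca.coord for r in self.residues if r.ca is not None])


@dataclass
class ChainStructure:
    """One protein chain: ordered residues, missing ranges, attached domains."""

    entry_id: str
    residues: list[Residue]
    missing_ranges: list[Segment] = field(default_factory=list)
    domains: list[DomainInstance] = field(default_factory=list)
    resolution: float = float("nan")

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for r in self.residues:
            key = r.seq_index.sort_key()
            if key in seen:
                raise ValueError(f"{self.entry_id}: duplicate residue {r.seq_index}")
            seen.add(key)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ordinal_of(self, rid: ResidueID) -> int:
        for i, r in enumerate(self.residues):
            if r.seq_index == rid:
                return i
        raise KeyError(f"residue {rid} not in chain {self.entry_id}")


def apply_domain_definitions(
    chain: ChainStructure, defs: list[DomainDefinition]
) -> ChainStructure:
    """Attach domain instances to ``chain`` per the given delineations.

    Each instance holds exactly the resolved residues falling inside its
    segments; domains are ordered N→C by the position of their first residue.
    A definition matching zero resolved residues is an error (it names a
    region entirely unresolved in this structure).
    """
    instances = []
    for d in defs:
        members = [
            r for r in chain.residues if any(s.contains(r.seq_index) for s in d.segments)
        ]
        if not members:
            raise ValueError(
                f"domain {d.domain_id}: no resolved residues in its segments"
            )
        instances.append(DomainInstance(definition=d, residues=members))
    order = {id(r): i for i, r in enumerate(chain.residues)}
    instances.sort(key=lambda inst: order[id(inst.residues[0])])
    return replace(chain, domains=instances)


def classify_continuity(domain: DomainInstance) -> str:
    """'continuous' iff the domain is delineated as a single segment."""
    return "continuous" if len(domain.definition.segments) == 1 else "discontinuous"


def _ordinal_span(chain: ChainStructure, domain: DomainInstance) -> tuple[int, int]:
    order = {id(r): i for i, r in enumerate(chain.residues)}
    idx = [order[id(r)] for r in domain.residues]
    return min(idx), max(idx)


def linker_length(
    chain: ChainStructure, dom_a: DomainInstance, dom_b: DomainInstance
) -> int:
    """Number of residues strictly between two continuous domains.

    Counts both resolved linker residues and annotated-missing positions (by
    author numbering) in the gap. Argument order is normalized so the
    N-terminal domain comes first; overlapping domains are an error.
    """
    a0, a1 = _ordinal_span(chain, dom_a)
    b0, b1 = _ordinal_span(chain, dom_b)
    if b0 < a0:
        (a0, a1), (b0, b1) = (b0, b1), (a0, a1)
        dom_a, dom_b = dom_b, dom_a
    if b0 <= a1:
        raise ValueError(
            f"domains {dom_a.domain_id} and {dom_b.domain_id} overlap on the chain"
        )
    resolved_between = b0 - a1 - 1
    # numbering gap beyond the resolved linker counts as missing residues
    last_a = chain.residues[a1].seq_index.number
    first_b = chain.residues[b0].seq_index.number
    numbering_gap = first_b - last_a - 1
    return max(resolved_between, numbering_gap)


def _has_missing_in_linker(
    chain: ChainStructure, dom_a: DomainInstance, dom_b: DomainInstance
) -> bool:
    a0, a1 = _ordinal_span(chain, dom_a)
    b0, b1 = _ordinal_span(chain, dom_b)
    if b0 < a0:
        a1, b0 = b1, a0
    last_a = chain.residues[a1].seq_index.number
    first_b = chain.residues[b0].seq_index.number
    if first_b - last_a - 1 > b0 - a1 - 1:
        return True
    return any(
        s.start > last_a and s.end < first_b for s in chain.missing_ranges
    )


def _intervening_domain(
    chain: ChainStructure, dom_a: DomainInstance, dom_b: DomainInstance
) -> bool:
    a0, a1 = _ordinal_span(chain, dom_a)
    b0, b1 = _ordinal_span(chain, dom_b)
    lo, hi = min(a1, b1), max(a0, b0)
    for other in chain.domains:
        if other is dom_a or other is dom_b:
            continue
        o0, o1 = _ordinal_span(chain, other)
        if o0 > lo and o1 < hi:
            return True
    return False


def is_consecutive_pair(
    chain: ChainStructure,
    dom_a: DomainInstance,
    dom_b: DomainInstance,
    max_linker_when_missing: int = 13,
    apply_cutoff_when_resolved: bool = False,
) -> bool:
    """Are two continuous domains consecutive (separated only by a linker)?

    When the linker contains missing residues, its (numbering-derived) length
    must not exceed ``max_linker_when_missing`` — a strict cut-off chosen from
    the minimum observed domain length, guaranteeing no classified domain
    could hide in the gap. Fully resolved linkers carry no length limit by
    default (``apply_cutoff_when_resolved`` switches the strict reading on).
    """
    if classify_continuity(dom_a) != "continuous" or classify_continuity(dom_b) != "continuous":
        return False
    if _intervening_domain(chain, dom_a, dom_b):
        return False
    n = linker_length(chain, dom_a, dom_b)
    if _has_missing_in_linker(chain, dom_a, dom_b) or apply_cutoff_when_resolved:
        return n <= max_linker_when_missing
    return True


def select_major_segment(
    domain: DomainInstance,
    interface,
    min_length: int = 100,
    min_coverage: float = 0.5,
    min_interface_residues: int = 20,
):
    """Pick the major segment of a discontinuous domain, or reject.

    The longest segment represents the domain iff it (a) has at least
    ``min_length`` residues, (b) covers at least ``min_coverage`` of the
    domain's total length, and (c) contributes at least
    ``min_interface_residues`` residues to the domain-pair interface.
    Returns the ``Segment`` or ``None`` when any rule fails.

    ``interface`` is a ``DomainInterface``; the side belonging to this domain
    is located by residue identity.
    """
    if classify_continuity(domain) != "discontinuous":
        raise ValueError("major-segment rule applies to discontinuous domains only")
    seg_residues: dict[int, list[Residue]] = {}
    for r in domain.residues:
        for si, seg in enumerate(domain.definition.segments):
            if seg.contains(r.seq_index):
                seg_residues.setdefault(si, []).append(r)
                break
    if not seg_residues:
        return None
    longest_i = max(seg_residues, key=lambda i: (len(seg_residues[i]), -i))
    longest = domain.definition.segments[longest_i]
    n_res = len(seg_residues[longest_i])
    if n_res < min_length:
        return None
    if n_res / domain.length < min_coverage:
        return None
    iface_res = interface.residues_of(domain)
    seg_ids = {id(r) for r in seg_residues[longest_i]}
    contributed = sum(1 for r in iface_res if id(r) in seg_ids)
    if contributed < min_interface_residues:
        return None
    return longest
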