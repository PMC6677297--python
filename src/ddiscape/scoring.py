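"""IS-score components: d0/s0 scales, contact overlap, Kabsch, scoring.

The interface similarity score of an alignment between a query interface
(length L_Q, counting both sides) and a template is

    S = (1/L_Q) * max[ sum_i f_i / (1 + d_i^2/d0^2) ]
    IS = (S + s0) / (1 + s0)

where d_i is the Cα-Cα distance of the i-th aligned pair under the optimal
rigid superposition, f_i = (c_i/a_i + c_i/b_i)/2 is the contact overlap at
position i (a_i, b_i: interfacial contact counts of the template and query
residue; c_i: contacts preserved by the mapping), s0 = 0.18 - 0.35/L_Q^0.3,
and d0 depends on the alignment mode. IS reaches exactly 1 for an identical
interface aligned to itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: interface residue key: ("a"|"b", ordinal within that side's domain)
ResKey = tuple[str, int]

D0_FLOOR = 0.5  # Å; the d0 formulas go non-positive for L_Q <= 15


@dataclass(frozen=True)
class ScoringParams:
    mode: str = "non-sequential"  # or "sequential"
    d0_floor: float = D0_FLOOR
    pairing_cutoff_factor: float = 2.0  # assignment cutoff = factor * d0
    max_iterations: int = 50
    convergence_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.mode not in ("sequential", "non-sequential"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")
        if self.d0_floor <= 0:
            raise ValueError("d0_floor must be positive")


def d0(L_Q: int, mode: str = "non-sequential", floor: float = D0_FLOOR) -> float:
    """Distance scale of the score, floored for short interfaces.

    sequential:      1.24 * (L_Q - 15)^(1/3) - 1.8
    non-sequential:  0.70 * (L_Q - 15)^(1/3) - 0.1
    """
    if L_Q < 1:
        raise ValueError("L_Q must be >= 1")
    if L_Q <= 15:
        return floor
    cbrt = (L_Q - 15.0) ** (1.0 / 3.0)
    if mode == "sequential":
        val = 1.24 * cbrt - 1.8
    elif mode == "non-sequential":
        val = 0.7 * cbrt - 0.1
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return max(val, floor)


def s0(L_Q: int) -> float:
    """Length-dependent normalization: 0.18 - 0.35 / L_Q^0.3.

    Positive for the interfaces of interest (L_Q >= 20); guards against the
    non-positive regime of very short interfaces.
    """
    val = 0.18 - 0.35 / L_Q**0.3
    if val <= 0:
        raise ValueError(f"s0 non-positive for L_Q={L_Q}; interface too short")
    return val


def contact_overlap(c_i: int, a_i: int, b_i: int) -> float:
    """f_i = (c_i/a_i + c_i/b_i) / 2, in [0, 1]."""
    if a_i < 1 or b_i < 1:
        raise ValueError("contact counts a_i, b_i must be >= 1")
    if not 0 <= c_i <= min(a_i, b_i):
        raise ValueError("need 0 <= c_i <= min(a_i, b_i)")
    return 0.5 * (c_i / a_i + c_i / b_i)


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ b + translation`` best fits ``a`` (proper rotation,
    det = +1). Degenerate inputs (N < 3 or collinear points) are an error.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coords must be matching (N, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition needs >= 3 paired points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, svals, vt = np.linalg.svd(h)
    if svals[1] < 1e-10 * max(svals[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    moved = (rot @ b.T).T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((a - moved) ** 2, axis=1))))
    return rot, trans, rmsd


@dataclass
class InterfaceAlignment:
    """A one-to-one residue correspondence between two interfaces.

    ``pairs`` maps query residue keys to template residue keys (keys are
    ("a"|"b", side ordinal)). ``domain_pairing`` is "direct" when query side
    a maps onto template side a, "swapped" otherwise.
    """

    query: "DomainInterface"
    template: "DomainInterface"
    pairs: list[tuple[ResKey, ResKey]]
    rotation: np.ndarray
    translation: np.ndarray
    domain_pairing: str = "direct"

    @property
    def N_a(self) -> int:
        return len(self.pairs)


@dataclass
class AlignmentScores:
    S: float
    IS_score: float
    s0: float
    d0: float
    rmsd: float
    f_res: float
    f_con: float
    N_a: int
    L_Q: int
    p_value: float | None = None
    per_pair: list[dict] = field(default_factory=list, repr=False)


def _interface_geometry(interface) -> dict[ResKey, np.ndarray]:
    """Cα coordinate per interfacial residue key; residues lacking Cα are
    skipped (they still count toward L)."""
    coords: dict[ResKey, np.ndarray] = {}
    for i in interface.side_a:
        r = interface.domain_a.residues[i]
        if r.ca is not None:
            coords[("a", i)] = r.ca.coord
    for j in interface.side_b:
        r = interface.domain_b.residues[j]
        if r.ca is not None:
            coords[("b", j)] = r.ca.coord
    return coords


def _contact_sets(interface) -> tuple[set[frozenset], dict[ResKey, int]]:
    """Unordered contact-pair set over residue keys, and per-key counts."""
    pairs = {
        frozenset({("a", c.res_a), ("b", c.res_b)}) for c in interface.contacts
    }
    counts: dict[ResKey, int] = {}
    for c in interface.contacts:
        counts[("a", c.res_a)] = counts.get(("a", c.res_a), 0) + 1
        counts[("b", c.res_b)] = counts.get(("b", c.res_b), 0) + 1
    return pairs, counts


def score_alignment(
    alignment: InterfaceAlignment, params: ScoringParams | None = None
) -> AlignmentScores:
    """Score a correspondence: S, IS-score, RMSD, f_res, f_con.

    Distances d_i are measured under the alignment's stored superposition.
    An empty alignment scores S = 0 and IS = s0/(1+s0), flagged by N_a = 0.
    """
    params = params or ScoringParams()
    query, template = alignment.query, alignment.template
    L_Q = query.L
    d0_val = d0(L_Q, params.mode, params.d0_floor)
    s0_val = s0(L_Q)

    qgeo = _interface_geometry(query)
    tgeo = _interface_geometry(template)
    qcontacts, qcounts = _contact_sets(query)
    tcontacts, tcounts = _contact_sets(template)
    mapping = dict(alignment.pairs)

    if not alignment.pairs:
        return AlignmentScores(
            S=0.0, IS_score=s0_val / (1 + s0_val), s0=s0_val, d0=d0_val,
            rmsd=float("nan"), f_res=0.0, f_con=0.0, N_a=0, L_Q=L_Q,
        )

    rot, trans = alignment.rotation, alignment.translation
    total = 0.0
    sq_sum = 0.0
    per_pair = []
    for qk, tk in alignment.pairs:
        dq = qgeo[qk]
        dt = rot @ tgeo[tk] + trans
        d_i = float(np.linalg.norm(dq - dt))
        # c_i: query contacts of qk whose partner maps onto a template contact
        c_i = 0
        for contact in qcontacts:
            if qk not in contact:
                continue
            (other,) = contact - {qk}
            if other in mapping and frozenset({tk, mapping[other]}) in tcontacts:
                c_i += 1
        a_i = tcounts.get(tk, 0)
        b_i = qcounts.get(qk, 0)
        f_i = contact_overlap(min(c_i, a_i, b_i), a_i, b_i) if a_i and b_i else 0.0
        term = f_i / (1 + (d_i / d0_val) ** 2)
        total += term
        sq_sum += d_i**2
        per_pair.append({"query": qk, "template": tk, "d": d_i,
                         "c": c_i, "a": a_i, "b": b_i, "f": f_i})

    preserved = sum(
        1
        for contact in qcontacts
        if all(k in mapping for k in contact)
        and frozenset({mapping[k] for k in contact}) in tcontacts
    )
    n_a = len(alignment.pairs)
    S = total / L_Q
    return AlignmentScores(
        S=S,
        IS_score=(S + s0_val) / (1 + s0_val),
        s0=s0_val,
        d0=d0_val,
        rmsd=float(np.sqrt(sq_sum / n_a)),
        f_res=n_a / L_Q,
        f_con=preserved / len(qcontacts) if qcontacts else 0.0,
        N_a=n_a,
        L_Q=L_Q,
        per_pair=per_pair,
    )
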