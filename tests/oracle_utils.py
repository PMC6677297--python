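"""Independent oracles used by the test suite.

These deliberately avoid the search machinery of the package: exhaustive
enumeration for interface alignment, dense matrix algebra for graph
reachability, and naive re-implementations of the selection rules. They are
slow and only run on tiny instances.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from ddiscape.interfaces import Contact, DomainInterface
from ddiscape.scoring import d0 as d0_fn, s0 as s0_fn
from ddiscape.structures import (
    Atom,
    DomainDefinition,
    DomainInstance,
    Residue,
    ResidueID,
    Segment,
)


def toy_interface(coords_a, coords_b, contacts, pair_id="toy"):
    """Build a DomainInterface directly from Cα coordinates and a contact
    list [(i, j), ...]; every residue must appear in some contact."""
    coords_a = np.asarray(coords_a, float)
    coords_b = np.asarray(coords_b, float)

    def _domain(coords, entry, number):
        residues = []
        for k, c in enumerate(coords):
            ca = Atom("CA", "C", c)
            residues.append(
                Residue("A", ResidueID(100 * number + k), "A", [ca], ca)
            )
        definition = DomainDefinition(
            entry_id=entry, domain_number=number,
            segments=[Segment("A", 100 * number, 100 * number + len(coords) - 1)],
            fold_label=f"toy/{entry}.{number}", resolution=2.0,
        )
        return DomainInstance(definition=definition, residues=residues)

    dom_a = _domain(coords_a, pair_id, 1)
    dom_b = _domain(coords_b, pair_id, 2)
    clist = [
        Contact(i, j, float(np.linalg.norm(coords_a[i] - coords_b[j])))
        for i, j in contacts
    ]
    return DomainInterface(pair_id=pair_id, domain_a=dom_a, domain_b=dom_b,
                           contacts=clist)


def _batched_kabsch(H):
    """Proper rotations minimizing lsq for a stack of covariance matrices."""
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("...ji,...kj->...ik", Vt, U))
    D = np.zeros_like(H)
    D[..., 0, 0] = 1.0
    D[..., 1, 1] = 1.0
    D[..., 2, 2] = det
    return np.einsum("...ji,...jk,...lk->...il", Vt, D, U)


def exhaustive_best_is(query: DomainInterface, template: DomainInterface) -> float:
    """Maximum IS-score over all full side-respecting bijections, both
    domain pairings, each scored under its own optimal superposition.

    Requires equal side sizes (query a = template side, etc.) and small
    sides (factorial enumeration).
    """
    def side_data(iface):
        ca = np.array([iface.domain_a.residues[i].ca.coord for i in iface.side_a])
        cb = np.array([iface.domain_b.residues[j].ca.coord for j in iface.side_b])
        adj = np.zeros((len(iface.side_a), len(iface.side_b)), bool)
        pos_a = {r: k for k, r in enumerate(iface.side_a)}
        pos_b = {r: k for k, r in enumerate(iface.side_b)}
        for c in iface.contacts:
            adj[pos_a[c.res_a], pos_b[c.res_b]] = True
        return ca, cb, adj

    qa, qb, Qadj = side_data(query)
    L_Q = query.L
    d0v = d0_fn(L_Q, "non-sequential")
    s0v = s0_fn(L_Q)
    ta, tb, Tadj = side_data(template)

    best = 0.0
    for ta_side, tb_side, adj_t in [(ta, tb, Tadj), (tb, ta, Tadj.T)]:
        if len(ta_side) != len(qa) or len(tb_side) != len(qb):
            continue
        best = max(
            best,
            _best_over_bijections(qa, qb, Qadj, ta_side, tb_side, adj_t,
                                  L_Q, d0v),
        )
    return (best + s0v) / (1 + s0v)


def _best_over_bijections(qa, qb, Qadj, ta, tb, Tadj, L_Q, d0v):
    na, nb = len(qa), len(qb)
    perms_a = np.array(list(permutations(range(na))))
    perms_b = np.array(list(permutations(range(nb))))
    P, Qn = len(perms_a), len(perms_b)

    qcen = np.vstack([qa, qb]).mean(axis=0)
    tcen = np.vstack([ta, tb]).mean(axis=0)
    X_a, X_b = qa - qcen, qb - qcen
    TA = (ta - tcen)[perms_a]            # (P, na, 3)
    TB = (tb - tcen)[perms_b]            # (Q, nb, 3)

    H_a = np.einsum("pni,nj->pij", TA, X_a)
    H_b = np.einsum("qni,nj->qij", TB, X_b)
    H = H_a[:, None] + H_b[None, :]      # (P, Q, 3, 3)
    R = _batched_kabsch(H)

    RA = np.einsum("pqij,pnj->pqni", R, TA)
    RB = np.einsum("pqij,qnj->pqni", R, TB)
    da2 = np.sum((X_a[None, None] - RA) ** 2, axis=-1)  # (P, Q, na)
    db2 = np.sum((X_b[None, None] - RB) ** 2, axis=-1)

    # contact preservation: M2[p, q, i, j] = Tadj[perm_a[p][i], perm_b[q][j]]
    M1 = Tadj[perms_a].astype(float)                  # (P, na, nb_t)
    M2 = M1[:, :, perms_b.T]                          # (P, na, nb, Q)
    M2 = np.moveaxis(M2, 3, 1)                        # (P, Q, na, nb)
    Qf = Qadj.astype(float)
    C_a = np.einsum("ij,pqij->pqi", Qf, M2)
    C_b = np.einsum("ij,pqij->pqj", Qf, M2)

    bq_a = Qadj.sum(axis=1).astype(float)             # query contact counts
    bq_b = Qadj.sum(axis=0).astype(float)
    tc_a = Tadj.sum(axis=1).astype(float)             # template counts
    tc_b = Tadj.sum(axis=0).astype(float)
    at_a = tc_a[perms_a][:, None, :]                  # (P, 1, na)
    at_b = tc_b[perms_b][None, :, :]                  # (1, Q, nb)

    C_a = np.minimum(C_a, np.minimum(bq_a[None, None], at_a))
    C_b = np.minimum(C_b, np.minimum(bq_b[None, None], at_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        f_a = 0.5 * (C_a / np.where(at_a > 0, at_a, np.inf)
                     + C_a / bq_a[None, None])
        f_b = 0.5 * (C_b / np.where(at_b > 0, at_b, np.inf)
                     + C_b / bq_b[None, None])
    S = (np.sum(f_a / (1 + da2 / d0v**2), axis=2)
         + np.sum(f_b / (1 + db2 / d0v**2), axis=2)) / L_Q
    return float(S.max())


def tm_gapless_oracle(mobile: np.ndarray, target: np.ndarray) -> float:
    """Lower-bound TM-score: best single gapless threading, scored over the
    threaded pairs only (no refinement, no DP)."""
    from ddiscape.scoring import kabsch_superpose

    a, b = np.asarray(target, float), np.asarray(mobile, float)
    L_t = len(a)
    d0v = d0_fn(L_t, "sequential")
    best = 0.0
    for frag in {min(len(a), len(b)), max(min(len(a), len(b)) // 2, 15)}:
        for ia in range(0, len(a) - frag + 1, 2):
            for ib in range(0, len(b) - frag + 1, 2):
                pa, pb = a[ia:ia + frag], b[ib:ib + frag]
                try:
                    rot, trans, _ = kabsch_superpose(pa, pb)
                except ValueError:
                    continue
                d = np.linalg.norm(pa - ((rot @ pb.T).T + trans), axis=1)
                best = max(best, float(np.sum(1 / (1 + (d / d0v) ** 2)) / L_t))
    return best


# ---------------------------------------------------------------------------
# Graph oracles


def pairs_within_k_matrix_power(adj: np.ndarray, k: int) -> int:
    """Ordered reachable pairs within k steps via boolean matrix powers."""
    n = adj.shape[0]
    reach = np.zeros_like(adj, dtype=bool)
    power = np.eye(n, dtype=bool)
    for _ in range(k):
        power = power @ adj
        reach |= power
    np.fill_diagonal(reach, False)
    return int(reach.sum())


def scc_sizes_bruteforce(adj: np.ndarray) -> list[int]:
    """SCC sizes by mutual-reachability closure (Floyd–Warshall style)."""
    n = adj.shape[0]
    reach = adj.copy().astype(bool)
    for m in range(n):
        reach |= np.outer(reach[:, m], reach[m, :])
    np.fill_diagonal(reach, True)
    mutual = reach & reach.T
    seen, sizes = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if mutual[i, j] and mutual[j, i]}
        seen |= comp
        sizes.append(len(comp))
    return sorted(sizes, reverse=True)


def naive_nonredundant(clusters, records):
    """Direct re-statement of the cluster-combination selection rule, written
    independently of the package implementation (per-combination scan)."""
    member_of = {}
    for c in clusters:
        for m in c.members:
            member_of.setdefault(m, c.cluster_id)
    chosen = {}
    ids = sorted(c.cluster_id for c in clusters)
    for i in ids:
        for j in ids:
            if not i < j:
                continue
            group_fwd, group_rev = [], []
            for rec in records:
                na = rec.domain_a.definition.domain_number
                nb = rec.domain_b.definition.domain_number
                ka, kb = (rec.entry_id, na), (rec.entry_id, nb)
                if member_of.get(ka) == i and member_of.get(kb) == j:
                    group_fwd.append(rec)
                elif member_of.get(ka) == j and member_of.get(kb) == i:
                    group_rev.append(rec)
            for group in (group_fwd, group_rev):
                if group:
                    best = min(group, key=lambda r: (r.resolution,
                                                     -r.total_length,
                                                     r.entry_id))
                    chosen[best.pair_id] = best
    return sorted(chosen.values(), key=lambda r: r.pair_id)


def random_toy_interface_pair(rng, n_side=5, noise=0.1):
    """A random small interface and a noisy rigid copy (same topology)."""
    from scipy.spatial.transform import Rotation

    while True:
        qa = rng.uniform(-4, 4, size=(n_side, 3)) + [0, 0, 3.0]
        qb = rng.uniform(-4, 4, size=(n_side, 3)) + [0, 0, -3.0]
        # nearest-neighbor contacts guarantee every residue participates
        contacts = set()
        for i in range(n_side):
            j = int(np.argmin(np.linalg.norm(qb - qa[i], axis=1)))
            contacts.add((i, j))
        for j in range(n_side):
            i = int(np.argmin(np.linalg.norm(qa - qb[j], axis=1)))
            contacts.add((i, j))
        # degenerate (collinear) clouds upset superposition: retry
        allc = np.vstack([qa, qb])
        svals = np.linalg.svd(allc - allc.mean(axis=0), compute_uv=False)
        if svals[1] > 1.0:
            break
    query = toy_interface(qa, qb, sorted(contacts), "toy_q")
    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.uniform(-20, 20, size=3)
    ta = (rot @ qa.T).T + shift + rng.normal(0, noise, size=qa.shape)
    tb = (rot @ qb.T).T + shift + rng.normal(0, noise, size=qb.shape)
    template = toy_interface(ta, tb, sorted(contacts), "toy_t")
    return query, template
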