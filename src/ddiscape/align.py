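"""Non-sequential interface alignment, TM-score, empirical significance.

``align_interfaces`` is a heuristic maximizer of the IS-score over (a) the
two possible domain pairings, (b) rigid superpositions, and (c) one-to-one
residue assignments that respect the chosen pairing. The search follows the
classic iterative-superposition design: from each initial superposition
(principal-axes pre-alignments plus contiguous interface-fragment seeds),
iterate {Kabsch on current pairs -> distance-plus-contact-overlap score
matrix -> Hungarian assignment with a pairing distance cutoff -> rescore}
to convergence and keep the global best. It is deterministic for fixed
inputs and parameters, and matches exhaustive search on small instances
(oracle-tested).

``tm_score_domains`` is a sequential (order-preserving) whole-domain
comparison: gapless-threading seeds, then iterative superposition plus
Needleman-Wunsch dynamic programming, scored with the sequential d0. It is
used only as a *dissimilarity* filter (TM-score < 0.4 means structurally
unrelated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import gumbel_r

from .interfaces import DomainInterface
from .scoring import (
    AlignmentScores,
    InterfaceAlignment,
    ScoringParams,
    d0 as d0_fn,
    kabsch_superpose,
    score_alignment,
    _contact_sets,
    _interface_geometry,
)
from .structures import DomainInstance

_BIG = 1e6  # forbidden-assignment cost


def _sides(interface: DomainInterface):
    """Keys, coords and side labels of an interface's Cα residues."""
    geo = _interface_geometry(interface)
    keys = list(geo)
    coords = np.array([geo[k] for k in keys])
    sides = np.array([0 if k[0] == "a" else 1 for k in keys])
    return keys, coords, sides


def _pca_frames(coords: np.ndarray):
    """Right-handed principal-axes frames (4 sign choices) of a point cloud."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt
    if np.linalg.det(axes) < 0:
        axes = axes * np.array([[1.0], [1.0], [-1.0]])
    frames = []
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        s3 = s1 * s2  # keep det = +1
        frames.append(axes * np.array([[s1], [s2], [s3]]))
    return frames


def _assign(
    qcoords, qsides, tcoords_moved, tsides, allowed, f_matrix, d0_val, cutoff
):
    """Hungarian assignment on the distance-plus-overlap score matrix.

    Pairs violating the side pairing or farther than ``cutoff`` are
    forbidden. Ties resolve to the lowest query ordinal (scipy's assignment
    is deterministic for a fixed matrix). Returns index pairs.
    """
    nq, nt = len(qcoords), len(tcoords_moved)
    diff = qcoords[:, None, :] - tcoords_moved[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    score = f_matrix / (1.0 + (dist / d0_val) ** 2)
    cost = -score
    forbidden = ~allowed[qsides[:, None], tsides[None, :]] | (dist > cutoff)
    cost = np.where(forbidden, _BIG, cost)
    if nq <= nt:
        rows, cols = linear_sum_assignment(cost)
    else:
        cols, rows = linear_sum_assignment(cost.T)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if not forbidden[r, c]]


def _adjacency(keys, contacts):
    """Boolean contact adjacency over key indices plus per-key counts."""
    idx = {k: i for i, k in enumerate(keys)}
    n = len(keys)
    adj = np.zeros((n, n), bool)
    for contact in contacts:
        k1, k2 = tuple(contact)
        if k1 in idx and k2 in idx:
            adj[idx[k1], idx[k2]] = adj[idx[k2], idx[k1]] = True
    counts = adj.sum(axis=1).astype(float)
    return adj, counts


def _overlap_counts(Q, T, pairs_idx):
    """C[i, j] = contacts of query residue i preserved if i were mapped to
    template residue j, given the current correspondence."""
    nq, nt = Q.shape[0], T.shape[0]
    M = np.zeros((nq, nt))
    for r, c in pairs_idx:
        M[r, c] = 1.0
    return Q.astype(float) @ M @ T.astype(float)


def _f_estimate(Q, T, bq, at, pairs_idx):
    """Per-candidate contact-overlap estimate from the current correspondence."""
    nq, nt = Q.shape[0], T.shape[0]
    if not pairs_idx:
        return np.full((nq, nt), 0.25)  # optimistic prior before any pairs
    C = _overlap_counts(Q, T, pairs_idx)
    cap = np.minimum(bq[:, None], at[None, :])
    C = np.minimum(C, cap)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 0.5 * (C / np.where(at[None, :] > 0, at[None, :], np.inf)
                   + C / np.where(bq[:, None] > 0, bq[:, None], np.inf))
    return f


def _raw_S(pairs_idx, rot, trans, qcoords, tcoords, Q, T, bq, at, L_Q, d0_val):
    """Σ f_i/(1+d_i²/d0²) / L_Q for an index correspondence."""
    rows = np.array([r for r, _ in pairs_idx])
    cols = np.array([c for _, c in pairs_idx])
    moved = (rot @ tcoords[cols].T).T + trans
    d = np.linalg.norm(qcoords[rows] - moved, axis=1)
    C = _overlap_counts(Q, T, pairs_idx)
    c_i = np.minimum(C[rows, cols], np.minimum(bq[rows], at[cols]))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 0.5 * (c_i / np.where(at[cols] > 0, at[cols], np.inf)
                   + c_i / np.where(bq[rows] > 0, bq[rows], np.inf))
    return float(np.sum(f / (1 + (d / d0_val) ** 2)) / L_Q)


def align_interfaces(
    query: DomainInterface,
    template: DomainInterface,
    params: ScoringParams | None = None,
    fragment_length: int = 6,
    fragment_stride: int = 2,
) -> tuple[InterfaceAlignment, AlignmentScores]:
    """Best non-sequential alignment of two interfaces by IS-score."""
    params = params or ScoringParams()
    qkeys, qcoords, qsides = _sides(query)
    tkeys, tcoords, tsides = _sides(template)
    if len(qkeys) < 3 or len(tkeys) < 3:
        raise ValueError("interfaces need >= 3 residues with Calpha coordinates")
    L_Q = query.L
    d0_val = d0_fn(L_Q, params.mode, params.d0_floor)
    cutoff = max(params.pairing_cutoff_factor * d0_val, 1.0)
    qcontacts, _ = _contact_sets(query)
    tcontacts, _ = _contact_sets(template)
    Q, bq = _adjacency(qkeys, qcontacts)
    T, at = _adjacency(tkeys, tcontacts)

    pairings = {
        "direct": np.array([[True, False], [False, True]]),
        "swapped": np.array([[False, True], [True, False]]),
    }

    best = None  # (S, pairing_name, pairs_idx, rot, trans)

    def run_iteration(pairs_idx, pairing_name, allowed, rot=None, trans=None):
        nonlocal best
        prev_S = -np.inf
        for _ in range(params.max_iterations):
            if rot is None:
                if len(pairs_idx) < 3:
                    return
                qa = qcoords[[r for r, _ in pairs_idx]]
                ta = tcoords[[c for _, c in pairs_idx]]
                try:
                    rot, trans, _ = kabsch_superpose(qa, ta)
                except ValueError:
                    return
            moved = (rot @ tcoords.T).T + trans
            f_mat = _f_estimate(Q, T, bq, at, pairs_idx)
            new_pairs = _assign(qcoords, qsides, moved, tsides, allowed,
                                f_mat, d0_val, cutoff)
            if len(new_pairs) < 3:
                return
            qa = qcoords[[r for r, _ in new_pairs]]
            ta = tcoords[[c for _, c in new_pairs]]
            try:
                rot, trans, _ = kabsch_superpose(qa, ta)
            except ValueError:
                return
            S = _raw_S(new_pairs, rot, trans, qcoords, tcoords,
                       Q, T, bq, at, L_Q, d0_val)
            if best is None or S > best[0] + 1e-12:
                best = (S, pairing_name, list(new_pairs), rot.copy(), trans.copy())
            if abs(S - prev_S) < params.convergence_tol:
                return
            prev_S = S
            pairs_idx = new_pairs

    for pairing_name, allowed in pairings.items():
        # principal-axes pre-alignments: 4 proper-rotation seeds
        for qframe in _pca_frames(qcoords)[:1]:
            for tframe in _pca_frames(tcoords):
                rot = qframe.T @ tframe
                trans = qcoords.mean(axis=0) - rot @ tcoords.mean(axis=0)
                run_iteration([], pairing_name, allowed, rot=rot, trans=trans)
        # contiguous interface-fragment seeds with compatible side labels
        for qside in (0, 1):
            qidx = [i for i in range(len(qkeys)) if qsides[i] == qside]
            for tside in (0, 1):
                if not allowed[qside, tside]:
                    continue
                tidx = [j for j in range(len(tkeys)) if tsides[j] == tside]
                f = min(fragment_length, len(qidx), len(tidx))
                if f < 3:
                    continue
                for qs in range(0, len(qidx) - f + 1, fragment_stride):
                    for ts in range(0, len(tidx) - f + 1, fragment_stride):
                        seed = list(zip(qidx[qs:qs + f], tidx[ts:ts + f]))
                        run_iteration(seed, pairing_name, allowed)
                        seed_rev = list(zip(qidx[qs:qs + f],
                                            tidx[ts:ts + f][::-1]))
                        run_iteration(seed_rev, pairing_name, allowed)

    if best is None:
        alignment = InterfaceAlignment(
            query=query, template=template, pairs=[],
            rotation=np.eye(3), translation=np.zeros(3),
        )
        return alignment, score_alignment(alignment, params)

    _, pairing_name, pairs_idx, rot, trans = best
    pairs_idx.sort(key=lambda rc: rc[0])  # lowest query ordinal first
    alignment = InterfaceAlignment(
        query=query,
        template=template,
        pairs=[(qkeys[r], tkeys[c]) for r, c in pairs_idx],
        rotation=rot,
        translation=trans,
        domain_pairing=pairing_name,
    )
    return alignment, score_alignment(alignment, params)


# ---------------------------------------------------------------------------
# Sequential whole-domain TM-score


def _tm_of_alignment(a, b, pairs, L_norm, d0_val):
    if len(pairs) < 3:
        return 0.0, None
    pa = a[[i for i, _ in pairs]]
    pb = b[[j for _, j in pairs]]
    try:
        rot, trans, _ = kabsch_superpose(pa, pb)
    except ValueError:
        return 0.0, None
    moved = (rot @ pb.T).T + trans
    d = np.linalg.norm(pa - moved, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0_val) ** 2)) / L_norm), (rot, trans)


def _dp_align(score: np.ndarray, gap: float = -0.6):
    """Needleman-Wunsch with linear gap penalty; returns aligned index pairs."""
    n, m = score.shape
    H = np.zeros((n + 1, m + 1))
    P = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 diag, 2 up, 3 left
    for i in range(1, n + 1):
        H[i, 0] = H[i - 1, 0] + gap
        P[i, 0] = 2
    for j in range(1, m + 1):
        H[0, j] = H[0, j - 1] + gap
        P[0, j] = 3
    for i in range(1, n + 1):
        diag = H[i - 1, :-1] + score[i - 1]
        for j in range(1, m + 1):
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            d = diag[j - 1]
            if d >= up and d >= left:
                H[i, j], P[i, j] = d, 1
            elif up >= left:
                H[i, j], P[i, j] = up, 2
            else:
                H[i, j], P[i, j] = left, 3
    pairs = []
    i, j = n, m
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def tm_score_one_way(
    mobile: np.ndarray,
    target: np.ndarray,
    d0_floor: float = 0.5,
    max_iterations: int = 20,
) -> float:
    """Sequential TM-score of ``mobile`` vs ``target``, normalized by the
    target length. Iterative fragment superposition + dynamic programming."""
    a, b = np.asarray(target, float), np.asarray(mobile, float)
    L_t = len(a)
    if L_t < 15 or len(b) < 15:
        raise ValueError("TM-score needs >= 15 residues (d0 regime)")
    d0_val = d0_fn(L_t, "sequential", d0_floor)
    L_min = min(len(a), len(b))
    best = 0.0

    # dense gapless-threading scan (cheap); DP-refine the best few seeds
    scored_seeds = []
    for frag in {L_min, max(L_min // 2, 15), max(L_min // 4, 15)}:
        for ia in range(0, len(a) - frag + 1, 2):
            for ib in range(0, len(b) - frag + 1, 2):
                seed = [(ia + k, ib + k) for k in range(frag)]
                tm, _ = _tm_of_alignment(a, b, seed, L_t, d0_val)
                best = max(best, tm)
                scored_seeds.append((tm, seed))
    scored_seeds.sort(key=lambda s: -s[0])

    for _, seed in scored_seeds[:8]:
        pairs = seed
        prev = -1.0
        for _ in range(max_iterations):
            tm, xform = _tm_of_alignment(a, b, pairs, L_t, d0_val)
            best = max(best, tm)
            if xform is None or abs(tm - prev) < 1e-6:
                break
            prev = tm
            rot, trans = xform
            moved = (rot @ b.T).T + trans
            diff = a[:, None, :] - moved[None, :, :]
            sim = 1.0 / (1.0 + (np.linalg.norm(diff, axis=2) / d0_val) ** 2)
            pairs = _dp_align(sim)
            if len(pairs) < 3:
                break
    return best


def tm_score_domains(
    dom_a: DomainInstance, dom_b: DomainInstance, normalize: str = "max"
) -> float:
    """Sequential structural similarity of two whole domains.

    ``normalize``: "max" scores by each domain in turn and returns the
    maximum (conservative for a dissimilarity filter); "a"/"b" normalize by
    that domain's length.
    """
    ca, cb = dom_a.ca_coords(), dom_b.ca_coords()
    if normalize == "a":
        return tm_score_one_way(cb, ca)
    if normalize == "b":
        return tm_score_one_way(ca, cb)
    return max(tm_score_one_way(cb, ca), tm_score_one_way(ca, cb))


# ---------------------------------------------------------------------------
# Empirical significance


@dataclass
class SignificanceModel:
    """Extreme-value (Gumbel) model of best-match IS-scores among random,
    structurally unrelated interface pairs."""

    loc: float
    scale: float
    n_samples: int
    alpha: float = 0.05

    def p_value(self, score: float) -> float:
        return float(gumbel_r.sf(score, loc=self.loc, scale=self.scale))

    @property
    def threshold(self) -> float:
        """IS-score at which p = alpha."""
        return float(gumbel_r.isf(self.alpha, loc=self.loc, scale=self.scale))

    def is_significant(self, score: float) -> bool:
        return self.p_value(score) < self.alpha


def calibrate_significance(
    null_scores, min_samples: int = 200, alpha: float = 0.05
) -> SignificanceModel:
    """Fit the null IS-score distribution from random interface pairs.

    ``null_scores``: best-alignment IS-scores of >= ``min_samples`` random
    (non-planted) interface pairs. The fitted Gumbel right-tail gives
    ``p_value(score)``, monotone decreasing in the score.
    """
    scores = np.asarray(list(null_scores), float)
    if len(scores) < min_samples:
        raise ValueError(
            f"significance calibration needs >= {min_samples} null scores, "
            f"got {len(scores)}"
        )
    loc, scale = gumbel_r.fit(scores)
    return SignificanceModel(loc=float(loc), scale=float(scale),
                             n_samples=len(scores), alpha=alpha)
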