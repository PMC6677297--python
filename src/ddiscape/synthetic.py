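"""Synthetic multidomain structures with controllable interfaces.

Stands in for a crystal-structure corpus: idealized domains (helix bundles,
beta sandwiches, mixed) built from ideal secondary-structure geometry, rigid
domain-domain placement tuned to a target interface size, planted
geometrically similar interfaces grafted into unrelated host domains,
inter-domain linkers with optional missing residues, discontinuous domains,
and sequence families at a controlled identity level. Everything is
deterministic under a fixed seed.

The generator emulates the *geometry* the pipeline consumes — backbone
(N, Cα, C, O) plus a pseudo-Cβ, no side chains — so "heavy atoms" in the
contact rule are these five atoms per residue. It does not emulate real
side-chain packing, crystallographic disorder beyond annotated missing
ranges, or realistic sequence-structure coupling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .interfaces import DomainInterface, build_interface
from .pdbio import write_domain_table, write_fasta, write_pdb
from .structures import (
    Atom,
    ChainStructure,
    DomainDefinition,
    DomainInstance,
    Residue,
    ResidueID,
    Segment,
    apply_domain_definitions,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
CA_BOND = 3.8          # Å, virtual Cα-Cα bond
CLASH_DIST = 2.5       # Å, heavy-atom self-avoidance
STYLES = ("helix-bundle", "beta-sandwich", "mixed")


@dataclass
class SyntheticSpec:
    """Parameters of one generated entry / suite."""

    seed: int = 0
    n_entries: int = 75
    domain_size_range: tuple[int, int] = (40, 70)
    interface_contact_target: int = 26  # interfacial residues (both sides)
    plant: tuple[str, float] | None = None  # (source interface id, sigma Å)
    linker_length: int = 5
    missing_linker: bool = False
    discontinuous: tuple[int, float] | None = None  # (n_segments, longest_fraction)
    family_identity: float = 0.4

    def __post_init__(self) -> None:
        if self.n_entries <= 0 or self.interface_contact_target <= 0:
            raise ValueError("counts must be positive")
        if self.plant is not None and self.plant[1] < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.discontinuous is not None:
            n_seg, frac = self.discontinuous
            if n_seg < 2 or not 0 < frac <= 1:
                raise ValueError("discontinuous needs n_segments >= 2, fraction in (0,1]")


@dataclass
class GeneratedEntry:
    """A generated chain plus the ground truth of its construction."""

    chain: ChainStructure
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Cα trace geometry


def _arc_points(p0: np.ndarray, p1: np.ndarray, m: int, normal: np.ndarray,
                step: float = CA_BOND) -> np.ndarray:
    """``m`` interior points on a circular arc from p0 to p1 with equal
    chord steps of length ``step``; the arc bulges along ``normal``."""
    chord = float(np.linalg.norm(p1 - p0))
    n_steps = m + 1
    if chord >= step * n_steps - 1e-9:
        raise ValueError("arc infeasible: chord too long for residue budget")
    if m == 0:
        return np.empty((0, 3))
    # solve for arc angle: chord = step * sin(theta/2) / sin(theta/(2 n))
    lo, hi = 1e-9, 2 * np.pi - 1e-9
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        ratio = np.sin(mid / 2) / np.sin(mid / (2 * n_steps))
        if ratio * step > chord:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    radius = chord / (2 * np.sin(theta / 2))
    u = (p1 - p0) / chord
    w = normal - np.dot(normal, u) * u
    if np.linalg.norm(w) < 1e-8:
        w = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(w) < 1e-8:
            w = np.cross(u, [0.0, 1.0, 0.0])
    w = w / np.linalg.norm(w)
    mid_pt = 0.5 * (p0 + p1)
    center = mid_pt - w * radius * np.cos(theta / 2)
    # circle in the (u, w) plane: p0 at angle -theta/2, p1 at +theta/2,
    # apex of the bulge (along +w) at angle 0
    pts = []
    for k in range(1, m + 1):
        phi = -theta / 2 + theta * k / n_steps
        pts.append(center + radius * (np.sin(phi) * u + np.cos(phi) * w))
    return np.array(pts)


def _helix_trace(n: int, origin: np.ndarray, direction: float, phase: float) -> np.ndarray:
    """Ideal α-helix Cα trace: 1.5 Å rise and 100°/residue about the z axis."""
    radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    ks = np.arange(n)
    pts = np.stack(
        [
            radius * np.cos(phase + twist * ks),
            radius * np.sin(phase + twist * ks),
            direction * rise * ks,
        ],
        axis=1,
    )
    return pts + origin


def _strand_trace(n: int, origin: np.ndarray, direction: float) -> np.ndarray:
    """Ideal β-strand Cα trace: 3.3 Å rise with a ±0.94 Å zigzag."""
    rise, zig = 3.3, 0.94
    ks = np.arange(n)
    pts = np.stack(
        [zig * (-1.0) ** ks, np.zeros(n), direction * rise * ks], axis=1
    )
    return pts + origin


def _partition(n_res: int, n_elements: int, loop_lengths: list[int]) -> list[int]:
    """Split ``n_res`` into ``n_elements`` secondary-structure lengths given
    fixed loop budgets between them."""
    budget = n_res - sum(loop_lengths)
    base = budget // n_elements
    lens = [base] * n_elements
    for i in range(budget - base * n_elements):
        lens[i] += 1
    if min(lens) < 4:
        raise ValueError(f"{n_res} residues too few for {n_elements} elements")
    return lens


def _element_layout(style: str, n_res: int):
    """(kind, length, origin, direction) per element plus loop budgets."""
    if style == "helix-bundle":
        n_el = max(2, int(round(n_res / 20)))
        loops = [2] * (n_el - 1)
        lens = _partition(n_res, n_el, loops)
        # two-column staggered grid, extensible to any helix count
        grid = [(9.5 * (i % 2) + 4.75 * ((i // 2) % 2), 8.2 * (i // 2))
                for i in range(n_el)]
        elems = []
        z_top = max(lens) * 1.5
        for i, ln in enumerate(lens):
            x, y = grid[i]
            direction = 1.0 if i % 2 == 0 else -1.0
            z0 = 0.0 if direction > 0 else z_top
            elems.append(("helix", ln, np.array([x, y, z0]), direction))
        return elems, loops
    if style == "helix-layer":
        # all helices in one row: the whole face is solvent-exposed, which
        # supports the large one-sided interfaces discontinuous entries need
        n_el = max(2, int(round(n_res / 20)))
        loops = [2] * (n_el - 1)
        lens = _partition(n_res, n_el, loops)
        elems = []
        z_top = max(lens) * 1.5
        for i, ln in enumerate(lens):
            direction = 1.0 if i % 2 == 0 else -1.0
            z0 = 0.0 if direction > 0 else z_top
            elems.append(("helix", ln, np.array([9.5 * i, 0.0, z0]), direction))
        return elems, loops
    if style == "beta-sandwich":
        n_st = max(4, min(8, 2 * (n_res // 22)))
        if n_st % 2:
            n_st -= 1
        half = n_st // 2
        loops = [2] * (n_st - 1)
        loops[half - 1] = 3  # sheet-crossing loop
        lens = _partition(n_res, n_st, loops)
        elems = []
        z_top = max(lens) * 3.3
        for i, ln in enumerate(lens):
            sheet = i // half
            col = i % half
            x = 4.8 * col
            y = 9.5 * sheet
            direction = 1.0 if i % 2 == 0 else -1.0
            z0 = 0.0 if direction > 0 else z_top
            elems.append(("strand", ln, np.array([x, y, z0]), direction))
        return elems, loops
    if style == "mixed":
        n_st, n_hel = 3, 2
        loops = [2, 2, 3, 3]
        lens = _partition(n_res, n_st + n_hel, loops)
        elems = []
        z_top_s = max(lens[:n_st]) * 3.3
        for i in range(n_st):
            direction = 1.0 if i % 2 == 0 else -1.0
            z0 = 0.0 if direction > 0 else z_top_s
            elems.append(("strand", lens[i], np.array([4.8 * i, 0.0, z0]), direction))
        for j in range(n_hel):
            i = n_st + j
            direction = 1.0 if i % 2 == 0 else -1.0
            z_top_h = lens[i] * 1.5
            z0 = 0.0 if direction > 0 else z_top_h
            elems.append(("helix", lens[i], np.array([2.4 + 9.0 * j, 9.0, z0]), direction))
        return elems, loops
    raise ValueError(f"unknown style {style!r}")


def _ca_trace(style: str, n_res: int, rng: np.random.Generator,
              bulge_jitter: float = 0.0) -> np.ndarray:
    """Cα trace of one domain: elements connected by arcs whose residue
    count adapts to the junction chord (gentle loops); the residue budget
    is balanced by shortening the final element."""
    elems, _ = _element_layout(style, n_res)
    centroid_hint = np.mean([e[2] for e in elems], axis=0)
    pieces: list[np.ndarray] = []
    built = 0
    for idx, (kind, ln, origin, direction) in enumerate(elems):
        if idx > 0:
            prev_end = pieces[-1][-1]
            if kind == "helix":
                phase = 0.0 if direction > 0 else np.pi
                start_pt = _helix_trace(1, origin, direction, phase)[0]
            else:
                start_pt = _strand_trace(1, origin, direction)[0]
            chord = float(np.linalg.norm(start_pt - prev_end))
            m = max(2, int(np.ceil(chord / CA_BOND)))
            outward = 0.5 * (prev_end + start_pt) - centroid_hint
            if bulge_jitter > 0:
                outward = outward + rng.normal(0.0, bulge_jitter, size=3)
            if np.linalg.norm(outward) < 1e-6:
                outward = np.array([0.0, -1.0, 0.0])
            while True:
                try:
                    loop_pts = _arc_points(prev_end, start_pt, m, outward)
                    break
                except ValueError:
                    m += 1
            pieces.append(loop_pts)
            built += m
        if idx == len(elems) - 1:
            ln = n_res - built
            if ln < 4:
                raise ValueError("residue budget exhausted by loops")
        if kind == "helix":
            phase = 0.0 if direction > 0 else np.pi
            trace = _helix_trace(ln, origin, direction, phase)
        else:
            trace = _strand_trace(ln, origin, direction)
        pieces.append(trace)
        built += ln
    coords = np.vstack(pieces)
    coords = coords + rng.normal(0.0, 0.05, size=coords.shape)
    return coords


def _backbone_atoms(ca: np.ndarray) -> list[list[Atom]]:
    """Backbone + pseudo-Cβ atoms around each Cα of a trace."""
    n = len(ca)
    atoms_per_res = []
    for k in range(n):
        prev_pt = ca[k - 1] if k > 0 else ca[k] - (ca[k + 1] - ca[k])
        next_pt = ca[k + 1] if k < n - 1 else ca[k] + (ca[k] - ca[k - 1])
        u = next_pt - prev_pt
        u = u / max(np.linalg.norm(u), 1e-8)
        ref = np.array([0.0, 0.0, 1.0])
        n1 = np.cross(u, ref)
        if np.linalg.norm(n1) < 1e-6:
            n1 = np.cross(u, [0.0, 1.0, 0.0])
        n1 = n1 / np.linalg.norm(n1)
        n2 = np.cross(u, n1)
        pos = ca[k]
        atoms_per_res.append(
            [
                Atom("N", "N", pos - 1.2 * u + 0.3 * n1),
                Atom("CA", "C", pos),
                Atom("C", "C", pos + 1.2 * u + 0.3 * n1),
                Atom("O", "O", pos + 1.2 * u + 1.4 * n1),
                Atom("CB", "C", pos + 1.5 * n2),
            ]
        )
    return atoms_per_res


def _self_clash(ca: np.ndarray, threshold: float = CLASH_DIST) -> bool:
    tree = cKDTree(ca)
    for i, j in tree.query_pairs(threshold):
        if abs(i - j) > 3:
            return True
    return False


def random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20)) for _ in range(n))


def _residues_from_trace(
    ca: np.ndarray, sequence: str, start_number: int, chain_id: str = "A"
) -> list[Residue]:
    atoms_per_res = _backbone_atoms(ca)
    residues = []
    for k, atoms in enumerate(atoms_per_res):
        ca_atom = atoms[1]
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_index=ResidueID(start_number + k),
                aa=sequence[k],
                atoms=atoms,
                ca=ca_atom,
            )
        )
    return residues


def make_idealized_domain(
    style: str,
    n_res: int,
    seed: int,
    entry_id: str = "SYN0_A",
    domain_number: int = 1,
    fold_label: str | None = None,
    resolution: float = 2.0,
    max_retries: int = 8,
) -> DomainInstance:
    """Build a self-avoiding idealized domain of the given style.

    The Cα trace follows ideal secondary-structure geometry (helix rise
    1.5 Å/residue with 100°/residue twist; strand rise 3.3 Å) with
    circular-arc loops keeping the virtual Cα-Cα bond at 3.8 Å.
    """
    if n_res < 30:
        raise ValueError("idealized domains need n_res >= 30")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        ca = _ca_trace(style, n_res, rng, bulge_jitter=0.4 * attempt)
        if not _self_clash(ca):
            break
    else:
        raise RuntimeError(f"could not build clash-free {style} domain of {n_res}")
    seq = random_sequence(n_res, rng)
    residues = _residues_from_trace(ca, seq, start_number=1)
    definition = DomainDefinition(
        entry_id=entry_id,
        domain_number=domain_number,
        segments=[Segment("A", 1, n_res)],
        fold_label=fold_label or f"{style}/v0",
        resolution=resolution,
    )
    return DomainInstance(definition=definition, residues=residues)


# ---------------------------------------------------------------------------
# Rigid placement of a partner domain


def _heavy_coords_by_residue(residues: list[Residue]):
    coords, owner = [], []
    for i, r in enumerate(residues):
        for c in r.heavy_coords:
            coords.append(c)
            owner.append(i)
    return np.array(coords), np.array(owner)


def _interface_size(coords_a, owner_a, coords_b, owner_b, cutoff=4.5):
    tree = cKDTree(coords_b)
    pairs = tree.query_ball_point(coords_a, cutoff)
    res_a, res_b = set(), set()
    for ia, nbrs in enumerate(pairs):
        for k in nbrs:
            res_a.add(int(owner_a[ia]))
            res_b.add(int(owner_b[k]))
    dmin, _ = tree.query(coords_a, k=1)
    min_d = float(np.min(dmin))
    return len(res_a) + len(res_b), min_d


def _interface_sides(coords_a, owner_a, coords_b, owner_b, cutoff=4.5):
    tree = cKDTree(coords_b)
    pairs = tree.query_ball_point(coords_a, cutoff)
    res_a, res_b = set(), set()
    for ia, nbrs in enumerate(pairs):
        for k in nbrs:
            res_a.add(int(owner_a[ia]))
            res_b.add(int(owner_b[k]))
    dmin, _ = tree.query(coords_a, k=1)
    return len(res_a), len(res_b), float(np.min(dmin))


def _transform_residues(residues: list[Residue], rot: np.ndarray, trans: np.ndarray,
                        renumber_from: int | None = None) -> list[Residue]:
    out = []
    for k, r in enumerate(residues):
        atoms = [Atom(a.name, a.element, rot @ a.coord + trans) for a in r.atoms]
        ca = next((a for a in atoms if a.name == "CA"), None)
        num = r.seq_index if renumber_from is None else ResidueID(renumber_from + k)
        out.append(Residue(r.chain_id, num, r.aa, atoms, ca))
    return out


def place_against(
    residues_a: list[Residue],
    residues_b: list[Residue],
    target_L: int,
    rng: np.random.Generator,
    tol_frac: float = 0.10,
    max_orientations: int = 150,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Find a rigid placement of B against A whose interface size is within
    ``tol_frac`` of ``target_L``. Returns (rotation, translation, achieved L).

    Strategy: random orientation, slide B along a random approach axis from
    first heavy-atom touch down to the clash limit in 0.25 Å steps, keep the
    separation whose L is closest to target; retry orientations until the
    tolerance band is hit.
    """
    coords_a, owner_a = _heavy_coords_by_residue(residues_a)
    coords_b0, owner_b = _heavy_coords_by_residue(residues_b)
    cen_a = coords_a.mean(axis=0)
    cen_b = coords_b0.mean(axis=0)
    lo = int(np.floor(target_L * (1 - tol_frac)))
    hi = int(np.ceil(target_L * (1 + tol_frac)))
    best = None  # (|L-target|, rot, trans, L, v)
    pool: list[tuple] = []

    # face-to-face bias: approach along (a tilt of) A's flattest principal
    # axis, with B's flattest face turned toward A — flat-face packing is
    # what produces interfaces of realistic size
    def _min_axis(coords):
        c = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        return vt[-1]

    axis_a = _min_axis(coords_a)
    axis_b = _min_axis(coords_b0)

    for trial in range(max_orientations):
        if trial % 3 == 2:  # keep some fully random poses in the mix
            rot = Rotation.random(random_state=rng).as_matrix()
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
        else:
            sign_a = 1.0 if rng.random() < 0.5 else -1.0
            tilt = rng.normal(0.0, 0.25, size=3)
            v = sign_a * axis_a + tilt
            v /= np.linalg.norm(v)
            sign_b = 1.0 if rng.random() < 0.5 else -1.0
            align, _ = Rotation.align_vectors((-v)[None, :],
                                              (sign_b * axis_b)[None, :])
            spin = Rotation.from_rotvec(v * rng.uniform(0, 2 * np.pi))
            rot = (spin * align).as_matrix()
        start = 60.0
        base_trans = cen_a + v * start - rot @ cen_b
        moved = (rot @ coords_b0.T).T + base_trans
        _, min_d = _interface_size(coords_a, owner_a, moved, owner_b)
        result = _slide(coords_a, owner_a, coords_b0, owner_b, rot, v,
                        cen_a, cen_b, target_L)
        if result is not None:
            gap, trans, L = result
            pool.append((gap, rot, trans, L, v))
            if best is None or gap < best[0]:
                best = pool[-1]
            if lo <= L <= hi:
                return rot, trans, L

    # hill-climb refinement around the most promising poses
    pool.sort(key=lambda p: p[0])
    for start_pose in pool[:4]:
        current = start_pose
        for step in range(60):
            _, rot0, _, _, v0 = current
            sigma = 0.2 if step % 2 else 0.1
            tweak = Rotation.from_rotvec(rng.normal(0.0, sigma, size=3)).as_matrix()
            rot = tweak @ rot0
            v = v0 + rng.normal(0.0, 0.08, size=3)
            v /= np.linalg.norm(v)
            result = _slide(coords_a, owner_a, coords_b0, owner_b, rot, v,
                            cen_a, cen_b, target_L)
            if result is None:
                continue
            gap, trans, L = result
            if gap < current[0]:
                current = (gap, rot, trans, L, v)
                if gap < best[0]:
                    best = current
            if lo <= L <= hi:
                return rot, trans, L

    if best is None:
        raise RuntimeError("placement search exhausted: no contacting pose found")
    _, rot, trans, L, _ = best
    if not lo <= L <= hi:
        raise RuntimeError(
            f"placement search exhausted: best L={L}, target {target_L}±{tol_frac:.0%}"
        )
    return rot, trans, L


def _slide(coords_a, owner_a, coords_b0, owner_b, rot, v, cen_a, cen_b,
           target_L, start: float = 60.0):
    """Slide B along -v from far away to the clash limit; return the pose
    closest to the target interface size: (|L-target|, translation, L)."""
    base_trans = cen_a + v * start - rot @ cen_b
    moved = (rot @ coords_b0.T).T + base_trans
    _, min_d = _interface_size(coords_a, owner_a, moved, owner_b)
    t = start - (min_d - 4.4)
    best = None
    while t > 0:
        trans = cen_a + v * t - rot @ cen_b
        moved = (rot @ coords_b0.T).T + trans
        L, min_d = _interface_size(coords_a, owner_a, moved, owner_b)
        if min_d < CLASH_DIST:
            break
        if L > 0:
            gap = abs(L - target_L)
            if best is None or gap < best[0]:
                best = (gap, trans, L)
            if L > target_L and gap >= best[0]:
                break
        t -= 0.2
    return best


def _place_for_contribution(
    residues_a: list[Residue],
    residues_b: list[Residue],
    min_side_a: int,
    rng: np.random.Generator,
    max_orientations: int = 400,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Rigid placement of B against A maximizing A's interfacial residue
    count; returns once side A contributes >= ``min_side_a`` residues."""
    coords_a, owner_a = _heavy_coords_by_residue(residues_a)
    coords_b0, owner_b = _heavy_coords_by_residue(residues_b)
    cen_a, cen_b = coords_a.mean(axis=0), coords_b0.mean(axis=0)

    def _min_axis(coords):
        c = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        return vt[-1]

    axis_a, axis_b = _min_axis(coords_a), _min_axis(coords_b0)

    def deepest(rot, v):
        """Deepest clash-free pose along -v: (side_a, trans, L)."""
        start = 60.0
        base = cen_a + v * start - rot @ cen_b
        moved = (rot @ coords_b0.T).T + base
        _, _, min_d = _interface_sides(coords_a, owner_a, moved, owner_b)
        t = start - (min_d - 4.4)
        pose = None
        while t > 0:
            trans = cen_a + v * t - rot @ cen_b
            moved = (rot @ coords_b0.T).T + trans
            na, nb, min_d = _interface_sides(coords_a, owner_a, moved, owner_b)
            if min_d < CLASH_DIST:
                break
            if na > 0 and (pose is None or na > pose[0]):
                pose = (na, trans, na + nb)
            t -= 0.2
        return pose

    pool = []
    best = None  # (side_a, rot, trans, L, v)
    for trial in range(max_orientations):
        if trial % 3 == 2:
            rot = Rotation.random(random_state=rng).as_matrix()
            v = rng.normal(size=3)
        else:
            sign_a = 1.0 if rng.random() < 0.5 else -1.0
            v = sign_a * axis_a + rng.normal(0.0, 0.25, size=3)
            sign_b = 1.0 if rng.random() < 0.5 else -1.0
            align, _ = Rotation.align_vectors(
                (-v)[None, :], (sign_b * axis_b)[None, :])
            spin = Rotation.from_rotvec(v / np.linalg.norm(v)
                                        * rng.uniform(0, 2 * np.pi))
            rot = (spin * align).as_matrix()
        v = v / np.linalg.norm(v)
        pose = deepest(rot, v)
        if pose is None:
            continue
        na, trans, L = pose
        pool.append((na, rot, trans, L, v))
        if best is None or na > best[0]:
            best = pool[-1]
        if na >= min_side_a:
            return rot, trans, L

    pool.sort(key=lambda p: -p[0])
    for start_pose in pool[:4]:
        current = start_pose
        for step in range(80):
            _, rot0, _, _, v0 = current
            sigma = 0.2 if step % 2 else 0.1
            tweak = Rotation.from_rotvec(rng.normal(0.0, sigma, size=3)).as_matrix()
            rot = tweak @ rot0
            v = v0 + rng.normal(0.0, 0.08, size=3)
            v /= np.linalg.norm(v)
            pose = deepest(rot, v)
            if pose is None:
                continue
            na, trans, L = pose
            if na > current[0]:
                current = (na, rot, trans, L, v)
                if na > best[0]:
                    best = current
            if na >= min_side_a:
                return rot, trans, L
    raise RuntimeError(
        f"placement search exhausted: best one-sided contribution "
        f"{best[0] if best else 0} < {min_side_a}"
    )


def _assemble_chain(
    entry_id: str,
    parts: list[tuple[str, list[Residue]]],
    linker_specs: dict[int, tuple[int, bool]],
    fold_labels: dict[str, str],
    resolution: float,
    rng: np.random.Generator,
    discontinuous_tail: tuple[str, list[Residue]] | None = None,
) -> ChainStructure:
    """Stitch domain residue blocks (already in final coordinates) into one
    renumbered chain with linkers / numbering gaps between blocks.

    ``linker_specs[i] = (length, missing)`` applies between block i and i+1.
    ``discontinuous_tail``: extra residues appended at the C terminus but
    belonging to the named (now discontinuous) domain.
    """
    residues: list[Residue] = []
    missing: list[Segment] = []
    segments: dict[str, list[Segment]] = {}
    number = 1
    for i, (name, block) in enumerate(parts):
        if i > 0:
            length, is_missing = linker_specs.get(i - 1, (0, False))
            if is_missing:
                if length:
                    missing.append(Segment("A", number, number + length - 1))
                number += length
            elif length:
                p0 = residues[-1].ca.coord
                p1 = block[0].ca.coord
                m = length
                while True:
                    try:
                        pts = _arc_points(p0, p1, m, rng.normal(size=3))
                        break
                    except ValueError:
                        m += 1
                seq = random_sequence(m, rng)
                residues.extend(_residues_from_trace(pts, seq, number))
                number += m
        start = number
        for r in block:
            residues.append(
                Residue(r.chain_id, ResidueID(number), r.aa, r.atoms, r.ca)
            )
            number += 1
        segments.setdefault(name, []).append(Segment("A", start, number - 1))
    if discontinuous_tail is not None:
        name, block = discontinuous_tail
        start = number
        for r in block:
            residues.append(
                Residue(r.chain_id, ResidueID(number), r.aa, r.atoms, r.ca)
            )
            number += 1
        segments.setdefault(name, []).append(Segment("A", start, number - 1))

    defs = [
        DomainDefinition(
            entry_id=entry_id,
            domain_number=k + 1,
            segments=segments[name],
            fold_label=fold_labels[name],
            resolution=resolution,
        )
        for k, name in enumerate(segments)
    ]
    chain = ChainStructure(
        entry_id=entry_id, residues=residues, missing_ranges=missing,
        resolution=resolution,
    )
    return apply_domain_definitions(chain, defs)


def make_domain_pair(
    spec: SyntheticSpec,
    entry_id: str = "SYN0_A",
    style_a: str = "helix-bundle",
    style_b: str = "beta-sandwich",
    fold_a: str | None = None,
    fold_b: str | None = None,
    resolution: float | None = None,
    sequence_a: str | None = None,
    sequence_b: str | None = None,
) -> GeneratedEntry:
    """A two-domain chain whose interface size hits the spec's target.

    Returns the chain (domains attached) and truth: achieved interface size,
    linker annotation, and the placement transform.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.domain_size_range
    n_a = int(rng.integers(lo, hi + 1))
    n_b = int(rng.integers(lo, hi + 1))
    dom_a = make_idealized_domain(style_a, n_a, int(rng.integers(2**31)))
    dom_b = make_idealized_domain(style_b, n_b, int(rng.integers(2**31)))
    if sequence_a:
        for r, aa in zip(dom_a.residues, sequence_a):
            r.aa = aa
    if sequence_b:
        for r, aa in zip(dom_b.residues, sequence_b):
            r.aa = aa
    rot, trans, L = place_against(
        dom_a.residues, dom_b.residues, spec.interface_contact_target, rng
    )
    placed_b = _transform_residues(dom_b.residues, rot, trans)
    res = resolution if resolution is not None else float(rng.uniform(1.5, 2.4))
    chain = _assemble_chain(
        entry_id,
        [("D1", dom_a.residues), ("D2", placed_b)],
        {0: (spec.linker_length, spec.missing_linker)},
        {"D1": fold_a or f"{style_a}/{entry_id}.1",
         "D2": fold_b or f"{style_b}/{entry_id}.2"},
        res,
        rng,
    )
    truth = {
        "achieved_L": L,
        "target_L": spec.interface_contact_target,
        "linker_length": spec.linker_length,
        "missing_linker": spec.missing_linker,
        "styles": [style_a, style_b],
    }
    return GeneratedEntry(chain=chain, truth=truth)


def make_multidomain_chain(
    seed: int,
    entry_id: str = "SYNM_A",
    styles: tuple[str, ...] = ("helix-bundle", "beta-sandwich", "mixed"),
    size: int = 45,
    target_L: int = 26,
    linker_length: int = 4,
) -> GeneratedEntry:
    """A chain of >= 3 domains placed sequentially, each contacting the
    previous one."""
    rng = np.random.default_rng(seed)
    blocks: list[tuple[str, list[Residue]]] = []
    for k, style in enumerate(styles):
        dom = make_idealized_domain(style, size, int(rng.integers(2**31)))
        if not blocks:
            blocks.append((f"D{k+1}", dom.residues))
            continue
        rot, trans, _ = place_against(blocks[-1][1], dom.residues, target_L, rng)
        blocks.append((f"D{k+1}", _transform_residues(dom.residues, rot, trans)))
    fold_labels = {f"D{k+1}": f"{styles[k]}/{entry_id}.{k+1}" for k in range(len(styles))}
    linkers = {i: (linker_length, False) for i in range(len(styles) - 1)}
    chain = _assemble_chain(entry_id, blocks, linkers, fold_labels,
                            float(rng.uniform(1.5, 2.4)), rng)
    return GeneratedEntry(chain=chain, truth={"styles": list(styles)})


def make_discontinuous_entry(
    seed: int,
    entry_id: str = "SYND_A",
    main_size: int = 130,
    tail_size: int = 12,
    partner_size: int = 120,
    min_major_contribution: int = 21,
    max_attempts: int = 10,
) -> GeneratedEntry:
    """A two-domain chain whose first domain is discontinuous: its major
    segment precedes the partner domain and a short second segment follows
    it in sequence. Placement retries until the major segment contributes
    at least ``min_major_contribution`` interfacial residues (the
    major-segment rule needs a one-sided interface of >= 20 residues)."""
    rng = np.random.default_rng(seed)
    dom_a = make_idealized_domain("helix-layer", main_size + tail_size,
                                  int(rng.integers(2**31)))
    dom_b = make_idealized_domain("beta-sandwich", partner_size,
                                  int(rng.integers(2**31)))
    main_res = dom_a.residues[:main_size]
    rot, trans, L = _place_for_contribution(
        main_res, dom_b.residues, min_major_contribution, rng,
        max_orientations=max_attempts * 60,
    )
    placed_b = _transform_residues(dom_b.residues, rot, trans)
    main = dom_a.residues[:main_size]
    tail = dom_a.residues[main_size:]
    chain = _assemble_chain(
        entry_id,
        [("D1", main), ("D2", placed_b)],
        {0: (3, False), 1: (3, False)},
        {"D1": f"helix-layer/{entry_id}.1", "D2": f"beta-sandwich/{entry_id}.2"},
        float(rng.uniform(1.5, 2.4)),
        rng,
        discontinuous_tail=("D1", tail),
    )
    return GeneratedEntry(
        chain=chain,
        truth={"major_segment_length": main_size, "tail_length": tail_size,
               "achieved_L": L},
    )


# ---------------------------------------------------------------------------
# Planted interface similarity


def plant_similar_interface(
    source: DomainInterface,
    noise_sigma: float,
    seed: int,
    host_styles: tuple[str, str] = ("mixed", "beta-sandwich"),
    entry_id: str = "SYNP_A",
    host_size: int = 42,
    standoff: float = 7.0,
    max_retries: int = 12,
) -> GeneratedEntry:
    """Graft a copy of a source interface into unrelated host domains.

    The source's interfacial residues (both sides, all backbone atoms) are
    copied under a random rigid transform with iid Gaussian per-residue
    displacement (sd = ``noise_sigma``), then each side is completed into a
    full domain by attaching a freshly generated host core placed on the
    outward face so it adds no cross-domain contacts. ``truth`` records the
    planted residue correspondence.
    """
    if source.is_empty:
        raise ValueError("cannot plant an empty interface")
    rng = np.random.default_rng(seed)
    src_a = [source.domain_a.residues[i] for i in source.side_a]
    src_b = [source.domain_b.residues[i] for i in source.side_b]

    for attempt in range(max_retries):
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.normal(0, 20.0, size=3)
        moved_a = _transform_residues(src_a, rot, shift)
        moved_b = _transform_residues(src_b, rot, shift)
        for r in moved_a + moved_b:
            disp = rng.normal(0.0, noise_sigma, size=3) if noise_sigma > 0 else 0.0
            new_atoms = [Atom(a.name, a.element, a.coord + disp) for a in r.atoms]
            r.atoms = new_atoms
            r.ca = next((a for a in new_atoms if a.name == "CA"), None)

        cen_a = np.mean([r.ca.coord for r in moved_a], axis=0)
        cen_b = np.mean([r.ca.coord for r in moved_b], axis=0)
        axis = cen_a - cen_b
        axis = axis / max(np.linalg.norm(axis), 1e-8)

        hosts = []
        ok = True
        for side, (style, patch, cen, sign) in enumerate(
            [(host_styles[0], moved_a, cen_a, 1.0),
             (host_styles[1], moved_b, cen_b, -1.0)]
        ):
            core = make_idealized_domain(style, host_size, int(rng.integers(2**31)))
            core_ca = core.ca_coords()
            core_cen = core_ca.mean(axis=0)
            radius = float(np.max(np.linalg.norm(core_ca - core_cen, axis=1)))
            crot = Rotation.random(random_state=rng).as_matrix()
            target = cen + sign * axis * (radius + standoff)
            ctrans = target - crot @ core_cen
            hosts.append(_transform_residues(core.residues, crot, ctrans))
        # cores must not contact the partner side (would distort the interface)
        ca_coords_a, _ = _heavy_coords_by_residue(hosts[0] + moved_a)
        cb_coords, _ = _heavy_coords_by_residue(hosts[1] + moved_b)
        core_a_coords, _ = _heavy_coords_by_residue(hosts[0])
        core_b_coords, _ = _heavy_coords_by_residue(hosts[1])
        opp_b = cKDTree(cb_coords)
        opp_a_tree = cKDTree(ca_coords_a)
        if np.min(opp_b.query(core_a_coords, k=1)[0]) < 5.0:
            ok = False
        if np.min(opp_a_tree.query(core_b_coords, k=1)[0]) < 5.0:
            ok = False
        patch_a_coords, _ = _heavy_coords_by_residue(moved_a)
        if np.min(cKDTree(patch_a_coords).query(core_a_coords, k=1)[0]) < CLASH_DIST:
            ok = False
        patch_b_coords, _ = _heavy_coords_by_residue(moved_b)
        if np.min(cKDTree(patch_b_coords).query(core_b_coords, k=1)[0]) < CLASH_DIST:
            ok = False
        if ok:
            break
    else:
        raise RuntimeError("graft failed: host cores kept clashing with the patch")

    rng2 = np.random.default_rng(seed + 7)
    chain = _assemble_chain(
        entry_id,
        [("D1", hosts[0]), ("D1b", moved_a), ("D2", moved_b), ("D2b", hosts[1])],
        {0: (2, False), 1: (4, True), 2: (2, False)},
        {"D1": f"{host_styles[0]}/{entry_id}.1", "D1b": "",
         "D2": f"{host_styles[1]}/{entry_id}.2", "D2b": ""},
        float(rng2.uniform(1.5, 2.4)),
        rng2,
    )
    # merge the patch blocks into their host domains: rebuild definitions
    ordered = sorted(chain.domains, key=lambda d: d.definition.segments[0].start)
    seg_list = [s for d in ordered for s in d.definition.segments]
    # blocks come out in order D1, D1b, D2, D2b
    d1_seg = Segment("A", seg_list[0].start, seg_list[1].end)
    d2_seg = Segment("A", seg_list[2].start, seg_list[3].end)
    defs = [
        DomainDefinition(entry_id, 1, [d1_seg], f"{host_styles[0]}/{entry_id}.1",
                         chain.resolution),
        DomainDefinition(entry_id, 2, [d2_seg], f"{host_styles[1]}/{entry_id}.2",
                         chain.resolution),
    ]
    bare = ChainStructure(
        entry_id=entry_id, residues=chain.residues,
        missing_ranges=chain.missing_ranges, resolution=chain.resolution,
    )
    chain = apply_domain_definitions(bare, defs)

    dom1, dom2 = chain.domains
    # the assembled chain shares atom-list objects with the moved patch
    # residues: recover each planted residue's ordinal by identity
    atoms_to_source = {}
    for k, i in enumerate(source.side_a):
        atoms_to_source[id(moved_a[k].atoms)] = ("a", i)
    for k, j in enumerate(source.side_b):
        atoms_to_source[id(moved_b[k].atoms)] = ("b", j)
    truth_pairs = []
    for side_name, dom in (("a", dom1), ("b", dom2)):
        for ordinal, r in enumerate(dom.residues):
            src = atoms_to_source.get(id(r.atoms))
            if src is not None:
                truth_pairs.append(
                    {"source": list(src), "planted": [side_name, ordinal]}
                )
    truth = {
        "source_pair_id": source.pair_id,
        "noise_sigma": noise_sigma,
        "correspondence": truth_pairs,
        "n_planted": len(truth_pairs),
    }
    return GeneratedEntry(chain=chain, truth=truth)


# ---------------------------------------------------------------------------
# Sequence families


def make_sequence_family(
    ancestor_length: int, n_members: int, target_identity: float, seed: int
) -> list[str]:
    """Sequences derived from one random ancestor by point substitutions so
    each member's identity to the ancestor is ``target_identity`` (±2%)."""
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    ancestor = random_sequence(ancestor_length, rng)
    members = [ancestor]
    n_mut = int(round((1 - target_identity) * ancestor_length))
    for _ in range(n_members - 1):
        seq = list(ancestor)
        sites = rng.choice(ancestor_length, size=n_mut, replace=False)
        for s in sites:
            choices = [a for a in AA20 if a != seq[s]]
            seq[s] = choices[int(rng.integers(len(choices)))]
        members.append("".join(seq))
    return members


# ---------------------------------------------------------------------------
# Benchmark corpus


def make_benchmark_suite(
    out_dir: str | Path,
    seed: int = 0,
    n_decoys: int = 50,
    n_planted: int = 20,
    planted_sigmas: tuple[float, ...] = (0.0, 0.25, 0.5),
    target_L: int = 26,
) -> dict:
    """Write a complete on-disk corpus: PDB files, a domain table, FASTA
    sequences and a truth JSON.

    Contents: one source entry, ``n_decoys`` decoy two-domain entries
    (mutually unrelated styles/folds — the significance null), ``n_planted``
    entries carrying a noisy copy of the source interface, one discontinuous
    entry, one 3-domain entry, and a couple of low-resolution entries to
    exercise the resolution filter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "entries": {}}
    all_defs = []
    fasta: dict[str, str] = {}

    def emit(entry: GeneratedEntry, tag: str):
        chain = entry.chain
        (out / f"{chain.entry_id}.pdb").write_text(write_pdb(chain))
        for dom in chain.domains:
            if dom.definition not in all_defs:
                all_defs.append(dom.definition)
            fasta[dom.domain_id] = dom.sequence
        manifest["entries"][chain.entry_id] = {"kind": tag, "truth": entry.truth}

    def with_retries(build, n_attempts: int = 12) -> GeneratedEntry:
        """The placement searches are stochastic and can exhaust for an
        unlucky sub-seed; drawing a fresh sub-seed keeps the corpus
        deterministic in the top-level seed."""
        last = None
        for _ in range(n_attempts):
            sub_seed = int(rng.integers(2**31))
            try:
                return build(sub_seed)
            except RuntimeError as exc:
                last = exc
        raise RuntimeError(f"corpus entry failed after {n_attempts} attempts: "
                           f"{last}")

    source = with_retries(lambda s: make_domain_pair(
        SyntheticSpec(seed=s, interface_contact_target=target_L),
        entry_id="SRC1_A",
    ))
    emit(source, "source")
    d1, d2 = source.chain.domains
    src_iface = build_interface(d1, d2)

    styles = list(STYLES)
    for i in range(n_decoys):
        sa, sb = styles[i % 3], styles[(i + 1) % 3]
        entry = with_retries(lambda s: make_domain_pair(
            SyntheticSpec(seed=s, interface_contact_target=target_L),
            entry_id=f"DEC{i:02d}_A", style_a=sa, style_b=sb,
        ))
        emit(entry, "decoy")

    sig_cycle = [planted_sigmas[i % len(planted_sigmas)] for i in range(n_planted)]
    for i, sigma in enumerate(sig_cycle):
        entry = with_retries(lambda s: plant_similar_interface(
            src_iface, noise_sigma=sigma, seed=s, entry_id=f"PLT{i:02d}_A",
        ))
        emit(entry, "planted")

    emit(with_retries(lambda s: make_discontinuous_entry(s, "DIS1_A")),
         "discontinuous")
    emit(with_retries(lambda s: make_multidomain_chain(s, "MUL1_A")),
         "multidomain")
    for i in range(2):
        entry = with_retries(lambda s: make_domain_pair(
            SyntheticSpec(seed=s, interface_contact_target=target_L),
            entry_id=f"LOW{i}_A", resolution=2.6 + 0.2 * i,
        ))
        emit(entry, "low_resolution")

    write_domain_table(all_defs, out / "domains.tsv")
    write_fasta(fasta, out / "sequences.fasta")
    (out / "truth.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
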