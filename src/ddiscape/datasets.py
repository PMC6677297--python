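"""Dataset construction: pair enumeration, non-redundancy, template libraries.

Four pair classes are enumerated from annotated chains:

* CC-2 — consecutive continuous pairs from 2-domain entries;
* CC-M — consecutive continuous pairs from entries with >= 3 domains;
* CU-M — all interacting continuous pairs (consecutive or not) from
  >= 3-domain entries;
* CD-2 — 2-domain entries with at least one discontinuous domain, each
  discontinuous domain represented by its major segment.

Retained pairs must interact (>= 20 interfacial residues) and, when the
entry's resolution is known, satisfy the <= 2.5 Å crystal-structure filter.

Non-redundancy works at the domain level: domains are greedily clustered at
40% sequence identity (CD-HIT-style), then for every cluster pair (i < j)
the entries common to both clusters (with different domain numbers)
contribute at most one representative per domain order — the one with the
best resolution, then the longest total length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .align import tm_score_domains
from .interfaces import DomainInterface, build_interface, is_interacting_pair
from .structures import ChainStructure, DomainInstance, classify_continuity, \
    is_consecutive_pair, select_major_segment

PAIR_CLASSES = ("CC-2", "CC-M", "CU-M", "CD-2", "PPI")


@dataclass
class DomainPairRecord:
    entry_id: str
    domain_a: DomainInstance
    domain_b: DomainInstance
    pair_class: str
    interface: DomainInterface
    resolution: float
    seq_a: str = ""  # clustering sequence (major segment for discontinuous)
    seq_b: str = ""

    def __post_init__(self) -> None:
        if self.pair_class not in PAIR_CLASSES:
            raise ValueError(f"unknown pair class {self.pair_class!r}")
        if not self.seq_a:
            self.seq_a = self.domain_a.sequence
        if not self.seq_b:
            self.seq_b = self.domain_b.sequence

    @property
    def pair_id(self) -> str:
        return f"{self.domain_a.domain_id}|{self.domain_b.domain_id}"

    @property
    def total_length(self) -> int:
        return self.domain_a.length + self.domain_b.length


@dataclass
class SequenceCluster:
    cluster_id: int
    members: list[tuple[str, int]]  # (entry_id, domain_number)
    representative: tuple[str, int]

    def __post_init__(self) -> None:
        if not self.members or self.representative not in self.members:
            raise ValueError("cluster needs members incl. its representative")


@dataclass
class TemplateLibrary:
    query: DomainPairRecord
    templates: list[DomainPairRecord]
    filters_applied: dict = field(default_factory=dict)


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -2.0
_aligner.extend_gap_score = -0.5


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Percent identity over the global alignment length (match 1,
    mismatch 0, affine gaps)."""
    if not seq1 or not seq2:
        raise ValueError("empty sequence")
    aln = _aligner.align(seq1, seq2)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def cluster_domains(
    domains: list[tuple[str, int, str]],
    identity_threshold: float = 40.0,
    identity_fn=pairwise_identity,
) -> list[SequenceCluster]:
    """Greedy incremental clustering at the identity threshold (inclusive).

    ``domains``: (entry_id, domain_number, sequence) triples. Processing
    order is by decreasing sequence length (CD-HIT convention); a domain
    joins the first cluster whose representative is at >= threshold
    identity, else founds a new cluster. Clusters are numbered 1..N.
    """
    order = sorted(domains, key=lambda d: (-len(d[2]), d[0], d[1]))
    clusters: list[dict] = []
    for entry, num, seq in order:
        for c in clusters:
            if identity_fn(c["rep_seq"], seq) >= identity_threshold:
                c["members"].append((entry, num))
                break
        else:
            clusters.append({"rep_seq": seq, "rep": (entry, num),
                             "members": [(entry, num)]})
    return [
        SequenceCluster(cluster_id=k + 1, members=c["members"],
                        representative=c["rep"])
        for k, c in enumerate(clusters)
    ]


def select_nonredundant_pairs(
    clusters: list[SequenceCluster],
    records: list[DomainPairRecord],
    resolution_first: bool = True,
) -> list[DomainPairRecord]:
    """Domain-level non-redundant pair selection over cluster combinations.

    For every cluster pair (i < j): entries present in both clusters with
    different domain numbers are candidates; zero candidates select nothing,
    one selects itself, several select the best resolution / longest length
    representative — separately per domain order, since a pair occurring in
    reversed domain order counts as a distinct interface.
    """
    member_cluster: dict[tuple[str, int], int] = {}
    for c in clusters:
        for m in c.members:
            member_cluster[m] = c.cluster_id

    by_key: dict[tuple[str, int, int], DomainPairRecord] = {}
    entry_base = {}
    for rec in records:
        na = rec.domain_a.definition.domain_number
        nb = rec.domain_b.definition.domain_number
        ka = (rec.entry_id, na)
        kb = (rec.entry_id, nb)
        if ka not in member_cluster or kb not in member_cluster:
            raise ValueError(f"record {rec.pair_id}: domains not clustered")
        by_key[(rec.entry_id, na, nb)] = rec
        entry_base.setdefault(rec.entry_id, rec)

    def sort_key(rec: DomainPairRecord):
        if resolution_first:
            return (rec.resolution, -rec.total_length, rec.entry_id)
        return (-rec.total_length, rec.resolution, rec.entry_id)

    selected: dict[str, DomainPairRecord] = {}
    cluster_by_id = {c.cluster_id: c for c in clusters}
    ids = sorted(cluster_by_id)
    for i in ids:
        for j in ids:
            if not i < j:
                continue
            ci, cj = cluster_by_id[i], cluster_by_id[j]
            entries_i = {e: n for e, n in ci.members}
            candidates: dict[str, list[DomainPairRecord]] = {"fwd": [], "rev": []}
            for e, nj in cj.members:
                ni = entries_i.get(e)
                if ni is None or ni == nj:
                    continue
                rec = by_key.get((e, ni, nj))
                if rec is not None:
                    candidates["fwd"].append(rec)
                rec_r = by_key.get((e, nj, ni))
                if rec_r is not None:
                    candidates["rev"].append(rec_r)
            for group in candidates.values():
                if group:
                    best = min(group, key=sort_key)
                    selected[best.pair_id] = best
    return sorted(selected.values(), key=lambda r: r.pair_id)


def _pair_record(
    chain: ChainStructure,
    dom_a: DomainInstance,
    dom_b: DomainInstance,
    pair_class: str,
    contact_cutoff: float,
    min_interface_residues: int,
) -> DomainPairRecord | None:
    iface = build_interface(dom_a, dom_b, contact_cutoff)
    if not is_interacting_pair(iface, min_interface_residues):
        return None
    seq_a, seq_b = dom_a.sequence, dom_b.sequence
    if pair_class == "CD-2":
        for dom, attr in ((dom_a, "seq_a"), (dom_b, "seq_b")):
            if classify_continuity(dom) == "discontinuous":
                seg = select_major_segment(
                    dom, iface, min_interface_residues=min_interface_residues
                )
                if seg is None:
                    return None
                seq = "".join(
                    r.aa for r in dom.residues if seg.contains(r.seq_index)
                )
                if attr == "seq_a":
                    seq_a = seq
                else:
                    seq_b = seq
    return DomainPairRecord(
        entry_id=chain.entry_id,
        domain_a=dom_a,
        domain_b=dom_b,
        pair_class=pair_class,
        interface=iface,
        resolution=chain.resolution,
        seq_a=seq_a,
        seq_b=seq_b,
    )


def enumerate_pairs(
    entries: list[ChainStructure],
    mode: str,
    contact_cutoff: float = 4.5,
    min_interface_residues: int = 20,
    max_missing_linker: int = 13,
    resolution_max: float = 2.5,
) -> list[DomainPairRecord]:
    """Enumerate interacting domain pairs of one dataset class (see module
    docstring). Entries with a known resolution above ``resolution_max``
    are excluded."""
    if mode not in ("CC-2", "CC-M", "CU-M", "CD-2"):
        raise ValueError(f"unknown enumeration mode {mode!r}")
    out: list[DomainPairRecord] = []
    for chain in entries:
        if chain.resolution == chain.resolution and chain.resolution > resolution_max:
            continue
        doms = chain.domains
        n = len(doms)
        if mode in ("CC-2", "CD-2") and n != 2:
            continue
        if mode in ("CC-M", "CU-M") and n < 3:
            continue
        continuous = [classify_continuity(d) == "continuous" for d in doms]
        if mode in ("CC-2", "CC-M"):
            for a, b in zip(range(n), range(1, n)):
                if not (continuous[a] and continuous[b]):
                    continue
                if not is_consecutive_pair(chain, doms[a], doms[b],
                                           max_missing_linker):
                    continue
                rec = _pair_record(chain, doms[a], doms[b], mode,
                                   contact_cutoff, min_interface_residues)
                if rec:
                    out.append(rec)
        elif mode == "CU-M":
            for a in range(n):
                for b in range(a + 1, n):
                    if not (continuous[a] and continuous[b]):
                        continue
                    rec = _pair_record(chain, doms[a], doms[b], mode,
                                       contact_cutoff, min_interface_residues)
                    if rec:
                        out.append(rec)
        else:  # CD-2
            if all(continuous):
                continue
            rec = _pair_record(chain, doms[0], doms[1], "CD-2",
                               contact_cutoff, min_interface_residues)
            if rec:
                out.append(rec)
    return out


def representative_for_protein(
    candidates: list[ChainStructure], resolution_first: bool = True
) -> ChainStructure:
    """Best-resolution (then longest, then lexicographic id) entry."""
    if not candidates:
        raise ValueError("no candidates")

    def key(c: ChainStructure):
        if resolution_first:
            return (c.resolution, -c.length, c.entry_id)
        return (-c.length, c.resolution, c.entry_id)

    return min(candidates, key=key)


def build_template_library(
    query: DomainPairRecord,
    pool: list[DomainPairRecord],
    tm_threshold: float = 0.4,
    identity_surrogate_threshold: float = 25.0,
    tm_fn=tm_score_domains,
    identity_fn=pairwise_identity,
) -> TemplateLibrary:
    """Structurally-unrelated templates for one query.

    A pool member survives iff, against BOTH query domains (all four
    cross-domain combinations): (a) no shared fold label, (b) sequence
    identity below the surrogate threshold (stand-in for a database
    E-value > 1 rule), (c) TM-score below ``tm_threshold``. ``tm_fn=None``
    skips rule (c) (e.g. when the pool is unrelated by construction or
    scores are cached elsewhere).
    """
    q_folds = {query.domain_a.fold_label, query.domain_b.fold_label}
    q_doms = (query.domain_a, query.domain_b)
    q_seqs = (query.seq_a, query.seq_b)
    templates = []
    trace: dict[str, str] = {}
    for cand in pool:
        if cand.entry_id == query.entry_id:
            trace[cand.pair_id] = "self"
            continue
        c_folds = {cand.domain_a.fold_label, cand.domain_b.fold_label}
        if q_folds & c_folds:
            trace[cand.pair_id] = "fold"
            continue
        c_seqs = (cand.seq_a, cand.seq_b)
        if any(identity_fn(qs, cs) >= identity_surrogate_threshold
               for qs in q_seqs for cs in c_seqs):
            trace[cand.pair_id] = "sequence"
            continue
        if tm_fn is not None:
            c_doms = (cand.domain_a, cand.domain_b)
            if any(tm_fn(qd, cd) >= tm_threshold
                   for qd in q_doms for cd in c_doms):
                trace[cand.pair_id] = "tm_score"
                continue
        trace[cand.pair_id] = "pass"
        templates.append(cand)
    return TemplateLibrary(
        query=query,
        templates=templates,
        filters_applied={
            "fold_rule": "no shared fold label",
            "sequence_rule": f"identity < {identity_surrogate_threshold}%",
            "structure_rule": (
                f"TM-score < {tm_threshold}" if tm_fn is not None else "skipped"
            ),
            "trace": trace,
        },
    )
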