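"""Reading and writing the pipeline's file formats.

Coordinates travel as standard PDB text (parsed with Bio.PDB); domain
delineations as a TSV table (entry_id, chain, domain_number, segments,
fold_label, resolution) where ``segments`` is "start-end[,start-end]";
sequences as FASTA.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structures import (
    AA3_TO_1,
    Atom,
    ChainStructure,
    DomainDefinition,
    Residue,
    ResidueID,
    Segment,
)

_WATER = {"HOH", "WAT", "DOD"}


def parse_structure(pdb_text: str, chain_id: str) -> ChainStructure:
    """Parse one chain from PDB-format text into a :class:`ChainStructure`.

    Residues keep author numbering (with insertion codes) in file order.
    Hydrogens are retained but flagged non-heavy. HETATM waters and ligands
    without a Cα are dropped; modified residues with a Cα (e.g. MSE) stay.
    Altloc conflicts resolve to the highest-occupancy conformer (Bio.PDB's
    default). ``missing_ranges`` merges REMARK 465 annotations with
    author-numbering gaps.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            structure = parser.get_structure("entry", io.StringIO(pdb_text))
        except Exception as exc:  # surfaced with parser context
            raise ValueError(f"unreadable PDB records: {exc}") from exc
    model = next(iter(structure), None)
    if model is None or chain_id not in [c.id for c in model]:
        raise KeyError(f"chain {chain_id!r} not present in structure")
    chain = model[chain_id]

    residues: list[Residue] = []
    for res in chain:
        hetflag, resseq, icode = res.id
        resname = res.get_resname().strip()
        if resname in _WATER:
            continue
        if hetflag.strip() and "CA" not in res:
            continue  # ligand/ion
        atoms: list[Atom] = []
        ca = None
        for at in res.get_atoms():  # DisorderedAtom yields selected altloc
            a = Atom(
                name=at.get_name(),
                element=(at.element or at.get_name()[0]).strip() or "C",
                coord=at.get_coord(),
            )
            atoms.append(a)
            if at.get_name() == "CA":
                ca = a
        if not atoms:
            continue
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_index=ResidueID(resseq, icode.strip()),
                aa=AA3_TO_1.get(resname, "X"),
                atoms=atoms,
                ca=ca,
            )
        )

    missing: list[Segment] = []
    header_missing = structure.header.get("missing_residues") or []
    annotated = sorted(
        m["ssseq"] for m in header_missing if m.get("chain") == chain_id
    )
    for num in annotated:
        if missing and missing[-1].end == num - 1:
            missing[-1] = Segment(chain_id, missing[-1].start, num)
        else:
            missing.append(Segment(chain_id, num, num))
    # numbering gaps not covered by REMARK 465
    covered = set()
    for seg in missing:
        covered.update(range(seg.start, seg.end + 1))
    for r1, r2 in zip(residues, residues[1:]):
        gap = range(r1.seq_index.number + 1, r2.seq_index.number)
        run: list[int] = []
        for num in gap:
            if num in covered:
                continue
            run.append(num)
        if run:
            missing.append(Segment(chain_id, run[0], run[-1]))
    missing.sort(key=lambda s: s.start)

    res_str = structure.header.get("resolution")
    return ChainStructure(
        entry_id=f"{structure.id}_{chain_id}" if structure.id != "entry" else chain_id,
        residues=residues,
        missing_ranges=missing,
        resolution=float(res_str) if res_str is not None else float("nan"),
    )


def write_pdb(chain: ChainStructure, chain_id: str = "A") -> str:
    """Serialize a chain as PDB text (ATOM records + REMARK 465)."""
    lines: list[str] = []
    if chain.missing_ranges:
        lines.append("REMARK 465   M RES C SSSEQI")
        for seg in chain.missing_ranges:
            for num in range(seg.start, seg.end + 1):
                lines.append(f"REMARK 465     GLY {chain_id}{num:6d}")
    one_to_three = {v: k for k, v in AA3_TO_1.items()}
    serial = 1
    for res in chain.residues:
        resname = one_to_three.get(res.aa, "UNK")
        for atom in res.atoms:
            x, y, z = atom.coord
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} {chain_id}"
                f"{res.seq_index.number:4d}{res.seq_index.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def format_segments(segments: list[Segment]) -> str:
    return ",".join(f"{s.start}-{s.end}" for s in segments)


def parse_segments(text: str, chain_id: str) -> list[Segment]:
    segs = []
    for part in text.split(","):
        start, end = part.split("-")
        segs.append(Segment(chain_id, int(start), int(end)))
    return segs


def write_domain_table(defs: list[DomainDefinition], path: str | Path) -> None:
    """TSV: entry_id, chain, domain_number, segments, fold_label, resolution."""
    with open(path, "w") as fh:
        fh.write("entry_id\tchain\tdomain_number\tsegments\tfold_label\tresolution\n")
        for d in defs:
            chain = d.entry_id[-1]
            fh.write(
                f"{d.entry_id}\t{chain}\t{d.domain_number}\t"
                f"{format_segments(d.segments)}\t{d.fold_label}\t{d.resolution:.2f}\n"
            )


def read_domain_table(path: str | Path) -> list[DomainDefinition]:
    defs = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("entry_id"):
            raise ValueError(f"{path}: missing domain-table header")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                entry, chain, num, segs, fold, res = line.split("\t")
                defs.append(
                    DomainDefinition(
                        entry_id=entry,
                        domain_number=int(num),
                        segments=parse_segments(segs, chain),
                        fold_label=fold,
                        resolution=float(res),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{ln}: bad domain record: {exc}") from exc
    return defs


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
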