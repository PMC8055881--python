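"""PDB structure parsing, chain quality control, and residue mapping.

Atom coordinates come from Bio.PDB (alternate locations resolved to the
highest-occupancy conformer; hydrogens and heteroatoms excluded).  DBREF and
SEQADV header records — which Bio.PDB does not expose — are read from their
fixed columns.  A vertex position on the transcript-encoded protein is taken
to be UniProt numbering and is converted to PDB author numbering by the
constant DBREF offset; a residue-identity check then eliminates sites whose
mapped structure residue disagrees with the expected amino acid, mirroring
the known failure mode where uploader-provided offsets are wrong (e.g. a
Valine found where a Threonine is expected).
"""
from __future__ import annotations

import hashlib
import io
import logging
import warnings

from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SeqUtils import seq1

from .types import (
    ChainModel,
    ChainQC,
    MappedVertex,
    MapStatus,
    QCReport,
    SiteVertex,
    StructureModel,
)

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    pass


def _parse_dbref(line: str) -> tuple[str, str, int, int, int, int]:
    """DBREF fixed columns -> (chain, accession, pdb_start, pdb_end, db_start, db_end)."""
    chain = line[12].strip()
    pdb_start = int(line[14:18])
    pdb_end = int(line[20:24])
    accession = line[33:41].strip()
    db_start = int(line[55:60])
    db_end = int(line[62:67])
    return chain, accession, pdb_start, pdb_end, db_start, db_end


def _parse_seqadv(line: str) -> tuple[str, str, str]:
    """SEQADV fixed columns -> (chain, residue description, conflict comment)."""
    res_name = line[12:15].strip()
    chain = line[16].strip()
    seq_num = line[18:22].strip()
    comment = line[49:].strip()
    return chain, f"{res_name} {seq_num}".strip(), comment


def parse_structure(pdb_text: str, pdb_id: str | None = None) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Raises :class:`StructureError` if the text contains no ATOM record.
    Chains lacking a DBREF record are retained but cannot be mapped.
    """
    if "ATOM" not in pdb_text:
        raise StructureError("no ATOM records in input")

    dbrefs: dict[str, tuple[str, int, int, int, int]] = {}
    seqadvs: dict[str, list[tuple[str, str]]] = {}
    header_id = None
    for line in pdb_text.splitlines():
        rec = line[:6].strip()
        if rec == "HEADER" and len(line) >= 66:
            header_id = line[62:66].strip()
        elif rec == "DBREF":
            chain, acc, ps, pe, ds, de = _parse_dbref(line)
            dbrefs[chain] = (acc, ps, pe, ds, de)
        elif rec == "SEQADV":
            chain, residue, comment = _parse_seqadv(line)
            seqadvs.setdefault(chain, []).append((residue, comment))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure(pdb_id or header_id or "XXXX", io.StringIO(pdb_text))

    chains: list[ChainModel] = []
    model = next(structure.get_models())
    for bio_chain in model:
        residues: dict[int, tuple[str, list[tuple[float, float, float]]]] = {}
        for res in bio_chain:
            if res.id[0] != " ":  # heteroatoms / waters
                continue
            atoms = [
                tuple(float(c) for c in atom.coord)
                for atom in res.get_atoms()  # disordered atoms yield the highest-occupancy altloc
                if atom.element not in ("H", "D")
            ]
            if atoms:
                residues[res.id[1]] = (res.resname, atoms)
        if not residues:
            continue
        cid = bio_chain.id
        if cid not in dbrefs:
            logger.warning("chain %s has no DBREF record; retained but unmappable", cid)
        chains.append(ChainModel(
            chain_id=cid,
            residues=residues,
            dbref=dbrefs.get(cid),
            seqadv_flags=seqadvs.get(cid, []),
        ))
    if not any(ch.residues for ch in chains):
        raise StructureError("no polymer residues with atoms")

    model_out = StructureModel(
        pdb_id=(pdb_id or header_id or "XXXX").upper(),
        chains=chains,
        source_text_hash=hashlib.sha256(pdb_text.encode()).hexdigest()[:16],
    )
    model_out.validate()
    return model_out


def _seqadv_net_length_change(flags: list[tuple[str, str]]) -> int:
    net = 0
    for _, comment in flags:
        up = comment.upper()
        if "INSERTION" in up:
            net += 1
        elif "DELETION" in up:
            net -= 1
    return net


def filter_chains(model: StructureModel) -> tuple[StructureModel, QCReport]:
    """Apply chain-level QC; dropped chains are excluded from all pairing.

    A chain is dropped when (1) its DBREF PDB-range length disagrees with the
    UniProt-range length after accounting for SEQADV insertions/deletions, or
    (2) any of its SEQADV records cites REMARK 999 (absent residues explained
    only by free text).  Pure filter: idempotent, never raises.
    """
    report = QCReport()
    for chain in model.chains:
        if chain.qc_status is not ChainQC.PASS:
            report.add(chain.qc_status.value)
            continue
        if any("REMARK 999" in comment.upper() for _, comment in chain.seqadv_flags):
            chain.qc_status = ChainQC.DROPPED_REMARK999
            report.add(ChainQC.DROPPED_REMARK999.value)
            continue
        if chain.dbref is not None:
            _, ps, pe, ds, de = chain.dbref
            pdb_len = pe - ps + 1
            db_len = de - ds + 1
            if pdb_len != db_len + _seqadv_net_length_change(chain.seqadv_flags):
                chain.qc_status = ChainQC.DROPPED_DBREF_INCONSISTENT
                report.add(ChainQC.DROPPED_DBREF_INCONSISTENT.value)
                continue
        report.add(ChainQC.PASS.value)
    return model, report


def map_vertex(
    vertex: SiteVertex,
    chain: ChainModel,
    pdb_id: str,
    transcript_map: dict[str, str],
) -> MappedVertex:
    """Place one vertex on one QC-passing chain.

    Returns map_status ``ok`` only when the transcript links to the chain's
    UniProt accession, the position falls inside the DBREF interval, the
    structure residue is resolved, and its amino acid matches the vertex's
    expected residue.
    """
    def _fail(status: MapStatus, resnum=None, resname=None) -> MappedVertex:
        return MappedVertex(vertex=vertex, pdb_id=pdb_id, chain_id=chain.chain_id,
                            structure_residue=resnum, mapped_residue_name=resname,
                            map_status=status)

    accession = transcript_map.get(vertex.transcript)
    if accession is None or chain.dbref is None or accession != chain.dbref[0]:
        return _fail(MapStatus.UNMAPPED)
    _, ps, pe, ds, de = chain.dbref
    if not (ds <= vertex.position <= de):
        return _fail(MapStatus.UNMAPPED)
    pdb_pos = vertex.position + chain.offset()
    if pdb_pos not in chain.residues:
        return _fail(MapStatus.UNMAPPED)
    resname, atoms = chain.residues[pdb_pos]
    if seq1(resname) != vertex.ref_residue:
        return _fail(MapStatus.ELIMINATED_RESIDUE_MISMATCH, pdb_pos, resname)
    return MappedVertex(
        vertex=vertex, pdb_id=pdb_id, chain_id=chain.chain_id,
        structure_residue=pdb_pos, mapped_residue_name=resname,
        map_status=MapStatus.OK, atoms=tuple(atoms),
    )


def map_vertices(
    vertices: list[SiteVertex],
    structures: list[StructureModel],
    transcript_map: dict[str, str],
) -> tuple[list[MappedVertex], QCReport]:
    """Map every vertex onto every QC-passing chain of every structure.

    Returns all mapping records (one per vertex x chain attempt that is not a
    trivial accession mismatch) plus a tally of outcomes.
    """
    out: list[MappedVertex] = []
    report = QCReport()
    for struct in structures:
        for chain in struct.chains:
            if chain.qc_status is not ChainQC.PASS:
                continue
            for v in vertices:
                mv = map_vertex(v, chain, struct.pdb_id, transcript_map)
                if mv.map_status is MapStatus.UNMAPPED and (
                    transcript_map.get(v.transcript) != (chain.dbref[0] if chain.dbref else None)
                ):
                    continue  # vertex simply belongs to another protein
                out.append(mv)
                report.add(mv.map_status.value)
    return out, report
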