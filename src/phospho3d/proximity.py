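"""Closest-atom 3D distances and proximity-pair construction.

Two vertices form a proximity pair when, on at least one structure where
both are resolved (same chain, or different chains of one co-crystallized
entry), the minimum Euclidean distance over all heavy-atom pairs of their
residues is within the cutoff.  The emitted distance is the minimum across
all such structures.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .types import MappedVertex, MapStatus, PairClass, ProximityPair, SiteVertex, VertexKind

logger = logging.getLogger(__name__)

PAIR_FILE_SUFFIX = {
    PairClass.MUT_MUT: ".pairwise",
    PairClass.MUT_SITE: ".musite",
    PairClass.SITE_SITE: ".sites",
}


def residue_min_distance(atoms_a, atoms_b) -> float:
    """Minimum Euclidean distance (Å) over all atom pairs of two residues."""
    if len(atoms_a) == 0:
        raise ValueError("residue A has no atoms")
    if len(atoms_b) == 0:
        raise ValueError("residue B has no atoms")
    return float(cdist(np.asarray(atoms_a, float), np.asarray(atoms_b, float)).min())


def _pair_class(a: SiteVertex, b: SiteVertex) -> PairClass:
    kinds = {a.kind, b.kind}
    if kinds == {VertexKind.MUTATION}:
        return PairClass.MUT_MUT
    if kinds == {VertexKind.PHOSPHOSITE}:
        return PairClass.SITE_SITE
    return PairClass.MUT_SITE


def build_pairs(
    mapped: list[MappedVertex],
    cutoff: float = 10.0,
    min_linear_separation: int = 0,
) -> list[ProximityPair]:
    """Emit proximity pairs from mapped vertices, collapsed across structures.

    A pair passes when its minimum closest-atom distance is <= ``cutoff`` and
    either the two vertices sit on different transcripts or their linear
    separation is >= ``min_linear_separation`` (0 disables the filter, the
    default).  Vertices are canonically ordered inside each pair so output
    is invariant under input order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    by_structure: dict[str, list[MappedVertex]] = {}
    for mv in mapped:
        if mv.map_status is MapStatus.OK:
            by_structure.setdefault(mv.pdb_id, []).append(mv)

    # (vertex key pair) -> (distance, structure label, cross_chain)
    best: dict[tuple, tuple[float, str, bool]] = {}
    identity: dict[tuple, SiteVertex] = {}
    for pdb_id, mvs in by_structure.items():
        mvs = sorted(mvs, key=lambda m: (m.vertex.key, m.chain_id))
        for i in range(len(mvs)):
            for j in range(i + 1, len(mvs)):
                va, vb = mvs[i].vertex, mvs[j].vertex
                if va.key == vb.key:
                    continue
                d = residue_min_distance(mvs[i].atoms, mvs[j].atoms)
                if d > cutoff:
                    continue
                ka, kb = sorted((va.key, vb.key))
                identity.setdefault(ka, va if va.key == ka else vb)
                identity.setdefault(kb, vb if vb.key == kb else va)
                label = f"{pdb_id}:{mvs[i].chain_id}{mvs[j].chain_id}"
                cross = mvs[i].chain_id != mvs[j].chain_id
                key = (ka, kb)
                if key not in best or d < best[key][0]:
                    best[key] = (d, label, cross)

    pairs: list[ProximityPair] = []
    for (ka, kb), (d, label, cross) in sorted(best.items()):
        a, b = identity[ka], identity[kb]
        if a.transcript == b.transcript:
            sep = abs(a.position - b.position)
            if sep < min_linear_separation:
                continue
        else:
            sep = None
        pairs.append(ProximityPair(
            a=a, b=b, distance_angstrom=d, best_structure=label,
            pair_class=_pair_class(a, b), linear_separation=sep, cross_chain=cross,
        ))
    return pairs


def write_pair_files(pairs: list[ProximityPair], out_prefix: str | Path) -> dict[PairClass, Path]:
    """Write pairs to three tab-delimited files by class.

    Mutation–site pairs go to ``<prefix>.musite``, site–site pairs to
    ``<prefix>.sites``, mutation–mutation pairs to ``<prefix>.pairwise``.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    header = ("gene_a\ttranscript_a\tpos_a\tlabel_a\t"
              "gene_b\ttranscript_b\tpos_b\tlabel_b\tdistance\tstructure\n")
    paths: dict[PairClass, Path] = {}
    for cls, suffix in PAIR_FILE_SUFFIX.items():
        path = out_prefix.with_suffix(out_prefix.suffix + suffix)
        with open(path, "w") as fh:
            fh.write(header)
            for p in pairs:
                if p.pair_class is not cls:
                    continue
                fh.write("\t".join([
                    p.a.gene, p.a.transcript, str(p.a.position), p.a.label,
                    p.b.gene, p.b.transcript, str(p.b.position), p.b.label,
                    f"{p.distance_angstrom:.4f}", p.best_structure,
                ]) + "\n")
        paths[cls] = path
    return paths
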