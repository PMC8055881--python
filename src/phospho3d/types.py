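"""Core domain types.

A *vertex* is a missense mutation or a phosphosite anchored to a residue
position on a transcript-encoded protein.  Vertices are mapped onto PDB
chains, paired by closest-atom 3D distance, and clustered on the resulting
proximity graph.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class VertexKind(enum.Enum):
    MUTATION = "mutation"
    PHOSPHOSITE = "phosphosite"


class ChainQC(enum.Enum):
    PASS = "pass"
    DROPPED_DBREF_INCONSISTENT = "dropped_dbref_inconsistent"
    DROPPED_REMARK999 = "dropped_remark999"


class MapStatus(enum.Enum):
    OK = "ok"
    ELIMINATED_RESIDUE_MISMATCH = "eliminated_residue_mismatch"
    UNMAPPED = "unmapped"


class PairClass(enum.Enum):
    MUT_MUT = "mut_mut"
    MUT_SITE = "mut_site"
    SITE_SITE = "site_site"


class ClusterType(enum.Enum):
    HYBRID = "hybrid"
    MUTATION_ONLY = "mutation_only"
    SITE_ONLY = "site_only"


class Relation(enum.Enum):
    DIRECT = "direct"
    PROXIMAL = "proximal"
    CLUSTERED = "clustered"


CANONICAL_PHOSPHO_RESIDUES = frozenset("STY")


@dataclass(frozen=True)
class SiteVertex:
    """A mutation or phosphosite vertex on the co-clustering graph.

    ``weight`` is the recurrence count: the number of distinct samples
    carrying the mutation, or 1 for phosphosites.
    """

    gene: str
    transcript: str
    position: int
    ref_residue: str
    kind: VertexKind
    alt_residue: str | None = None
    weight: int = 1
    description: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.weight < 1:
            raise ValueError(f"weight must be >= 1, got {self.weight}")
        if self.kind is VertexKind.MUTATION and not self.alt_residue:
            raise ValueError("mutation vertex requires alt_residue")
        if self.kind is VertexKind.PHOSPHOSITE and self.alt_residue:
            raise ValueError("phosphosite vertex must not carry alt_residue")

    @property
    def key(self) -> tuple:
        """Identity key: distinct alt alleles at one position are distinct vertices."""
        return (self.kind.value, self.transcript, self.position, self.alt_residue or "")

    @property
    def label(self) -> str:
        if self.kind is VertexKind.MUTATION:
            return f"p.{self.ref_residue}{self.position}{self.alt_residue}"
        return f"p.{self.ref_residue}{self.position}"


@dataclass
class ChainModel:
    """One chain of a PDB entry with author-numbered residues and heavy atoms."""

    chain_id: str
    # residue author_seq_number -> (residue_name, list of (x, y, z))
    residues: dict[int, tuple[str, list[tuple[float, float, float]]]]
    dbref: tuple[str, int, int, int, int] | None = None  # (uniprot, pdb_start, pdb_end, db_start, db_end)
    seqadv_flags: list[tuple[str, str]] = field(default_factory=list)  # (residue descr, reason)
    qc_status: ChainQC = ChainQC.PASS

    @property
    def uniprot(self) -> str | None:
        return self.dbref[0] if self.dbref else None

    def offset(self) -> int:
        """Constant author-numbering offset: pdb_pos = db_pos + offset."""
        if self.dbref is None:
            raise ValueError(f"chain {self.chain_id} has no DBREF record")
        _, pdb_start, _, db_start, _ = self.dbref
        return pdb_start - db_start


@dataclass
class StructureModel:
    pdb_id: str
    chains: list[ChainModel]
    source_text_hash: str = ""

    def chain(self, chain_id: str) -> ChainModel:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(chain_id)

    def validate(self) -> None:
        for ch in self.chains:
            if not ch.residues:
                raise ValueError(f"{self.pdb_id} chain {ch.chain_id} has no residues")
            for num, (_, atoms) in ch.residues.items():
                if not atoms:
                    raise ValueError(
                        f"{self.pdb_id} chain {ch.chain_id} residue {num} has no atoms"
                    )
                for xyz in atoms:
                    if not all(math.isfinite(c) for c in xyz):
                        raise ValueError(
                            f"non-finite coordinate in {self.pdb_id}/{ch.chain_id}/{num}"
                        )


@dataclass(frozen=True)
class MappedVertex:
    """A vertex placed on one structure chain, with the residue-identity check applied."""

    vertex: SiteVertex
    pdb_id: str
    chain_id: str
    structure_residue: int | None
    mapped_residue_name: str | None
    map_status: MapStatus
    atoms: tuple[tuple[float, float, float], ...] = ()


@dataclass(frozen=True)
class ProximityPair:
    """Two vertices co-resolved on >= 1 structure within the distance cutoff.

    ``distance_angstrom`` is the minimum closest-atom distance across all
    structures on which the pair is co-resolved; ``best_structure`` names the
    structure (and chains) achieving it.
    """

    a: SiteVertex
    b: SiteVertex
    distance_angstrom: float
    best_structure: str
    pair_class: PairClass
    linear_separation: int | None
    cross_chain: bool

    def __post_init__(self) -> None:
        if self.distance_angstrom < 0:
            raise ValueError("distance must be nonnegative")


@dataclass
class Cluster:
    """A connected component of the proximity graph with its closeness score.

    ``cc_score`` is the cluster closeness Cc = sum_i c(v_i) where
    c(v_i) = sum_{j != i} w_j * 2^(-g_ij / s); the centroid is the member of
    maximal centrality.
    """

    cluster_id: str
    members: list[SiteVertex]
    centralities: list[float]
    centroid: SiteVertex
    cc_score: float
    cluster_type: ClusterType
    rank_percentile_within_type: float | None = None

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({m.gene for m in self.members}))


@dataclass(frozen=True)
class SpatialRelation:
    """Linear-sequence relation of a co-clustered phosphosite to its mutations."""

    site: SiteVertex
    relation: Relation
    partners: tuple[SiteVertex, ...]


@dataclass
class QCReport:
    """Bookkeeping of retained vs eliminated items per elimination reason."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + n

    def total(self, *reasons: str) -> int:
        return sum(self.counts.get(r, 0) for r in reasons)
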