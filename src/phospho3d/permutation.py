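"""Permutation-null benchmarking of hybrid clusters.

The mutation backbone is held fixed while phosphosites are randomly
repositioned, per gene, at structure-covered S/T/Y candidate positions with
the observed residue-type counts preserved exactly.  The full pair+cluster
pipeline is rerun per simulation and observed hybrid-cluster closeness
scores are compared against the pooled null distribution at a percentile
threshold; ROC analysis sweeps the Cc threshold between observed and null
scores.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import seq1

from .clustering import find_clusters
from .proximity import build_pairs
from .structures import map_vertices
from .types import (
    CANONICAL_PHOSPHO_RESIDUES,
    ChainQC,
    ClusterType,
    SiteVertex,
    StructureModel,
    VertexKind,
)

logger = logging.getLogger(__name__)


@dataclass
class NullConfig:
    n_simulations: int = 100
    seed: int = 0
    gene_scope: list[str] | None = None  # genes to permute; None = all genes with sites
    percent_threshold: float = 5.0
    pooled: bool = True  # threshold from pooled null scores (per-simulation variant off)
    distance_cutoff: float = 10.0
    min_linear_separation: int = 0
    vertex_type: str = "recurrence"
    geodesic_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")


@dataclass
class NullEnsemble:
    null_scores: list[list[float]]  # hybrid-cluster Cc per simulation
    observed_scores: list[float]
    threshold_score: float
    observed_pass_fraction: float
    null_pass_fraction: float

    @property
    def pooled_null(self) -> np.ndarray:
        return np.concatenate([np.asarray(s) for s in self.null_scores]) \
            if any(self.null_scores) else np.array([])


def candidate_positions(
    transcript: str,
    structures: list[StructureModel],
    transcript_map: dict[str, str],
) -> list[tuple[int, str]]:
    """All S/T/Y protein positions of a transcript covered by >= 1 QC-passing chain."""
    accession = transcript_map.get(transcript)
    if accession is None:
        logger.warning("transcript %s absent from transcript map; no candidates", transcript)
        return []
    found: dict[int, str] = {}
    for struct in structures:
        for chain in struct.chains:
            if chain.qc_status is not ChainQC.PASS or chain.dbref is None:
                continue
            if chain.dbref[0] != accession:
                continue
            _, ps, pe, ds, de = chain.dbref
            off = chain.offset()
            for db_pos in range(ds, de + 1):
                pdb_pos = db_pos + off
                if pdb_pos not in chain.residues:
                    continue
                letter = seq1(chain.residues[pdb_pos][0])
                if letter in CANONICAL_PHOSPHO_RESIDUES:
                    found[db_pos] = letter
    if not found:
        logger.warning("transcript %s: no covered S/T/Y candidate positions", transcript)
    return sorted(found.items())


def permute_sites(
    observed: list[SiteVertex],
    candidates: list[tuple[int, str]],
    rng: np.random.Generator,
) -> list[SiteVertex]:
    """Redraw one gene's phosphosites at candidate positions, preserving the
    observed per-residue-type counts exactly (sampling without replacement)."""
    if not observed:
        return []
    gene, transcript = observed[0].gene, observed[0].transcript
    need: dict[str, int] = {}
    for s in observed:
        need[s.ref_residue] = need.get(s.ref_residue, 0) + 1
    out: list[SiteVertex] = []
    for res_type in sorted(need):
        pool = [pos for pos, letter in candidates if letter == res_type]
        k = need[res_type]
        if len(pool) < k:
            raise ValueError(
                f"gene {gene}: {len(pool)} candidate {res_type} positions "
                f"but {k} observed sites of that type")
        chosen = rng.choice(len(pool), size=k, replace=False)
        for idx in sorted(int(i) for i in chosen):
            out.append(SiteVertex(
                gene=gene, transcript=transcript, position=pool[idx],
                ref_residue=res_type, kind=VertexKind.PHOSPHOSITE,
                description="permuted"))
    return out


def _hybrid_scores(clusters) -> list[float]:
    return [c.cc_score for c in clusters if c.cluster_type is ClusterType.HYBRID]


def run_null(
    config: NullConfig,
    mutations: list[SiteVertex],
    sites: list[SiteVertex],
    structures: list[StructureModel],
    transcript_map: dict[str, str],
) -> NullEnsemble:
    """Run the full pair+cluster pipeline once on observed data and once per
    simulated phosphosite dataset; compare hybrid-cluster Cc distributions.

    The mutation backbone is mapped once and reused across simulations.
    Per-simulation RNG streams derive from ``config.seed`` by simulation
    index, so the ensemble is reproducible bit-for-bit and independent of
    execution order.
    """
    mapped_mut, _ = map_vertices(mutations, structures, transcript_map)

    sites_by_tx: dict[str, list[SiteVertex]] = {}
    for s in sites:
        sites_by_tx.setdefault(s.transcript, []).append(s)
    scope = set(config.gene_scope) if config.gene_scope is not None else {
        s.gene for s in sites}
    candidates = {
        tx: candidate_positions(tx, structures, transcript_map)
        for tx, group in sites_by_tx.items() if group[0].gene in scope
    }

    def _score(site_list: list[SiteVertex]) -> list[float]:
        mapped_sites, _ = map_vertices(site_list, structures, transcript_map)
        pairs = build_pairs(mapped_mut + mapped_sites,
                            cutoff=config.distance_cutoff,
                            min_linear_separation=config.min_linear_separation)
        clusters = find_clusters(pairs, vertex_type=config.vertex_type,
                                 geodesic_scale=config.geodesic_scale)
        return _hybrid_scores(clusters)

    observed_scores = _score(sites)

    streams = np.random.SeedSequence(config.seed).spawn(config.n_simulations)
    null_scores: list[list[float]] = []
    for sim_index, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        try:
            synthetic: list[SiteVertex] = []
            for tx, group in sites_by_tx.items():
                if group[0].gene in scope:
                    synthetic.extend(permute_sites(group, candidates[tx], rng))
                else:
                    synthetic.extend(group)
            null_scores.append(_score(synthetic))
        except Exception as exc:
            raise RuntimeError(f"simulation {sim_index} failed: {exc}") from exc

    pooled = np.concatenate([np.asarray(s) for s in null_scores if s]) \
        if any(null_scores) else np.array([0.0])
    threshold = float(np.percentile(pooled, 100.0 - config.percent_threshold))
    obs = np.asarray(observed_scores)
    return NullEnsemble(
        null_scores=null_scores,
        observed_scores=observed_scores,
        threshold_score=threshold,
        observed_pass_fraction=float(np.mean(obs > threshold)) if obs.size else 0.0,
        null_pass_fraction=float(np.mean(pooled > threshold)),
    )


def roc_curve(scores, labels) -> tuple[list[tuple[float, float, float]], float]:
    """ROC over Cc thresholds: returns [(threshold, sensitivity, specificity)]
    and the trapezoid AUC.  Labels must contain both classes."""
    from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc

    y = np.asarray(labels, dtype=bool)
    x = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    fpr, tpr, thresholds = _sk_roc(y.astype(int), x)
    points = [(float(t), float(se), float(1.0 - fp))
              for t, se, fp in zip(thresholds, tpr, fpr)]
    return points, float(roc_auc_score(y.astype(int), x))
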