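"""End-to-end orchestration: map vertices onto structures, build proximity
pairs, discover clusters, classify site relations, and write stage outputs
with a reproducibility manifest."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .clustering import Cluster, find_clusters, threshold_top_percent, write_cluster_table
from .io_tables import parse_mutation_table, parse_site_table, parse_transcript_map
from .proximity import ProximityPair, build_pairs, write_pair_files
from .structures import StructureError, filter_chains, map_vertices, parse_structure
from .types import QCReport, SiteVertex, StructureModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    structures_dir: str
    mutations: str
    sites: str
    transcript_map: str
    out_dir: str
    distance_cutoff: float = 10.0
    min_linear_separation: int = 0
    vertex_type: str = "recurrence"
    top_percent: float = 5.0
    geodesic_scale: float = 1.0
    seed: int = 0
    allow_noncanonical: bool = False

    def validate(self) -> None:
        for attr in ("structures_dir", "mutations", "sites", "transcript_map"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")
        if not 0 < self.top_percent <= 100:
            raise ValueError("top_percent must be in (0, 100]")
        if self.geodesic_scale <= 0:
            raise ValueError("geodesic_scale must be positive")


def load_structures(structures_dir: str | Path) -> list[StructureModel]:
    """Parse and QC-filter every ``*.pdb`` file in a directory (sorted order)."""
    models = []
    for path in sorted(Path(structures_dir).glob("*.pdb")):
        try:
            model = parse_structure(path.read_text(), pdb_id=path.stem)
        except Exception as exc:
            raise StructureError(f"{path.name}: {exc}") from exc
        filter_chains(model)
        models.append(model)
    if not models:
        raise FileNotFoundError(f"no .pdb files under {structures_dir}")
    return models


def cluster_dataset(
    mutations: list[SiteVertex],
    sites: list[SiteVertex],
    structures: list[StructureModel],
    transcript_map: dict[str, str],
    distance_cutoff: float = 10.0,
    min_linear_separation: int = 0,
    vertex_type: str = "recurrence",
    geodesic_scale: float = 1.0,
) -> tuple[list[ProximityPair], list[Cluster], QCReport]:
    """Core computation shared by the CLI pipeline and the permutation null."""
    mapped, report = map_vertices(mutations + sites, structures, transcript_map)
    pairs = build_pairs(mapped, cutoff=distance_cutoff,
                        min_linear_separation=min_linear_separation)
    clusters = find_clusters(pairs, vertex_type=vertex_type,
                             geodesic_scale=geodesic_scale)
    return pairs, clusters, report


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run map -> pair -> cluster -> classify and write all stage outputs.

    Returns the manifest (also written to ``manifest.json``); reruns with an
    identical config produce byte-identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {
            "mutations": _file_hash(config.mutations),
            "sites": _file_hash(config.sites),
            "transcript_map": _file_hash(config.transcript_map),
        },
        "stages": [],
    }

    def _finish(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})

    try:
        structures = load_structures(config.structures_dir)
        mutations = parse_mutation_table(config.mutations)
        sites = parse_site_table(config.sites,
                                 allow_noncanonical=config.allow_noncanonical)
        tx_map = parse_transcript_map(config.transcript_map)
        _finish("map", structures=len(structures), mutations=len(mutations),
                sites=len(sites))

        mapped, qc = map_vertices(mutations + sites, structures, tx_map)
        pairs = build_pairs(mapped, cutoff=config.distance_cutoff,
                            min_linear_separation=config.min_linear_separation)
        pair_paths = write_pair_files(pairs, out / "pairs")
        _finish("pair", n_pairs=len(pairs), qc=qc.counts,
                files={k.value: str(v) for k, v in pair_paths.items()})

        clusters = find_clusters(pairs, vertex_type=config.vertex_type,
                                 geodesic_scale=config.geodesic_scale)
        retained = threshold_top_percent(clusters, percent=config.top_percent)
        write_cluster_table(clusters, out / "clusters.tsv")
        write_cluster_table(retained, out / "clusters_top.tsv")
        _finish("cluster", n_clusters=len(clusters), n_retained=len(retained))

        from .stats import classify_spatial_relations, write_relation_table
        relations = classify_spatial_relations(clusters)
        write_relation_table(relations, out / "site_relations.tsv")
        _finish("classify", n_relations=len(relations))

        summary = {
            "n_pairs": len(pairs),
            "n_clusters": len(clusters),
            "n_clusters_by_type": {
                t: sum(1 for c in clusters if c.cluster_type.value == t)
                for t in ("hybrid", "mutation_only", "site_only")
            },
            "n_retained_top_percent": len(retained),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
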