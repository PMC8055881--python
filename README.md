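# phospho3d

Spatial co-clustering of phosphosites and missense mutations on 3D protein
structures.

Most phosphosites detected in large phosphoproteomic screens have unknown
function. One way to prioritize them is spatial context: a phosphosite that
sits next to recurrent cancer mutations on the folded protein — even when it
is far away in the linear sequence — is a strong candidate for functional
relevance. `phospho3d` finds such sites by mapping mutations and phosphosites
onto PDB structures, linking residue pairs whose closest heavy atoms lie
within a distance cutoff, and scoring the connected clusters of the
resulting proximity graph.

## Method

Mutations and phosphosites are vertices of an undirected graph *G* = (*V*, *E*)
whose edges are proximity pairs weighted by closest-atom 3D distance (Å).
For each connected component, all-pairs geodesics *g<sub>ij</sub>* are
computed with the Floyd–Warshall algorithm seeded by the edge-distance
matrix. Per-vertex centrality and the cluster closeness score are

    c(v_i) = Σ_{j≠i} w_j · 2^(−g_ij)          Cc = Σ_i c(v_i)

where *w<sub>j</sub>* is the vertex recurrence (number of samples carrying a
mutation; 1 for phosphosites) in the default recurrence-weighted mode. A
high Cc indicates a dense cluster of recurrent events. Clusters are typed as
*hybrid* (mutations and phosphosites), *mutation-only*, or *site-only*, and
the top 5% by Cc within each type are retained. A permutation null — the
mutation backbone fixed, phosphosites redrawn at structure-covered S/T/Y
positions with residue-type ratios preserved — benchmarks the hybrid
clusters, and downstream statistics (one-tailed Fisher enrichment with BH
FDR, one-sided rank-sum dependency tests, ecdf-percentile expression models)
interrogate the co-clustered sites. Co-clustered sites are classified as
*direct* (same residue as a mutation), *proximal* (within 2 residues
linearly), or *clustered* (3D proximity only).

## Worked example

The bundled generator plants a 3D hotspot on a synthetic helix: mutations
p.S40F (3 samples) and p.R90H (2 samples) plus phosphosites p.S40, p.T42 and
p.Y140 are forced into a 4 Å sphere, with decoy events scattered along the
helix more than 10 Å apart.

```
phospho3d simulate --kind hotspot --seed 0 --out fx
phospho3d run --structures fx/structures --mutations fx/mutations.tsv \
    --sites fx/sites.tsv --transcript-map fx/transcript_map.tsv --out out
phospho3d classify --structures fx/structures --mutations fx/mutations.tsv \
    --sites fx/sites.tsv --transcript-map fx/transcript_map.tsv \
    --out out/relations.tsv
```

The classify step prints

```
{
  "clustered": 1,
  "direct": 1,
  "proximal": 1
}
```

i.e. the pipeline recovers one hybrid cluster (Cc = 7.159) holding all five
planted vertices, with p.S40 directly overlapping its mutation, p.T42 two
residues away (proximal), and p.Y140 — 100 residues from position 40 in the
sequence — detected only through 3D structure ("clustered"). The decoys form
no clusters. `out/clusters.tsv` lists every member with its centrality,
centroid flag, Cc and within-type rank percentile.

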