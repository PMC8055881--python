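# Methods

## Model

Missense mutations and phosphosites are vertices anchored to residue
positions on transcript-encoded proteins. After mapping onto PDB chains,
two vertices co-resolved on at least one structure (same chain, or two
chains of one co-crystallized entry) form a proximity pair if the minimum
Euclidean distance over all heavy-atom pairs of their residues is within a
cutoff. Each connected component of the proximity graph is scored by

- geodesics `g_ij`: Floyd–Warshall all-pairs shortest paths over the
  edge-distance matrix (Å);
- centrality `c(v_i) = Σ_{j≠i} w_j · 2^(−g_ij/s)`;
- cluster closeness `Cc = Σ_i c(v_i)`; the centroid is the member of
  maximal centrality.

Assumptions worth making explicit: distances are taken from static crystal
structures (no conformational ensembles); pairs across different PDB
entries are never formed (no docking); the minimum distance across all
structures is the edge weight, which favors the most compact observed
conformation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `distance_cutoff` | 10.0 Å | closest-atom edge cutoff. Not printed in the method's source description; 10 Å is the standard contact-shell scale of this tool family and is exposed as `--distance-cutoff`. |
| `min_linear_separation` | 0 (off) | optional exclusion of same-transcript pairs closer than k residues in sequence; hotspot tools often use one, so it stays tunable. |
| `vertex_type` | `recurrence` | `recurrence` weighs each mutation by the number of carrying samples (phosphosites weigh 1); `site` is unweighted. |
| `geodesic_scale` s | 1.0 | exponent scale in `2^(−g/s)`. The printed formula uses the geodesic directly, which with Å distances makes 2^(−g) terms small; s is an explicit knob because the original unit convention is not recoverable. Default keeps the formula as printed. |
| `top_percent` | 5 | per-type retention quantile, the calibration the permutation benchmark supports. |
| permutation `n_simulations` | 100 | simulated phosphosite datasets per null run. |

## Numerical and design choices

- **Edge weights may be exactly 0.** A mutation and a phosphosite at the
  same residue are distinct vertices at closest-atom distance 0 (the
  "direct" relation); a 0-weight edge contributes 2^0 = 1 to centrality.
- **Cluster seeding.** Candidate clusters are exactly the connected
  components of the cutoff-filtered proximity graph — the simplest
  construction consistent with edges being the set of proximal pairs.
  IDs are `<gene-or-complex index>.<subindex>` assigned in deterministic
  sorted order.
- **Percentile rule.** Retention uses the empirical `(100−p)`th percentile
  (`numpy.percentile`, linear interpolation) with ties at the threshold
  kept. Historical cluster counts obtained with other rounding conventions
  are not reproduced by design.
- **Ties.** Centroid ties break toward the lower transcript position, then
  the lexicographically smaller gene symbol. Rank-sum tests use the exact
  null only for tie-free samples of combined size ≤ 20, otherwise the
  normal approximation with mid-ranks and tie correction.
- **Floating point.** Score identities (Cc vs member re-summation) are
  asserted at 1e−9 relative tolerance.
- **Chain QC.** A chain is dropped when its DBREF PDB-range length differs
  from the UniProt-range length after SEQADV insertion/deletion accounting,
  or when a SEQADV record cites REMARK 999. Mapping uses the constant DBREF
  offset; mapped residues whose amino acid disagrees with the expected
  residue are eliminated rather than silently kept.
- **Transcript linkage** is an explicit two-column ENST→UniProt input
  table; no annotation release is bundled, and isoform reconciliation is
  the caller's responsibility.
- **Permutation null.** The 5% threshold is taken on pooled null scores
  (per-simulation thresholds can be obtained from the stored ensemble).
  Per-simulation RNG streams are spawned from the seed by simulation index.
  Structure mapping is recomputed for the simulated sites each round; the
  mutation backbone is mapped once and reused.
- **Fisher direction** defaults to "greater" (enrichment in the
  co-clustered group), matching the direction of the curated assay tables;
  the odds ratio reported is the transparent sample estimate ad/bc.
- **ecdf** is right-continuous (fraction ≤ query). Domain membership uses
  closed 1-based intervals.

## Synthetic data

The generator emits ideal helix traces (1.5 Å rise, 100° twist, 2.3 Å
radius) with two heavy atoms per residue — CA plus an offset CB pseudo-atom,
so closest-atom distances genuinely differ from CA–CA distances. A planted
hotspot forces chosen sequence positions into a small sphere displaced from
the helix axis, creating the method's target signature: events adjacent in
3D but distant in sequence. On the plain helix, residues ≥ 7 positions apart
are > 10 Å apart, so scattered decoys stay unpaired at the default cutoff.

The scatter (no-signal) fixture draws phosphosites uniformly from each
gene's structure-covered S/T/Y positions — the same law the permutation
null redraws from — making observed and null hybrid clusters exchangeable,
which is what allows the top-5% threshold calibration to be tested at all.

What this does **not** emulate: real side-chain geometry and rotamers,
multi-domain folds, structure redundancy and coverage bias, disordered
regions, sequencing artifacts, or realistic mutation recurrence spectra.
Passing tests therefore demonstrate correctness of the algorithmic
machinery under controlled geometry, not performance on cohort-scale data;
cohort-scale results additionally depend on database snapshots that are
out of scope here.

## Problem sizes

Tests and the acceptance script run at deliberately small scale, chosen as
the smallest sizes at which each property is statistically meaningful: the
planted fixture uses one 160-residue chain with 9 events; the calibration
fixture uses 40 genes × 80 residues (~100+ observed hybrid clusters) with
100 simulations; the repeated planted-vs-null check uses 100 seeded runs of
30 simulations each; geodesic oracles use 200 random graphs of ≤ 10
vertices.

## Known limitations

- PDB text format only (no mmCIF); one model per entry is used.
- No solvent accessibility, interface area, or conformational weighting;
  distance is the only structural evidence.
- Individual clusters carry no p-values; prioritization is by Cc
  percentile, as in the underlying method.
- The multivariate (logistic) modelling layer and external pathway
  enrichment services are intentionally out of scope.
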