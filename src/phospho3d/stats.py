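"""Downstream statistics on cluster output.

Covers the linear-relation classification of co-clustered phosphosites
(direct / proximal / clustered), the >= 2-source curation rule for
activating mutations, one-tailed Fisher enrichment (functional-assay and
domain-level with the >= 5-events rule), one-sided rank-sum dependency
comparisons, ecdf expression percentiles with a covariate-adjusted carrier
model, and Benjamini-Hochberg FDR.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import Cluster, ClusterType, Relation, SiteVertex, SpatialRelation, VertexKind

PROXIMAL_MAX_SEPARATION = 2  # "within 2 amino acid residues linearly"


@dataclass
class AssociationResult:
    statistic: float
    p_value: float
    label: str = ""
    direction: str = ""
    n_per_group: tuple[int, int] | None = None
    fdr: float | None = None


# ---------------------------------------------------------------- relations

def classify_spatial_relations(clusters: list[Cluster]) -> list[SpatialRelation]:
    """Label every co-clustered phosphosite with its strongest linear relation
    to the mutations of its hybrid cluster: direct (same transcript position)
    > proximal (|delta| <= 2 on the same transcript) > clustered (3D only).

    A site appearing in several hybrid clusters keeps its single strongest
    label across them, so the relation labels partition the co-clustered
    sites.
    """
    best: dict[tuple, SpatialRelation] = {}
    rank = {Relation.DIRECT: 0, Relation.PROXIMAL: 1, Relation.CLUSTERED: 2}
    for cl in clusters:
        if cl.cluster_type is not ClusterType.HYBRID:
            continue
        muts = [m for m in cl.members if m.kind is VertexKind.MUTATION]
        for site in cl.members:
            if site.kind is not VertexKind.PHOSPHOSITE:
                continue
            direct = tuple(m for m in muts if m.transcript == site.transcript
                           and m.position == site.position)
            proximal = tuple(
                m for m in muts
                if m.transcript == site.transcript
                and 1 <= abs(m.position - site.position) <= PROXIMAL_MAX_SEPARATION)
            if direct:
                rel = SpatialRelation(site, Relation.DIRECT, direct)
            elif proximal:
                rel = SpatialRelation(site, Relation.PROXIMAL, proximal)
            else:
                rel = SpatialRelation(site, Relation.CLUSTERED, tuple(muts))
            prev = best.get(site.key)
            if prev is None or rank[rel.relation] < rank[prev.relation]:
                best[site.key] = rel
    return [best[k] for k in sorted(best)]


def write_relation_table(relations: list[SpatialRelation], path) -> None:
    rows = [{
        "Gene": r.site.gene,
        "Transcript": r.site.transcript,
        "Position": r.site.position,
        "Site": r.site.label,
        "Relation": r.relation.value,
        "Partner_Mutations": ",".join(m.label for m in r.partners),
    } for r in relations]
    pd.DataFrame(rows, columns=["Gene", "Transcript", "Position", "Site",
                                "Relation", "Partner_Mutations"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- curation

def curate_activating(source_lists: dict[str, list[str] | set[str]],
                      min_sources: int = 2) -> set[str]:
    """Retain mutations listed as activating by >= ``min_sources`` distinct
    curated databases."""
    return {mut for mut, sources in source_lists.items()
            if len(set(sources)) >= min_sources}


# ---------------------------------------------------------------- tests

def fisher_one_tailed(table, alternative: str = "greater",
                      label: str = "") -> AssociationResult:
    """One-tailed Fisher exact test on a 2x2 table of nonnegative counts.

    The statistic is the sample odds ratio ad/bc (inf when bc = 0 with
    ad > 0, nan for 0/0).  Both row margins (group sizes) must be positive;
    an all-zero outcome column is permitted and yields p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if t[0].sum() == 0 or t[1].sum() == 0:
        raise ValueError("degenerate margin: empty group row")
    a, b, c, d = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    if b * c > 0:
        odds = a * d / (b * c)
    else:
        odds = np.inf if a * d > 0 else np.nan
    p = float(sps.fisher_exact(t, alternative=alternative).pvalue)
    return AssociationResult(statistic=float(odds), p_value=p, label=label,
                             direction=alternative,
                             n_per_group=(int(t[0].sum()), int(t[1].sum())))


def domain_enrichment(
    domains: list[tuple[str, str, int, int]],
    events: list[tuple[str, int, bool]],
    min_events: int = 5,
    alternative: str = "greater",
) -> tuple[list[AssociationResult], list[tuple[str, str]]]:
    """Per-domain Fisher enrichment of co-clustered status.

    ``domains`` rows are (gene, domain_id, start, end) with closed 1-based
    intervals; ``events`` rows are (gene, position, co_clustered).  Each 2x2
    table tallies domain membership against co-clustered status.  Domains
    with fewer than ``min_events`` events are skipped (reported with reason
    ``below_min_events``); BH FDR is applied across the tested domains.
    """
    results: list[AssociationResult] = []
    skipped: list[tuple[str, str]] = []
    for gene, domain_id, start, end in domains:
        if start > end:
            raise ValueError(f"domain {domain_id}: start {start} > end {end}")
        inside = [(g, pos, cc) for g, pos, cc in events
                  if g == gene and start <= pos <= end]
        outside = [(g, pos, cc) for g, pos, cc in events
                   if not (g == gene and start <= pos <= end)]
        if len(inside) < min_events:
            skipped.append((domain_id, "below_min_events"))
            continue
        table = [
            [sum(cc for *_, cc in inside), sum(not cc for *_, cc in inside)],
            [sum(cc for *_, cc in outside), sum(not cc for *_, cc in outside)],
        ]
        results.append(fisher_one_tailed(table, alternative=alternative,
                                         label=domain_id))
    if results:
        fdrs = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, fdrs):
            r.fdr = float(q)
    return results, skipped


def rank_sum_one_sided(group_a, group_b, alternative: str = "less",
                       label: str = "") -> AssociationResult:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two groups.

    Exact null distribution when the combined sample is <= 20 without ties;
    otherwise the normal approximation with mid-ranks and tie correction.
    ``alternative='less'`` tests whether ``group_a`` is located left of
    ``group_b`` (e.g. more dependent in a knockout screen).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact = a.size + b.size <= 20 and np.unique(pooled).size == pooled.size
    res = sps.mannwhitneyu(a, b, alternative=alternative,
                           method="exact" if exact else "asymptotic")
    return AssociationResult(statistic=float(res.statistic),
                             p_value=float(res.pvalue), label=label,
                             direction=alternative,
                             n_per_group=(int(a.size), int(b.size)))


# ---------------------------------------------------------------- expression

def expression_percentile(cohort, query: float) -> float:
    """Right-continuous ecdf percentile: fraction of cohort values <= query."""
    c = np.asarray(cohort, dtype=float)
    if c.size == 0:
        raise ValueError("cohort must be non-empty")
    return float(np.mean(c <= query))


def carrier_association(
    percentiles,
    carrier,
    covariates: pd.DataFrame,
    min_carriers: int = 3,
    label: str = "",
) -> AssociationResult | None:
    """OLS of expression percentile on carrier status with covariate
    adjustment (age continuous; gender/ethnicity as categorical dummies).

    Returns None (skipped) when the stratum has fewer than ``min_carriers``
    carriers.  A rank-deficient design raises, naming a collinear column.
    Reported: carrier coefficient and its two-sided p-value.
    """
    import statsmodels.api as sm

    y = np.asarray(percentiles, dtype=float)
    flags = np.asarray(carrier, dtype=bool)
    if flags.sum() < min_carriers:
        return None
    design = pd.DataFrame({"carrier": flags.astype(float)}, index=covariates.index)
    for col in covariates.columns:
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series):
            design[col] = series.astype(float)
        else:
            dummies = pd.get_dummies(series, prefix=col, drop_first=True, dtype=float)
            design = pd.concat([design, dummies], axis=1)
    X = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        for col in [c for c in X.columns if c != "const"]:
            reduced = X.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise ValueError(f"design is rank-deficient: column {col!r} is collinear")
        raise ValueError("design is rank-deficient")
    fit = sm.OLS(y, X).fit()
    return AssociationResult(statistic=float(fit.params["carrier"]),
                             p_value=float(fit.pvalues["carrier"]),
                             label=label, direction="two-sided",
                             n_per_group=(int(flags.sum()), int((~flags).sum())))


# ---------------------------------------------------------------- correction

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
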