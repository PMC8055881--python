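"""Readers for the tab-delimited inputs: phosphosite table, MAF-like mutation
table, and the two-column transcript-to-UniProt accession map.

Phosphosite rows carry ``Gene, Transcript, Position, Residue, Description``;
mutation rows are MAF-like with ``Hugo_Symbol, Transcript_ID, HGVSp_Short,
Variant_Classification, Tumor_Sample_Barcode``.  Mutation recurrence (the
number of distinct samples carrying an identical amino-acid change) becomes
the vertex weight used by recurrence-weighted clustering.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from .types import CANONICAL_PHOSPHO_RESIDUES, SiteVertex, VertexKind

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["Gene", "Transcript", "Position", "Residue", "Description"]
MAF_COLUMNS = [
    "Hugo_Symbol",
    "Transcript_ID",
    "HGVSp_Short",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
]

# p.R132H (missense); p.R132* etc. intentionally fail the alt-residue class
_HGVSP_MISSENSE = re.compile(r"^p\.([A-Y])(\d+)([A-Y])$")


class TableError(ValueError):
    """Hard error on a malformed input table."""


def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required column(s) {', '.join(missing)}")


def parse_site_table(path: str | Path, allow_noncanonical: bool = False) -> list[SiteVertex]:
    """Read a phosphosite table into vertices (kind=phosphosite, weight=1).

    Duplicate (transcript, position) rows are deduplicated with merged
    descriptions; malformed rows are logged with their line number and
    skipped.  Phospho-residues outside {S, T, Y} are rejected unless
    ``allow_noncanonical`` is set (some curated datasets report
    non-canonical classes such as phospho-arginine).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, SITE_COLUMNS, str(path))

    by_key: dict[tuple[str, int], SiteVertex] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            pos = int(row["Position"])
        except ValueError:
            logger.warning("%s line %d: non-integer position %r, row skipped",
                           path, line_no, row["Position"])
            continue
        res = row["Residue"].strip().upper()
        if len(res) != 1 or not res.isalpha():
            logger.warning("%s line %d: bad residue %r, row skipped", path, line_no, res)
            continue
        if res not in CANONICAL_PHOSPHO_RESIDUES and not allow_noncanonical:
            logger.warning("%s line %d: non-canonical phospho-residue %s, row skipped "
                           "(pass allow_noncanonical to keep)", path, line_no, res)
            continue
        key = (row["Transcript"].strip(), pos)
        if key in by_key:
            prev = by_key[key]
            merged = "; ".join(d for d in (prev.description, row["Description"].strip()) if d)
            by_key[key] = SiteVertex(
                gene=prev.gene, transcript=prev.transcript, position=prev.position,
                ref_residue=prev.ref_residue, kind=VertexKind.PHOSPHOSITE,
                description=merged)
            logger.info("%s line %d: duplicate site %s:%d deduplicated", path, line_no, *key)
            continue
        by_key[key] = SiteVertex(
            gene=row["Gene"].strip(),
            transcript=key[0],
            position=pos,
            ref_residue=res,
            kind=VertexKind.PHOSPHOSITE,
            description=row["Description"].strip(),
        )
    return list(by_key.values())


def parse_mutation_table(path: str | Path) -> list[SiteVertex]:
    """Read a MAF-like table into missense-mutation vertices.

    Only ``Missense_Mutation`` rows are kept.  Identical amino-acid changes
    (same transcript, position, alt allele) collapse into one vertex whose
    weight is the number of distinct samples carrying the change.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, MAF_COLUMNS, str(path))

    samples: dict[tuple, set[str]] = {}
    meta: dict[tuple, tuple[str, str, int, str, str]] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2
        if row["Variant_Classification"].strip() != "Missense_Mutation":
            logger.info("%s line %d: non-missense row (%s) excluded",
                        path, line_no, row["Variant_Classification"])
            continue
        hgvsp = row["HGVSp_Short"].strip()
        m = _HGVSP_MISSENSE.match(hgvsp)
        if not m:
            logger.warning("%s line %d: unparsable protein change %r, row skipped",
                           path, line_no, hgvsp)
            continue
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        key = (row["Transcript_ID"].strip(), pos, alt)
        samples.setdefault(key, set()).add(row["Tumor_Sample_Barcode"].strip())
        meta[key] = (row["Hugo_Symbol"].strip(), key[0], pos, ref, alt)

    out = []
    for key, (gene, tx, pos, ref, alt) in meta.items():
        out.append(SiteVertex(
            gene=gene, transcript=tx, position=pos, ref_residue=ref,
            kind=VertexKind.MUTATION, alt_residue=alt, weight=len(samples[key])))
    return out


def parse_transcript_map(path: str | Path) -> dict[str, str]:
    """Read the two-column ENST -> UniProt accession map (tab-delimited, no header
    required; a header row starting with a non-ENST token is skipped)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    for raw in path.read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise TableError(f"{path}: expected 2 tab-separated columns, got {raw!r}")
        tx, acc = parts[0].strip(), parts[1].strip()
        if tx.lower() in {"transcript", "enst"}:
            continue
        mapping[tx] = acc
    return mapping
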