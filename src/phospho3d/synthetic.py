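"""Self-contained synthetic fixtures: PDB-format helix structures with
planted 3D hotspots, plus matching mutation/site/transcript-map tables.

Geometry is an ideal alpha-helix trace (1.5 Å rise and 100 degree twist per
residue, 2.3 Å axial radius), two heavy atoms per residue (CA plus an
offset CB pseudo-atom, so closest-atom distances differ from CA-CA
distances).  A planted hotspot forces a chosen set of sequence positions
into a small sphere displaced from the helix axis: linearly distant
residues become spatially adjacent, the signature the clustering method is
built to detect.  On the plain helix, residues more than ~6 positions apart
are farther than 10 Å, so scattered decoy events stay unpaired at the
default cutoff.

Not physically realistic folds -- deterministic geometry for oracle tests.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import SiteVertex, StructureModel, VertexKind

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic structure + its planted hotspot."""

    gene: str = "GENE1"
    transcript: str = "ENST00000000001"
    uniprot: str = "P00001"
    pdb_id: str = "1FIX"
    chain_id: str = "A"
    n_residues: int = 160
    sequence: str | None = None          # generated from seed when None
    rise: float = 1.5                    # Å per residue along the helix axis
    twist_deg: float = 100.0
    helix_radius: float = 2.3
    hotspot_positions: tuple[int, ...] = ()
    hotspot_radius: float = 4.0          # max pairwise CA distance inside the hotspot
    hotspot_center: tuple[float, float, float] = (30.0, 0.0, 12.0)
    db_offset: int = 0                   # pdb author number = uniprot position + offset
    seed: int = 0


def _fixed_width(fields: list[tuple[int, str]], width: int = 80) -> str:
    line = [" "] * width
    for start, text in fields:
        line[start:start + len(text)] = list(text)
    return "".join(line).rstrip()


def dbref_line(pdb_id: str, chain: str, pdb_start: int, pdb_end: int,
               accession: str, db_start: int, db_end: int) -> str:
    return _fixed_width([
        (0, "DBREF"), (7, f"{pdb_id:<4}"), (12, chain),
        (14, f"{pdb_start:>4}"), (20, f"{pdb_end:>4}"),
        (26, "UNP"), (33, f"{accession:<8}"),
        (42, f"{accession}_HUMAN"[:12]),
        (55, f"{db_start:>5}"), (62, f"{db_end:>5}"),
    ])


def seqadv_line(pdb_id: str, res_name: str, chain: str, seq_num: int,
                accession: str, comment: str) -> str:
    return _fixed_width([
        (0, "SEQADV"), (7, f"{pdb_id:<4}"), (12, f"{res_name:<3}"),
        (16, chain), (18, f"{seq_num:>4}"), (24, "UNP"),
        (29, f"{accession:<9}"), (49, comment),
    ])


def atom_line(serial: int, name: str, res_name: str, chain: str, res_seq: int,
              xyz: tuple[float, float, float], occupancy: float = 1.0,
              element: str = "C", alt_loc: str = " ") -> str:
    x, y, z = xyz
    return (f"ATOM  {serial:>5} {name:<4}{alt_loc}{res_name:>3} {chain}"
            f"{res_seq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}"
            f"  0.00          {element:>2}")


def generate_sequence(n_residues: int, rng: np.random.Generator) -> str:
    """Random sequence with S/T/Y enriched (p = 0.10 each) so every fixture
    has a workable pool of candidate phospho-positions."""
    others = [a for a in AMINO_ACIDS if a not in "STY"]
    probs = {a: 0.7 / len(others) for a in others}
    probs.update({"S": 0.1, "T": 0.1, "Y": 0.1})
    letters = list(probs)
    p = np.array([probs[a] for a in letters])
    idx = rng.choice(len(letters), size=n_residues, p=p)
    return "".join(letters[i] for i in idx)


def residue_coordinates(spec: FixtureSpec) -> dict[int, list[tuple[float, float, float]]]:
    """Deterministic CA/CB coordinates per 1-based position.

    Hotspot positions sit on a circle of radius ``hotspot_radius / 2``
    around ``hotspot_center`` (pairwise CA distance <= hotspot_radius);
    all others follow the ideal helix.
    """
    coords: dict[int, list[tuple[float, float, float]]] = {}
    hotspot = sorted(spec.hotspot_positions)
    cx, cy, cz = spec.hotspot_center
    for i in range(1, spec.n_residues + 1):
        if i in spec.hotspot_positions:
            k = hotspot.index(i)
            theta = 2.0 * math.pi * k / max(len(hotspot), 1)
            r = spec.hotspot_radius / 2.0
            ca = (cx + r * math.cos(theta), cy + r * math.sin(theta), cz)
            cb = (cx + (r + 1.2) * math.cos(theta),
                  cy + (r + 1.2) * math.sin(theta), cz)
        else:
            angle = math.radians(spec.twist_deg) * (i - 1)
            ca = (spec.helix_radius * math.cos(angle),
                  spec.helix_radius * math.sin(angle),
                  spec.rise * (i - 1))
            cb = ((spec.helix_radius + 1.2) * math.cos(angle),
                  (spec.helix_radius + 1.2) * math.sin(angle),
                  spec.rise * (i - 1))
        coords[i] = [tuple(round(c, 3) for c in ca), tuple(round(c, 3) for c in cb)]
    return coords


def make_structure(spec: FixtureSpec) -> tuple[str, dict]:
    """Emit PDB-format text plus a truth table of residue coordinates.

    The truth table maps position -> {"residue": letter, "atoms": [...]} and
    lets downstream tests assert distances without re-reading the PDB text.
    """
    if spec.sequence is None:
        sequence = generate_sequence(spec.n_residues,
                                     np.random.default_rng(spec.seed))
    else:
        sequence = spec.sequence
    if len(sequence) != spec.n_residues:
        raise ValueError("sequence length must equal n_residues")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid residue letter(s): {sorted(bad)}")
    for pos in spec.hotspot_positions:
        if not 1 <= pos <= spec.n_residues:
            raise ValueError(f"hotspot position {pos} outside 1..{spec.n_residues}")

    coords = residue_coordinates(spec)
    lines = [
        _fixed_width([(0, "HEADER"), (10, "SYNTHETIC HELIX FIXTURE"),
                      (62, spec.pdb_id)]),
        dbref_line(spec.pdb_id, spec.chain_id, 1 + spec.db_offset,
                   spec.n_residues + spec.db_offset, spec.uniprot,
                   1, spec.n_residues),
    ]
    truth: dict[int, dict] = {}
    serial = 1
    for i in range(1, spec.n_residues + 1):
        letter = sequence[i - 1]
        res_name = THREE_LETTER[letter]
        res_seq = i + spec.db_offset
        for name, xyz in zip(("CA", "CB"), coords[i]):
            lines.append(atom_line(serial, name, res_name, spec.chain_id,
                                   res_seq, xyz))
            serial += 1
        truth[i] = {"residue": letter, "author_number": res_seq,
                    "atoms": coords[i]}
    lines.append("END")
    return "\n".join(lines) + "\n", {"sequence": sequence, "residues": truth}


@dataclass
class SyntheticDataset:
    """A complete in-memory input set: structures + event tables + map."""

    structures: list[StructureModel]
    pdb_texts: dict[str, str]
    mutations: list[SiteVertex]
    sites: list[SiteVertex]
    transcript_map: dict[str, str]
    truth: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write structures/, mutations.tsv, sites.tsv, transcript_map.tsv,
        truth.json under ``out_dir``; returns the paths."""
        out = Path(out_dir)
        (out / "structures").mkdir(parents=True, exist_ok=True)
        for pdb_id, text in self.pdb_texts.items():
            (out / "structures" / f"{pdb_id}.pdb").write_text(text)

        mut_path = out / "mutations.tsv"
        with open(mut_path, "w") as fh:
            fh.write("Hugo_Symbol\tTranscript_ID\tHGVSp_Short\t"
                     "Variant_Classification\tTumor_Sample_Barcode\n")
            sample = 0
            for m in self.mutations:
                for _ in range(m.weight):
                    sample += 1
                    fh.write(f"{m.gene}\t{m.transcript}\t{m.label}\t"
                             f"Missense_Mutation\tSAMPLE-{sample:04d}\n")

        site_path = out / "sites.tsv"
        with open(site_path, "w") as fh:
            fh.write("Gene\tTranscript\tPosition\tResidue\tDescription\n")
            for s in self.sites:
                fh.write(f"{s.gene}\t{s.transcript}\t{s.position}\t"
                         f"{s.ref_residue}\t{s.description or 'synthetic site'}\n")

        map_path = out / "transcript_map.tsv"
        with open(map_path, "w") as fh:
            for tx, acc in sorted(self.transcript_map.items()):
                fh.write(f"{tx}\t{acc}\n")

        truth_path = out / "truth.json"
        truth_path.write_text(json.dumps(self.truth, indent=1, sort_keys=True,
                                         default=str))
        return {"structures": out / "structures", "mutations": mut_path,
                "sites": site_path, "transcript_map": map_path,
                "truth": truth_path}


def plant_hotspot_dataset(seed: int = 0) -> SyntheticDataset:
    """One-gene dataset with a planted hybrid hotspot and scattered decoys.

    Planted events (all forced into the hotspot sphere): mutations p.S40F
    (3 samples) and p.R90H (2 samples); phosphosites p.S40 (direct overlap
    with p.S40F), p.T42 (proximal, two residues from position 40), and
    p.Y140 (linearly distant from both mutations -- a 3D-only relation).
    Decoy events at positions 10, 20, 70, 80 sit on the plain helix, all
    pairwise farther than the default 10 Å cutoff, so the pipeline should
    recover exactly one hybrid cluster holding the five planted vertices.
    """
    from .structures import filter_chains, parse_structure

    rng = np.random.default_rng(seed)
    n = 160
    seq = list(generate_sequence(n, rng))
    forced = {40: "S", 42: "T", 90: "R", 140: "Y", 20: "S", 80: "T"}
    for pos, letter in forced.items():
        seq[pos - 1] = letter
    # decoy mutations need a ref != alt; any letter works
    spec = FixtureSpec(sequence="".join(seq), n_residues=n,
                       hotspot_positions=(40, 42, 90, 140), seed=seed)
    pdb_text, truth = make_structure(spec)
    model = parse_structure(pdb_text, pdb_id=spec.pdb_id)
    filter_chains(model)

    def mut(pos: int, alt: str, weight: int) -> SiteVertex:
        return SiteVertex(gene=spec.gene, transcript=spec.transcript,
                          position=pos, ref_residue=seq[pos - 1],
                          kind=VertexKind.MUTATION, alt_residue=alt,
                          weight=weight)

    def site(pos: int) -> SiteVertex:
        return SiteVertex(gene=spec.gene, transcript=spec.transcript,
                          position=pos, ref_residue=seq[pos - 1],
                          kind=VertexKind.PHOSPHOSITE,
                          description="planted" if pos in spec.hotspot_positions
                          else "decoy")

    def _alt(pos: int) -> str:
        ref = seq[pos - 1]
        return "A" if ref != "A" else "G"

    mutations = [mut(40, "F", 3), mut(90, "H", 2),
                 mut(10, _alt(10), 1), mut(70, _alt(70), 1)]
    sites = [site(40), site(42), site(140), site(20), site(80)]

    return SyntheticDataset(
        structures=[model],
        pdb_texts={spec.pdb_id: pdb_text},
        mutations=mutations,
        sites=sites,
        transcript_map={spec.transcript: spec.uniprot},
        truth={
            "spec": {"n_residues": n, "seed": seed,
                     "hotspot_positions": list(spec.hotspot_positions)},
            "structure": truth,
            "planted_vertices": [v.label for v in mutations[:2] + sites[:3]],
            "expected_relations": {"p.S40": "direct", "p.T42": "proximal",
                                   "p.Y140": "clustered"},
        },
    )


def make_scatter_dataset(
    n_genes: int = 40,
    n_residues: int = 80,
    n_mutations: int = 8,
    n_sites: int = 8,
    seed: int = 0,
) -> SyntheticDataset:
    """Multi-gene no-signal dataset: plain helices, mutations at uniformly
    random positions, phosphosites drawn uniformly (without replacement)
    from each gene's structure-covered S/T/Y positions -- i.e. exactly the
    law the permutation null redraws from, so observed and null hybrid
    clusters are exchangeable and threshold calibration can be tested.
    """
    from .structures import filter_chains, parse_structure

    rng = np.random.default_rng(seed)
    structures, pdb_texts, mutations, sites = [], {}, [], []
    transcript_map: dict[str, str] = {}
    for g in range(n_genes):
        gene = f"GEN{g:03d}"
        tx = f"ENST{g:011d}"
        acc = f"P{g:05d}"
        pdb_id = f"S{g:03X}"
        seq = generate_sequence(n_residues, rng)
        spec = FixtureSpec(gene=gene, transcript=tx, uniprot=acc,
                           pdb_id=pdb_id, n_residues=n_residues,
                           sequence=seq, seed=seed)
        text, _ = make_structure(spec)
        model = parse_structure(text, pdb_id=pdb_id)
        filter_chains(model)
        structures.append(model)
        pdb_texts[pdb_id] = text
        transcript_map[tx] = acc

        positions = rng.choice(n_residues, size=n_mutations, replace=False) + 1
        for pos in sorted(int(p) for p in positions):
            ref = seq[pos - 1]
            alt = "A" if ref != "A" else "G"
            mutations.append(SiteVertex(
                gene=gene, transcript=tx, position=pos, ref_residue=ref,
                kind=VertexKind.MUTATION, alt_residue=alt,
                weight=int(rng.integers(1, 4))))

        sty = [i + 1 for i, a in enumerate(seq) if a in "STY"]
        k = min(n_sites, len(sty))
        chosen = rng.choice(len(sty), size=k, replace=False)
        for idx in sorted(int(i) for i in chosen):
            pos = sty[idx]
            sites.append(SiteVertex(
                gene=gene, transcript=tx, position=pos,
                ref_residue=seq[pos - 1], kind=VertexKind.PHOSPHOSITE,
                description="scattered"))

    return SyntheticDataset(structures=structures, pdb_texts=pdb_texts,
                            mutations=mutations, sites=sites,
                            transcript_map=transcript_map,
                            truth={"kind": "scatter", "seed": seed,
                                   "n_genes": n_genes})
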