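"""Synthetic structures with matched cross-link tables of known geometry.

Scenes place residues on idealized helical traces (rise 1.5 Å per residue,
radius 2.3 Å, ~100° twist) with chains offset in space, so intra- and
inter-chain Cα distances sweep smoothly from a few Å to well beyond typical
linker maxima and both satisfied and over-length links can be planted
deterministically.  Every scene writes a valid mmCIF, a matching FASTA and a
generic cross-link TSV, and records the planned distance and status of each
link: the pipeline must reproduce them exactly.

Planned distances are computed from coordinates rounded to the 3 decimals the
mmCIF text carries, so pipeline agreement is exact (<1e-6 Å), not approximate.

These fixtures test bookkeeping and math, not biophysics — the geometry is
not a physically realistic protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .crosslink_io import LinkerSpec, DEFAULT_LINKERS, write_linker_table
from .errors import SceneError
from .structure_io import ONE_TO_THREE

AA20 = "ACDEFGHIKLMNPQRSTVWY"

HELIX_RISE = 1.5       # Å per residue along the chain axis
HELIX_RADIUS = 2.3     # Å
HELIX_TWIST = math.radians(100.0)
CHAIN_SPACING = 12.0   # Å between chain axes

MIN_INTRA_SEQ_SEP = 3  # planted intra-chain links skip near-diagonal pairs


@dataclass(frozen=True)
class PlannedLink:
    protein_a: str
    pos_a: int
    protein_b: str
    pos_b: int
    linker: str
    spectral_count: int
    distance: float  # Å, from the coordinates as written to the mmCIF
    status: str      # satisfied | over_length


@dataclass
class SyntheticScene:
    entry_id: str
    structure_path: Path
    fasta_path: Path
    links_path: Path
    accessions: list[str]          # one protein per chain, chain order
    chain_ids: list[str]
    sequences: dict[str, str]      # accession -> sequence
    coords: dict[str, np.ndarray]  # chain_id -> (L, 3) rounded coordinates
    planned: list[PlannedLink]
    linker: LinkerSpec
    seed: int

    @property
    def n_over_planned(self) -> int:
        return sum(1 for p in self.planned if p.status == "over_length")

    @property
    def n_satisfied_planned(self) -> int:
        return sum(1 for p in self.planned if p.status == "satisfied")


def _chain_coords(chain_index: int, chain_len: int) -> np.ndarray:
    """Helical Cα trace for one chain, rounded to mmCIF precision."""
    i = np.arange(chain_len, dtype=float)
    theta = i * HELIX_TWIST
    x = chain_index * CHAIN_SPACING + HELIX_RADIUS * np.cos(theta)
    y = HELIX_RADIUS * np.sin(theta)
    z = i * HELIX_RISE
    return np.round(np.stack([x, y, z], axis=1), 3)


def _write_mmcif(path: Path, entry_id: str, chain_ids: Sequence[str],
                 sequences: Sequence[str], coords: Sequence[np.ndarray]) -> None:
    lines = [
        f"data_{entry_id}",
        "#",
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_entity_id",
        "_atom_site.label_seq_id",
        "_atom_site.pdbx_PDB_ins_code",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_asym_id",
        "_atom_site.pdbx_PDB_model_num",
    ]
    serial = 0
    for entity, (cid, seq, xyz) in enumerate(zip(chain_ids, sequences, coords), start=1):
        for resnum, (aa, pos) in enumerate(zip(seq, xyz), start=1):
            serial += 1
            comp = ONE_TO_THREE[aa]
            lines.append(
                f"ATOM {serial} C CA . {comp} {cid} {entity} {resnum} ? "
                f"{pos[0]:.3f} {pos[1]:.3f} {pos[2]:.3f} 1.00 0.00 {resnum} {cid} 1")
    lines.append("#")
    path.write_text("\n".join(lines) + "\n")


def make_scene(out_dir: str | Path, n_chains: int = 2, chain_len: int = 40,
               n_links: int = 10, frac_over: float = 0.5,
               linker: LinkerSpec = DEFAULT_LINKERS["DSS"],
               seed: int = 0) -> SyntheticScene:
    """Generate a fully determined synthetic scene under ``out_dir``.

    Each chain is a distinct random-sequence protein, so every protein maps to
    exactly one chain and the pipeline's minimum-over-copies rule reduces to
    the planned pair.  ``frac_over`` of the ``n_links`` planted links are
    sampled from site pairs whose Cα distance exceeds the linker maximum, the
    rest from pairs within it; raises SceneError when the geometry cannot
    supply the requested split.
    """
    if chain_len < 10:
        raise SceneError("chain_len must be >= 10")
    if not 0.0 <= frac_over <= 1.0:
        raise SceneError("frac_over must lie in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chain_ids = [chr(ord("A") + k) for k in range(n_chains)]
    accessions = [f"SYNP{k + 1:02d}" for k in range(n_chains)]
    sequences = ["".join(rng.choice(list(AA20), size=chain_len)) for _ in range(n_chains)]
    coords = [_chain_coords(k, chain_len) for k in range(n_chains)]

    # enumerate candidate site pairs and classify by planned status
    sat_pool: list[tuple[int, int, int, int, float]] = []
    over_pool: list[tuple[int, int, int, int, float]] = []
    for i in range(n_chains):
        for j in range(i, n_chains):
            for a in range(chain_len):
                b_start = a + MIN_INTRA_SEQ_SEP if i == j else 0
                for b in range(b_start, chain_len):
                    d = float(np.linalg.norm(coords[i][a] - coords[j][b]))
                    rec = (i, a + 1, j, b + 1, d)
                    (sat_pool if d <= linker.max_ca_distance else over_pool).append(rec)

    n_over = int(round(frac_over * n_links))
    n_sat = n_links - n_over
    if len(over_pool) < n_over:
        raise SceneError(
            f"geometry yields only {len(over_pool)} over-length site pairs "
            f"(> {linker.max_ca_distance} Å) but {n_over} were requested; "
            f"increase chain_len or lower frac_over")
    if len(sat_pool) < n_sat:
        raise SceneError(
            f"geometry yields only {len(sat_pool)} satisfiable site pairs "
            f"but {n_sat} were requested")

    planned: list[PlannedLink] = []
    for pool, count, status in ((sat_pool, n_sat, "satisfied"),
                                (over_pool, n_over, "over_length")):
        picks = rng.choice(len(pool), size=count, replace=False)
        for idx in sorted(int(p) for p in picks):
            i, a, j, b, d = pool[idx]
            pa, pb = accessions[i], accessions[j]
            if (pb, b) < (pa, a):
                pa, a, pb, b = pb, b, pa, a
            planned.append(PlannedLink(pa, a, pb, b, linker.name,
                                       int(rng.integers(1, 5)), d, status))
    planned.sort(key=lambda p: (p.protein_a, p.pos_a, p.protein_b, p.pos_b))

    entry_id = f"sd{seed % 100:02d}"
    structure_path = out_dir / f"{entry_id}.cif"
    fasta_path = out_dir / "database.fasta"
    links_path = out_dir / "links.tsv"
    _write_mmcif(structure_path, entry_id, chain_ids, sequences, coords)
    fasta_path.write_text("".join(
        f">{acc} synthetic fixture chain\n{seq}\n"
        for acc, seq in zip(accessions, sequences)))
    with open(links_path, "w") as fh:
        fh.write("protein_a\tpos_a\tprotein_b\tpos_b\tlinker\tcount\n")
        for p in planned:
            fh.write(f"{p.protein_a}\t{p.pos_a}\t{p.protein_b}\t{p.pos_b}"
                     f"\t{p.linker}\t{p.spectral_count}\n")

    return SyntheticScene(
        entry_id=entry_id,
        structure_path=structure_path,
        fasta_path=fasta_path,
        links_path=links_path,
        accessions=accessions,
        chain_ids=chain_ids,
        sequences=dict(zip(accessions, sequences)),
        coords=dict(zip(chain_ids, coords)),
        planned=planned,
        linker=linker,
        seed=seed,
    )


def make_mutated_chain(sequence: str, n_subs: int, seed: int = 0) -> str:
    """Substitute ``n_subs`` distinct positions with different residues.

    Used to exercise alignment identity thresholds: the mutated chain aligns
    to the original with identity (len - n_subs) / len.
    """
    if n_subs >= len(sequence):
        raise ValueError("n_subs must be smaller than the sequence length")
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(sequence), size=n_subs, replace=False)
    chars = list(sequence)
    for pos in sorted(int(p) for p in positions):
        alternatives = [c for c in AA20 if c != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def write_demo(out_dir: str | Path, seed: int = 7) -> Path:
    """Emit a demo scene plus a ready-to-run YAML config; returns the config path."""
    import yaml

    out_dir = Path(out_dir)
    scene = make_scene(out_dir / "scene", n_chains=3, chain_len=40,
                       n_links=12, frac_over=0.25, seed=seed)
    linker_path = out_dir / "linkers.tsv"
    write_linker_table(DEFAULT_LINKERS, linker_path)
    # paths are written relative to the config file so the directory can move
    config = {
        "links": str(scene.links_path.relative_to(out_dir)),
        "links_format": "generic",
        "fasta": str(scene.fasta_path.relative_to(out_dir)),
        "structure_dir": str(scene.structure_path.parent.relative_to(out_dir)),
        "linker_table": str(linker_path.relative_to(out_dir)),
        "min_identity": 0.9,
        "min_coverage": 0.3,
        "score": {"w_s": 0.7, "w_c": 0.3, "w_v": 0.2, "k": 3.0},
        "output_dir": "results",
        "pymol": True,
    }
    config_path = out_dir / "run.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return config_path
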