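"""mmCIF structure reading and PPI-structure candidate enumeration.

Structures are parsed with gemmi.  Only the first model and only amino-acid
residues are retained; the user-facing residue coordinate system is author
numbering (auth_asym_id / auth_seq_id + insertion code) because the PyMOL
scripts emitted downstream select residues by it.
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .crosslink_io import PPI
from .errors import StructureParseError

log = logging.getLogger("xlmap")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class ResidueRecord:
    """One residue in author numbering, with its Cα position if present."""

    auth_seq_num: int
    insertion_code: str  # "" when absent
    aa: str              # one-letter, X for nonstandard amino acids
    ca_xyz: np.ndarray | None  # (3,) float64 in Å, or None if no Cα

    @property
    def auth_label(self) -> str:
        """Residue number + insertion code, as PyMOL's resi expects."""
        return f"{self.auth_seq_num}{self.insertion_code}"


@dataclass
class ChainRecord:
    chain_id: str
    residues: list[ResidueRecord]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class StructureModel:
    """A parsed structure entry: first model, polymer chains, Cα coordinates."""

    entry_id: str
    chains: list[ChainRecord]
    model_number: int = 1
    source_path: Path | None = None

    def chain(self, chain_id: str) -> ChainRecord:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(chain_id)


def _pick_ca(residue: gemmi.Residue) -> np.ndarray | None:
    """Cα coordinates: highest occupancy wins, ties break to first altloc."""
    best = None
    for atom in residue:
        if atom.name != "CA" or atom.element.name != "C":
            continue
        key = (-atom.occ, atom.altloc)
        if best is None or key < best[0]:
            best = (key, atom.pos)
    if best is None:
        return None
    pos = best[1]
    return np.array([pos.x, pos.y, pos.z], dtype=float)


def parse_mmcif(path: str | Path, entry_id: str | None = None) -> StructureModel:
    """Parse one PDBx/mmCIF file (optionally gzipped) into a StructureModel.

    First model only; amino-acid residues only (waters and ligands excluded);
    one ResidueRecord per (auth_asym_id, auth_seq_id, ins_code); nonstandard
    amino acids map to X.  Raises StructureParseError when the file is
    unreadable or holds no polymer chain.
    """
    path = Path(path)
    if entry_id is None:
        stem = path.name
        for suffix in (".gz", ".cif"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        entry_id = stem.lower()
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"{path}: unreadable mmCIF ({exc})") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    model = st[0]

    chains: dict[str, dict[tuple[int, str], ResidueRecord]] = {}
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = res.name in THREE_TO_ONE or (info is not None and info.is_amino_acid())
            if not is_aa:
                continue
            icode = res.seqid.icode.strip()
            key = (res.seqid.num, icode)
            per_chain = chains.setdefault(chain.name, {})
            if key in per_chain:  # microheterogeneity: keep first
                continue
            per_chain[key] = ResidueRecord(
                auth_seq_num=res.seqid.num,
                insertion_code=icode,
                aa=THREE_TO_ONE.get(res.name, "X"),
                ca_xyz=_pick_ca(res),
            )
    chain_records = [
        ChainRecord(cid, [per[k] for k in sorted(per)])
        for cid, per in sorted(chains.items())
    ]
    chain_records = [ch for ch in chain_records if ch.residues]
    if not chain_records:
        raise StructureParseError(f"{path}: no polymer (amino-acid) chains")
    return StructureModel(
        entry_id=entry_id,
        chains=chain_records,
        model_number=getattr(model, "num", 1),
        source_path=path,
    )


def _resolve_cif(directory: Path, entry: str) -> Path | None:
    for name in (f"{entry}.cif", f"{entry}.cif.gz",
                 f"{entry.lower()}.cif", f"{entry.lower()}.cif.gz"):
        p = directory / name
        if p.exists():
            return p
    return None


def fetch_mmcif(entry: str, directory: Path,
                url_template: str = "https://files.rcsb.org/download/{entry}.cif") -> Path:
    """Download one mmCIF into the local cache directory (network required)."""
    directory.mkdir(parents=True, exist_ok=True)
    dest = directory / f"{entry.lower()}.cif"
    urllib.request.urlretrieve(url_template.format(entry=entry.upper()), dest)
    return dest


def load_structure_set(directory: str | Path,
                       entries: Sequence[str] | None = None,
                       allow_online_fetch: bool = False,
                       ) -> tuple[list[StructureModel], dict[str, str]]:
    """Load every requested entry from a local mmCIF directory.

    ``entries=None`` loads every ``*.cif`` / ``*.cif.gz`` in the directory.
    Returns the surviving models sorted by entry id together with a map of
    per-entry failure reasons; raises StructureParseError if nothing survives.
    """
    directory = Path(directory)
    if entries is None:
        found = sorted(set(list(directory.glob("*.cif")) + list(directory.glob("*.cif.gz"))))
        entries = []
        for p in found:
            stem = p.name
            for suffix in (".gz", ".cif"):
                if stem.endswith(suffix):
                    stem = stem[: -len(suffix)]
            entries.append(stem)
    models: list[StructureModel] = []
    failures: dict[str, str] = {}
    for entry in sorted(set(entries)):
        path = _resolve_cif(directory, entry)
        if path is None and allow_online_fetch:
            try:
                path = fetch_mmcif(entry, directory)
            except OSError as exc:
                failures[entry] = f"fetch failed: {exc}"
                log.warning("entry %s: fetch failed (%s)", entry, exc)
                continue
        if path is None:
            failures[entry] = "not found"
            log.warning("entry %s: no mmCIF file in %s", entry, directory)
            continue
        try:
            models.append(parse_mmcif(path, entry_id=entry.lower()))
        except StructureParseError as exc:
            failures[entry] = str(exc)
            log.warning("entry %s: %s", entry, exc)
    if not models:
        summary = "; ".join(f"{k}: {v}" for k, v in sorted(failures.items())) or "no entries requested"
        raise StructureParseError(f"no structure could be loaded ({summary})")
    models.sort(key=lambda m: m.entry_id)
    return models, failures


def candidate_pairs(ppis: Sequence[PPI], structures: Sequence[StructureModel],
                    mapping: Mapping[str, Iterable[str]] | None = None,
                    ) -> list[tuple[PPI, StructureModel]]:
    """Enumerate the PPI-structure pairs to evaluate, in deterministic order.

    With a protein→entry mapping table, each PPI is paired only with entries
    listed for either of its proteins; without one, every PPI is paired with
    every structure and sequence alignment discards the non-matches.
    """
    structures = sorted(structures, key=lambda m: m.entry_id)
    ppis = sorted(ppis, key=lambda p: p.key)
    pairs: list[tuple[PPI, StructureModel]] = []
    for ppi in ppis:
        if mapping is not None:
            allowed = {e.lower() for prot in (ppi.protein_a, ppi.protein_b)
                       for e in mapping.get(prot, ())}
            pairs.extend((ppi, st) for st in structures if st.entry_id in allowed)
        else:
            pairs.extend((ppi, st) for st in structures)
    return pairs


def load_entry_mapping(path: str | Path) -> dict[str, set[str]]:
    """Read a protein→structure mapping TSV (columns: accession, entry_id)."""
    import csv

    mapping: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"accession", "entry_id"} <= set(reader.fieldnames):
            raise StructureParseError(f"{path}: mapping table needs columns accession, entry_id")
        for row in reader:
            mapping.setdefault(row["accession"].strip(), set()).add(row["entry_id"].strip().lower())
    return mapping
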