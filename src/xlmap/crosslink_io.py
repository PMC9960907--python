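"""Parsing of cross-link identification tables and the FASTA search database.

Cross-link identifications arrive either as a pLink2-style cross-linked-peptides
CSV (site strings of the form ``ACC(pos)-ACC(pos)``) or as a generic TSV with
explicit columns.  Both are normalized into :class:`CrossLink` records with a
canonical site ordering so that duplicates collapse deterministically, validated
against the FASTA database, and grouped into protein–protein interactions (PPIs).

Positions are 1-based database-sequence coordinates everywhere in the public API.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import EmptyInputError, InputFormatError

log = logging.getLogger("xlmap")

# the 20 standard residues plus X (unknown)
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class CrossLink:
    """One identified residue–residue linkage between two proteins.

    Sites are stored in canonical order: ``(protein_a, pos_a) <=
    (protein_b, pos_b)`` lexicographically.  ``spectral_count`` is the number
    of PSMs (or the summed count column) supporting the link.
    """

    protein_a: str
    pos_a: int
    protein_b: str
    pos_b: int
    linker: str
    spectral_count: int = 1

    def __post_init__(self) -> None:
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError("residue positions are 1-based and must be >= 1")
        if (self.protein_a, self.pos_a) > (self.protein_b, self.pos_b):
            raise ValueError("cross-link sites must be canonically ordered")
        if self.spectral_count < 0:
            raise ValueError("spectral_count must be non-negative")

    @property
    def is_intra(self) -> bool:
        return self.protein_a == self.protein_b

    @property
    def key(self) -> tuple[str, int, str, int, str]:
        """Dedup key: both sites plus the linker name."""
        return (self.protein_a, self.pos_a, self.protein_b, self.pos_b, self.linker)


def make_link(protein_a: str, pos_a: int, protein_b: str, pos_b: int,
              linker: str, spectral_count: int = 1) -> CrossLink:
    """Build a CrossLink with sites put into canonical order."""
    if (protein_b, pos_b) < (protein_a, pos_a):
        protein_a, pos_a, protein_b, pos_b = protein_b, pos_b, protein_a, pos_a
    return CrossLink(protein_a, pos_a, protein_b, pos_b, linker, spectral_count)


@dataclass(frozen=True)
class LinkerSpec:
    """A cross-linker and its maximum allowed Cα–Cα distance in Å."""

    name: str
    max_ca_distance: float

    def __post_init__(self) -> None:
        if not self.max_ca_distance > 0:
            raise ValueError(f"max_ca_distance must be > 0, got {self.max_ca_distance}")


#: Default maximum Cα–Cα distances (Å).  30 Å is the conventional upper bound
#: for ~11 Å spacer-arm lysine-reactive reagents once side-chain reach and
#: coordinate uncertainty are folded in; treated as data, overridable via TSV.
DEFAULT_LINKERS: dict[str, LinkerSpec] = {
    "DSS": LinkerSpec("DSS", 30.0),
    "BS3": LinkerSpec("BS3", 30.0),
    "DSBU": LinkerSpec("DSBU", 30.0),
}


def load_linker_table(path: str | Path) -> dict[str, LinkerSpec]:
    """Read a linker TSV (columns: name, max_ca_distance) into a spec table."""
    table: dict[str, LinkerSpec] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"name", "max_ca_distance"} <= set(reader.fieldnames):
            raise InputFormatError(f"{path}: linker table needs columns name, max_ca_distance")
        for row in reader:
            name = row["name"].strip()
            table[name] = LinkerSpec(name, float(row["max_ca_distance"]))
    if not table:
        raise EmptyInputError(f"{path}: empty linker table")
    return table


def write_linker_table(linkers: Mapping[str, LinkerSpec], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("name\tmax_ca_distance\n")
        for name in sorted(linkers):
            fh.write(f"{name}\t{linkers[name].max_ca_distance:g}\n")


@dataclass(frozen=True)
class ProteinSequence:
    """One database entry: accession plus one-letter amino-acid sequence."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(f"{self.accession}: non-standard residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PPI:
    """An unordered protein pair together with all its cross-links."""

    protein_a: str
    protein_b: str
    links: tuple[CrossLink, ...]

    def __post_init__(self) -> None:
        if not self.links:
            raise ValueError("a PPI must carry at least one cross-link")
        for lk in self.links:
            if {lk.protein_a, lk.protein_b} != {self.protein_a, self.protein_b}:
                raise ValueError("link protein pair does not match the PPI pair")

    @property
    def is_intra(self) -> bool:
        return self.protein_a == self.protein_b

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class Rejection:
    """One rejected input row and the reason it was dropped."""

    row: int
    reason: str


def write_rejections(rejections: Sequence[Rejection], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("row\treason\n")
        for r in rejections:
            fh.write(f"{r.row}\t{r.reason}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _resolve_accession(token: str) -> str:
    """First whitespace token; UniProt ``sp|ACC|NAME`` resolves to ACC."""
    token = token.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


# residues outside the standard 20 are folded to X at parse time
_NONSTANDARD = re.compile(r"[BJOUZ]")


def parse_fasta(path: str | Path) -> dict[str, ProteinSequence]:
    """Parse the sequence database; returns accession -> ProteinSequence.

    Sequences are upper-cased with gap/stop characters stripped and rare
    non-standard letters folded to X.  Duplicate accessions keep the first
    record and log a warning.
    """
    records: dict[str, ProteinSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _resolve_accession(rec.description or rec.id)
        seq = str(rec.seq).upper().replace("-", "").replace(".", "").replace("*", "")
        seq = _NONSTANDARD.sub("X", seq)
        if acc in records:
            log.warning("duplicate accession %s in %s: keeping first record", acc, path)
            continue
        records[acc] = ProteinSequence(acc, seq)
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# cross-link tables
# ---------------------------------------------------------------------------

_SITE_PAIR = re.compile(r"^(.+?)\((\d+)\)-(.+?)\((\d+)\)$")


def _validate_sites(pa: str, sa: int, pb: str, sb: int,
                    sequences: Mapping[str, ProteinSequence]) -> str | None:
    """Return a rejection reason, or None if both sites are in bounds."""
    for acc, pos in ((pa, sa), (pb, sb)):
        if acc not in sequences:
            return f"accession {acc} not in FASTA"
        if pos > len(sequences[acc]):
            return f"position {pos} exceeds length {len(sequences[acc])} of {acc}"
    return None


def _collapse(raw: Iterable[tuple[str, int, str, int, str, int]]) -> list[CrossLink]:
    """Aggregate spectral counts over the canonical dedup key."""
    counts: dict[tuple[str, int, str, int, str], int] = {}
    for pa, sa, pb, sb, linker, n in raw:
        if (pb, sb) < (pa, sa):
            pa, sa, pb, sb = pb, sb, pa, sa
        key = (pa, sa, pb, sb, linker)
        counts[key] = counts.get(key, 0) + n
    return [CrossLink(*key, spectral_count=n) for key, n in sorted(counts.items())]


def parse_plink2(path: str | Path, sequences: Mapping[str, ProteinSequence],
                 default_linker: str = "DSS",
                 ) -> tuple[list[CrossLink], list[Rejection]]:
    """Parse a pLink2-style cross-linked-peptides CSV.

    Each data row is one PSM; its ``Proteins`` field holds a site string
    ``ACC(pos)-ACC(pos)`` (UniProt-piped accessions are resolved).  Rows with
    several slash-separated site assignments are ambiguous and dropped.  The
    linker name comes from a ``Linker`` column when present, else
    ``default_linker``.  Returns the collapsed links plus a rejection log.
    """
    raw: list[tuple[str, int, str, int, str, int]] = []
    rejections: list[Rejection] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path}: empty pLink2 file")
        by_lower = {name.lower(): name for name in reader.fieldnames}
        site_col = by_lower.get("proteins")
        if site_col is None:
            raise InputFormatError(f"{path}: no 'Proteins' column in pLink2 file")
        linker_col = by_lower.get("linker")
        for rownum, row in enumerate(reader, start=2):
            value = (row.get(site_col) or "").strip().rstrip("/")
            pairs = [p for p in value.split("/") if p]
            if len(pairs) != 1:
                rejections.append(Rejection(rownum, "ambiguous or empty site localization"))
                continue
            m = _SITE_PAIR.match(pairs[0])
            if not m:
                rejections.append(Rejection(rownum, f"malformed site string {pairs[0]!r}"))
                log.warning("%s row %d: malformed site string %r", path, rownum, pairs[0])
                continue
            pa = _resolve_accession(m.group(1))
            pb = _resolve_accession(m.group(3))
            sa, sb = int(m.group(2)), int(m.group(4))
            linker = (row.get(linker_col) or "").strip() if linker_col else ""
            linker = linker or default_linker
            reason = _validate_sites(pa, sa, pb, sb, sequences)
            if reason is not None:
                rejections.append(Rejection(rownum, reason))
                continue
            raw.append((pa, sa, pb, sb, linker, 1))
    return _collapse(raw), rejections


GENERIC_COLUMNS = ("protein_a", "pos_a", "protein_b", "pos_b", "linker")


def parse_generic(path: str | Path, sequences: Mapping[str, ProteinSequence],
                  ) -> tuple[list[CrossLink], list[Rejection]]:
    """Parse the generic cross-link TSV.

    Header columns: protein_a, pos_a, protein_b, pos_b, linker and an optional
    count column (default 1).  Same normalization and rejection contract as
    :func:`parse_plink2`.
    """
    raw: list[tuple[str, int, str, int, str, int]] = []
    rejections: list[Rejection] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path}: empty cross-link TSV")
        missing = [c for c in GENERIC_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise InputFormatError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
        has_count = "count" in reader.fieldnames
        for rownum, row in enumerate(reader, start=2):
            try:
                sa = int(row["pos_a"])
                sb = int(row["pos_b"])
                n = int(row["count"]) if has_count and row["count"] else 1
            except (TypeError, ValueError):
                rejections.append(Rejection(rownum, "non-integer position or count"))
                log.warning("%s row %d: non-integer position or count", path, rownum)
                continue
            pa, pb = row["protein_a"].strip(), row["protein_b"].strip()
            linker = row["linker"].strip()
            reason = _validate_sites(pa, sa, pb, sb, sequences)
            if reason is not None:
                rejections.append(Rejection(rownum, reason))
                continue
            raw.append((pa, sa, pb, sb, linker, n))
    return _collapse(raw), rejections


def write_generic(links: Iterable[CrossLink], path: str | Path) -> None:
    """Serialize links to the generic TSV; re-parsing round-trips exactly."""
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(GENERIC_COLUMNS + ("count",)) + "\n")
        for lk in sorted(links, key=lambda l: l.key):
            fh.write(f"{lk.protein_a}\t{lk.pos_a}\t{lk.protein_b}\t{lk.pos_b}"
                     f"\t{lk.linker}\t{lk.spectral_count}\n")


# ---------------------------------------------------------------------------
# PPI grouping
# ---------------------------------------------------------------------------

def group_ppis(links: Iterable[CrossLink]) -> list[PPI]:
    """Partition links into one PPI per unordered protein pair.

    Intra-protein links yield single-protein PPIs.  The sum of link counts is
    preserved and the output order is deterministic (sorted by protein pair).
    """
    groups: dict[tuple[str, str], list[CrossLink]] = {}
    for lk in links:
        groups.setdefault((lk.protein_a, lk.protein_b), []).append(lk)
    return [
        PPI(pa, pb, tuple(sorted(groups[(pa, pb)], key=lambda l: l.key)))
        for pa, pb in sorted(groups)
    ]
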