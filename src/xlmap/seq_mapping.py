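"""Sequence-to-structure residue mapping via exact local alignment.

Each database protein is aligned against every chain sequence of a candidate
structure with Smith–Waterman under BLOSUM62 and affine gaps (open 11,
extend 1 — the classic protein BLAST defaults), replacing a heuristic BLAST
call with the exact optimum.  Accepted alignments (identity and coverage above
threshold) become position-level maps from database coordinates to structure
residues.  A protein may map to several chains (homo-oligomers); all accepted
chains are retained and multiplicity is resolved downstream by the distance
module.

Tie-breaking is fully deterministic: among equal-scoring end cells the one
with the smallest target index, then smallest query index, wins, and the
traceback prefers diagonal over up (gap in target) over left (gap in query).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Align import substitution_matrices

from .crosslink_io import ProteinSequence
from .structure_io import ResidueRecord, StructureModel

log = logging.getLogger("xlmap")

GAP_OPEN = 11
GAP_EXTEND = 1

DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MIN_COVERAGE = 0.3

_NEG = -(10 ** 9)


def _blosum62_lookup() -> dict[tuple[str, str], int]:
    mat = substitution_matrices.load("BLOSUM62")
    alpha = mat.alphabet
    table: dict[tuple[str, str], int] = {}
    for i, a in enumerate(alpha):
        for j, b in enumerate(alpha):
            table[(a, b)] = int(mat[i, j])
    return table


_BLOSUM62 = _blosum62_lookup()


def _score(a: str, b: str) -> int:
    """BLOSUM62 substitution score; unknown letters fall back to X."""
    try:
        return _BLOSUM62[(a, b)]
    except KeyError:
        a = a if (a, "A") in _BLOSUM62 else "X"
        b = b if ("A", b) in _BLOSUM62 else "X"
        return _BLOSUM62[(a, b)]


@dataclass
class AlignmentResult:
    """Optimal local alignment of a query (database) vs target (chain) sequence.

    ``aligned_pairs`` holds 1-based (query_pos, target_pos) for every
    match/mismatch column; gap columns are absent.  ``identity`` is the
    fraction of identical aligned columns; spans are 1-based inclusive.
    """

    score: int
    identity: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    aligned_pairs: list[tuple[int, int]]


def local_align(query: str, target: str,
                gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND,
                ) -> AlignmentResult:
    """Exact Smith–Waterman local alignment with affine gap penalties.

    A gap of length L costs ``gap_open + L * gap_extend``.  Returns a
    zero-score result with no aligned pairs when no positive-scoring local
    alignment exists.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    n, m = len(query), len(target)
    first_open = gap_open + gap_extend  # cost of the first gapped position

    # H: best alignment ending at (i, j); E: ending with gap in query
    # (consuming target); F: ending with gap in target (consuming query).
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]

    best_score, best_i, best_j = 0, 0, 0
    for i in range(1, n + 1):
        qc = query[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - first_open, Ei[j - 1] - gap_extend)
            f = max(Hi1[j] - first_open, Fi1[j] - gap_extend)
            h = max(0, Hi1[j - 1] + _score(qc, target[j - 1]), e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            # deterministic best cell: highest score, then smallest target
            # index, then smallest query index
            if h > best_score or (h == best_score and h > 0 and
                                  (j, i) < (best_j, best_i)):
                best_score, best_i, best_j = h, i, j

    pairs: list[tuple[int, int]] = []
    i, j, state = best_i, best_j, "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            if H[i - 1][j - 1] + _score(query[i - 1], target[j - 1]) == h:
                pairs.append((i, j))
                i -= 1
                j -= 1
            elif F[i][j] == h:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # vertical: gap in target, consumes query
            if H[i - 1][j] - first_open == F[i][j]:
                state = "H"
            i -= 1
        else:  # "E", horizontal: gap in query, consumes target
            if H[i][j - 1] - first_open == E[i][j]:
                state = "H"
            j -= 1
    pairs.reverse()

    if not pairs:
        return AlignmentResult(0, 0.0, (0, 0), (0, 0), [])
    matches = sum(1 for q, t in pairs if query[q - 1] == target[t - 1])
    return AlignmentResult(
        score=best_score,
        identity=matches / len(pairs),
        query_span=(pairs[0][0], pairs[-1][0]),
        target_span=(pairs[0][1], pairs[-1][1]),
        aligned_pairs=pairs,
    )


@dataclass
class ResidueMap:
    """Accepted alignment of one protein onto one structure chain.

    ``pos_map`` sends 1-based database positions to structure residues; gap
    columns are simply absent.  ``coverage`` is the aligned query span length
    over the query length.
    """

    accession: str
    entry_id: str
    chain_id: str
    pos_map: dict[int, ResidueRecord]
    identity: float
    coverage: float


def build_residue_map(protein: ProteinSequence, structure: StructureModel,
                      min_identity: float = DEFAULT_MIN_IDENTITY,
                      min_coverage: float = DEFAULT_MIN_COVERAGE,
                      ) -> list[ResidueMap]:
    """Align one protein against every chain; keep all accepted chains.

    A chain is accepted when alignment identity >= min_identity and query
    coverage >= min_coverage.  Returns an empty list (logged) when no chain
    passes — e.g. the structure simply does not contain this protein.
    """
    maps: list[ResidueMap] = []
    for chain in structure.chains:
        if not chain.sequence:
            continue
        aln = local_align(protein.sequence, chain.sequence)
        if not aln.aligned_pairs:
            continue
        span = aln.query_span[1] - aln.query_span[0] + 1
        coverage = span / len(protein.sequence)
        if aln.identity < min_identity or coverage < min_coverage:
            continue
        pos_map = {q: chain.residues[t - 1] for q, t in aln.aligned_pairs}
        maps.append(ResidueMap(
            accession=protein.accession,
            entry_id=structure.entry_id,
            chain_id=chain.chain_id,
            pos_map=pos_map,
            identity=aln.identity,
            coverage=coverage,
        ))
    if not maps:
        log.debug("%s: no chain of %s accepted", protein.accession, structure.entry_id)
    return maps


def map_site(link_site: tuple[str, int], maps: Iterable[ResidueMap],
             ) -> list[tuple[str, str, ResidueRecord]]:
    """Resolve one (accession, database position) to structure residues.

    Returns (entry_id, chain_id, residue) for every accepted chain copy where
    the position is aligned and the residue has a Cα; unaligned positions and
    Cα-less residues yield no hit for that chain.
    """
    accession, pos = link_site
    hits: list[tuple[str, str, ResidueRecord]] = []
    for rmap in maps:
        if rmap.accession != accession:
            continue
        res = rmap.pos_map.get(pos)
        if res is not None and res.ca_xyz is not None:
            hits.append((rmap.entry_id, rmap.chain_id, res))
    return hits
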