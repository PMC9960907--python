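"""Result tables and PyMOL visualization scripts.

Three TSV outputs: a comprehensive per-link distance table, a per-structure
summary, and the ranked pair-score table.  All files are written atomically
(temp file + rename), carry the tool version and a config echo in leading
``#`` comment lines, and are byte-deterministic for identical inputs —
distances are rounded to 3 decimals (round-half-even) for that reason.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import __version__
from .distance import PairReport, SATISFIED, OVER_LENGTH
from .errors import XlmapError

log = logging.getLogger("xlmap")

DEFAULT_COLORS = {"satisfied": "yellow", "over_length": "red"}


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _header_lines(meta: Mapping[str, object] | None) -> list[str]:
    lines = [f"# xlmap {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    return lines


def _fmt_distance(d: float | None) -> str:
    return "" if d is None else f"{d:.3f}"


def _sorted_reports(reports: Iterable[PairReport]) -> list[PairReport]:
    return sorted(reports, key=lambda r: (r.ppi.key, r.entry_id))


COMPREHENSIVE_COLUMNS = (
    "protein_a", "pos_a", "protein_b", "pos_b", "linker", "spectral_count",
    "entry_id", "chain_a", "res_a", "chain_b", "res_b", "distance", "status",
)


def write_comprehensive(reports: Iterable[PairReport], path: str | Path,
                        meta: Mapping[str, object] | None = None) -> Path:
    """All PPI and structural distance information, one row per link record."""
    path = Path(path)
    rows = _header_lines(meta)
    rows.append("\t".join(COMPREHENSIVE_COLUMNS))
    for report in _sorted_reports(reports):
        for rec in report.records:
            lk = rec.link
            rows.append("\t".join((
                lk.protein_a, str(lk.pos_a), lk.protein_b, str(lk.pos_b),
                lk.linker, str(lk.spectral_count), rec.entry_id,
                rec.chain_a or "", rec.res_a.auth_label if rec.res_a else "",
                rec.chain_b or "", rec.res_b.auth_label if rec.res_b else "",
                _fmt_distance(rec.distance), rec.status,
            )))
    _atomic_write(path, "\n".join(rows) + "\n")
    return path


BY_STRUCTURE_COLUMNS = (
    "entry_id", "n_ppis", "n_links_mapped", "n_satisfied", "n_over", "best_score",
)


def write_by_structure(reports: Iterable[PairReport], path: str | Path,
                       meta: Mapping[str, object] | None = None) -> Path:
    """PPIs categorized by structure entry, with per-entry aggregate counts."""
    path = Path(path)
    groups: dict[str, list[PairReport]] = {}
    for report in _sorted_reports(reports):
        groups.setdefault(report.entry_id, []).append(report)
    rows = _header_lines(meta)
    rows.append("\t".join(BY_STRUCTURE_COLUMNS))
    for entry in sorted(groups):
        reps = groups[entry]
        best = max((r.score for r in reps if r.score is not None), default=None)
        rows.append("\t".join((
            entry, str(len(reps)),
            str(sum(r.n_mapped for r in reps)),
            str(sum(r.n_satisfied for r in reps)),
            str(sum(r.n_over for r in reps)),
            "" if best is None else f"{best:.3f}",
        )))
    _atomic_write(path, "\n".join(rows) + "\n")
    return path


SCORE_COLUMNS = (
    "protein_a", "protein_b", "entry_id", "n_total", "n_mapped", "n_satisfied",
    "n_over", "f_sat", "coverage", "violation", "evidence", "score",
)


def write_scores(ranked: Sequence[PairReport], histogram: Sequence[int],
                 path: str | Path,
                 meta: Mapping[str, object] | None = None) -> Path:
    """The ranked pair-score table; histogram counts go into trailing comments."""
    path = Path(path)
    rows = _header_lines(meta)
    rows.append("\t".join(SCORE_COLUMNS))
    for r in ranked:
        f = r.features
        rows.append("\t".join((
            r.ppi.protein_a, r.ppi.protein_b, r.entry_id,
            str(r.n_total), str(r.n_mapped), str(r.n_satisfied), str(r.n_over),
            f"{f.f_sat:.4f}" if f else "", f"{f.coverage:.4f}" if f else "",
            f"{f.violation:.4f}" if f else "", f"{f.evidence:.4f}" if f else "",
            f"{r.score:.3f}" if r.score is not None else "",
        )))
    for i, count in enumerate(histogram):
        lo, hi = i * 5, i * 5 + 5
        rows.append(f"# hist[{lo}-{hi}): {count}")
    _atomic_write(path, "\n".join(rows) + "\n")
    return path


def _pml_selection(entry: str, chain: str, res_label: str) -> str:
    return f"({entry} and chain {chain} and resi {res_label} and name CA)"


def write_pymol(report: PairReport, directory: str | Path,
                colors: Mapping[str, str] = DEFAULT_COLORS,
                structure_file: str | None = None) -> Path | None:
    """Write a .pml script drawing every mapped cross-link of one pair.

    The script loads the structure, draws one distance object per mapped
    record using author chain/residue/CA selections (insertion codes
    included), colors satisfied and over-length links distinctly and stamps
    the pair score on a label.  Returns None (logged) when the report has no
    mapped record.
    """
    mapped = [r for r in report.records if r.status in (SATISFIED, OVER_LENGTH)]
    if not mapped:
        log.info("pair %s/%s on %s: no mapped record, no PyMOL script",
                 report.ppi.protein_a, report.ppi.protein_b, report.entry_id)
        return None
    directory = Path(directory)
    entry = report.entry_id
    if structure_file is None:
        structure_file = f"{entry}.cif"
    name = f"{report.ppi.protein_a}_{report.ppi.protein_b}_{entry}.pml"
    lines = [
        f"# xlmap {__version__} cross-link visualization",
        f"# pair: {report.ppi.protein_a} - {report.ppi.protein_b} on {entry}",
        f"load {structure_file}, {entry}",
        "hide everything",
        f"show cartoon, {entry}",
        f"color grey80, {entry}",
    ]
    for idx, rec in enumerate(mapped, start=1):
        obj = f"xl_{idx:04d}"
        sel_a = _pml_selection(entry, rec.chain_a, rec.res_a.auth_label)
        sel_b = _pml_selection(entry, rec.chain_b, rec.res_b.auth_label)
        lines.append(f"distance {obj}, {sel_a}, {sel_b}")
        lines.append(f"color {colors[rec.status]}, {obj}")
    score_txt = "unscored" if report.score is None else f"{report.score:.1f}"
    lines.append(
        f'pseudoatom {entry}_score, label="pair score {score_txt}", pos=[0, 0, 0]')
    lines.append("set dash_gap, 0.4")
    lines.append("set label_size, 14")
    path = directory / name
    _atomic_write(path, "\n".join(lines) + "\n")
    return path
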