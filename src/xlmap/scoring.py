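"""Per PPI-structure-pair dynamism scoring.

The score summarizes how well a structure explains the observed cross-links:
a high score means the restraints are consistent with the static structure,
a low score points to conformational dynamism or a mismatched structure.

Features per pair
-----------------
f_sat      n_satisfied / n_mapped                (0 when nothing is mapped)
coverage   n_mapped / n_total
violation  mean over over-length links of (distance - max) / max, >= 0
evidence   n_mapped / (n_mapped + k), a pseudo-count confidence weight

Score
-----
score = 100 * evidence * max(0, w_s * f_sat + w_c * coverage
                                 - w_v * min(violation, 1))

With the default weights (w_s=0.7, w_c=0.3, w_v=0.2, k=3) the score lives in
[0, 100], is monotone increasing in f_sat and coverage, decreasing in
violation, and approaches 100 only with many mapped, fully satisfied links:
the pseudo-count k keeps a single lucky restraint from scoring 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .distance import OVER_LENGTH, PairReport
from .errors import ConfigError


@dataclass(frozen=True)
class ScoreFeatures:
    f_sat: float
    coverage: float
    violation: float
    n_mapped: int
    evidence: float


@dataclass(frozen=True)
class ScoreWeights:
    w_s: float = 0.7
    w_c: float = 0.3
    w_v: float = 0.2
    k: float = 3.0

    def __post_init__(self) -> None:
        if min(self.w_s, self.w_c, self.w_v) < 0 or self.k < 0:
            raise ConfigError("score weights must be non-negative")
        if abs(self.w_s + self.w_c - 1.0) > 1e-9:
            raise ConfigError(f"w_s + w_c must equal 1, got {self.w_s + self.w_c}")


DEFAULT_WEIGHTS = ScoreWeights()


def compute_features(report: PairReport, k: float = DEFAULT_WEIGHTS.k) -> ScoreFeatures:
    """Derive the score features of one PPI-structure pair from its records."""
    n_mapped = report.n_mapped
    f_sat = report.n_satisfied / n_mapped if n_mapped else 0.0
    coverage = n_mapped / report.n_total if report.n_total else 0.0
    over = [(r.distance - r.max_distance) / r.max_distance
            for r in report.records if r.status == OVER_LENGTH]
    violation = sum(over) / len(over) if over else 0.0
    evidence = n_mapped / (n_mapped + k) if n_mapped else 0.0
    return ScoreFeatures(f_sat, coverage, violation, n_mapped, evidence)


def compute_score(features: ScoreFeatures,
                  weights: ScoreWeights = DEFAULT_WEIGHTS) -> float:
    """Bounded [0, 100] agreement score from the pair features."""
    raw = (weights.w_s * features.f_sat
           + weights.w_c * features.coverage
           - weights.w_v * min(features.violation, 1.0))
    return min(100.0, max(0.0, 100.0 * features.evidence * max(0.0, raw)))


def score_report(report: PairReport,
                 weights: ScoreWeights = DEFAULT_WEIGHTS) -> PairReport:
    """Fill in a report's features and score in place (and return it)."""
    report.features = compute_features(report, weights.k)
    report.score = compute_score(report.features, weights)
    return report


HIST_BIN_WIDTH = 5


def score_table(reports: Iterable[PairReport],
                ) -> tuple[list[PairReport], list[int]]:
    """Rank scored reports and build the global score histogram.

    Returns the reports sorted by score descending (ties broken by entry id,
    then protein pair) plus histogram counts over [0, 100] in bins of width 5
    (the last bin includes 100).  Bin counts sum to the number of reports.
    """
    ranked = sorted(reports, key=lambda r: (-(r.score or 0.0), r.entry_id, r.ppi.key))
    hist = [0] * (100 // HIST_BIN_WIDTH)
    for r in ranked:
        idx = min(int((r.score or 0.0) // HIST_BIN_WIDTH), len(hist) - 1)
        hist[idx] += 1
    return ranked, hist
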