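"""Direction concordance between human eQTL evidence and mouse knockouts.

For a gene implicated by a pleiotropy-selected variant, two independent
lines of evidence can agree on mechanism: the direction in which the
*protective* allele shifts the gene's expression in human tissue, and the
direction in which knocking the gene out shifts lean mass and strength in
mice.  If the protective allele raises expression, losing the gene should
be harmful (knockout decreases lean mass/strength) — and vice versa.  This
module scores that agreement gene by gene and tallies the evidence set,
including how many implicated genes respond to resistance exercise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

ConcordanceFlag = Literal["concordant", "discordant", "undetermined"]


@dataclass(frozen=True)
class GeneEvidence:
    """Per-gene evidence directions.

    ``expression_direction``: +1 if the protective allele increases the
    gene's expression, -1 if it decreases it, None if unknown.
    ``knockout_direction``: +1 if knockout increases lean mass and strength
    in mice, -1 if it decreases them, None if unknown or not significant
    (``knockout_tested`` distinguishes tested-without-effect from untested).
    ``exercise_response``: expression change after a single bout of
    resistance exercise ('up', 'down', 'none', 'unknown').
    """

    gene: str
    expression_direction: int | None = None
    knockout_direction: int | None = None
    knockout_tested: bool = False
    exercise_response: str = "unknown"

    def __post_init__(self) -> None:
        for d in (self.expression_direction, self.knockout_direction):
            if d not in (+1, -1, None):
                raise ValueError(f"{self.gene}: direction must be +1, -1 or None")
        if self.exercise_response not in ("up", "down", "none", "unknown"):
            raise ValueError(f"{self.gene}: bad exercise_response {self.exercise_response!r}")
        if self.knockout_direction is not None and not self.knockout_tested:
            raise ValueError(f"{self.gene}: knockout direction implies knockout_tested")


def concordant(evidence: GeneEvidence) -> ConcordanceFlag:
    """Score human-vs-mouse direction agreement for one gene.

    Concordant patterns: protective allele raises expression and knockout
    lowers lean mass/strength (losing the gene is harmful), or protective
    allele lowers expression and knockout raises lean mass/strength.  If
    either direction is unknown the gene is undetermined.
    """
    e, k = evidence.expression_direction, evidence.knockout_direction
    if e is None or k is None:
        return "undetermined"
    return "concordant" if e == -k else "discordant"


def concordance_summary(evidence: Iterable[GeneEvidence]) -> dict[str, int]:
    """Tally a gene-evidence set.

    Returns counts of concordant / discordant / undetermined genes, how many
    genes had mouse knockout data at all (``knockout_tested``), how many of
    those showed a significant knockout effect (``knockout_significant``),
    and how many genes respond to resistance exercise
    (``exercise_responsive`` = up- or downregulated).
    """
    counts = {
        "concordant": 0,
        "discordant": 0,
        "undetermined": 0,
        "knockout_tested": 0,
        "knockout_significant": 0,
        "exercise_responsive": 0,
    }
    for ev in evidence:
        counts[concordant(ev)] += 1
        if ev.knockout_tested:
            counts["knockout_tested"] += 1
        if ev.knockout_direction is not None:
            counts["knockout_significant"] += 1
        if ev.exercise_response in ("up", "down"):
            counts["exercise_responsive"] += 1
    return counts
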