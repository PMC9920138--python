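"""Unweighted polygenic risk scores and quantile risk bands.

The score of an individual is the plain count of risk alleles over a
variant set (0/1/2 per variant: homozygous non-risk, heterozygous,
homozygous risk).  Individuals are then split into five ~20% groups ordered
by score — low, below-average, average, above-average and high risk — and
each band reports its observed risk-allele-count range and size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .panel import MISSING, GenotypePanel
from .sumstats import VariantKey

logger = logging.getLogger(__name__)

BAND_LABELS = ("low", "below_average", "average", "above_average", "high")


@dataclass(frozen=True)
class RiskBand:
    label: str
    min_alleles: int
    max_alleles: int
    n_individuals: int


@dataclass(frozen=True)
class RiskBandTable:
    """Five ordered risk bands with observed allele-count ranges and sizes."""

    trait_label: str
    n_snps: int
    bands: tuple[RiskBand, ...]
    assignments: tuple[str, ...] = ()  # band label per sample, panel order

    def __post_init__(self) -> None:
        sizes = sum(b.n_individuals for b in self.bands)
        mins = [b.min_alleles for b in self.bands]
        if mins != sorted(mins):
            raise ValueError("bands must be ordered by min_alleles")
        if self.assignments and len(self.assignments) != sizes:
            raise ValueError("assignments must cover every banded sample")


@dataclass(frozen=True)
class ScoreResult:
    """Per-sample integer risk-allele counts plus a missingness audit."""

    sample_ids: tuple[str, ...]
    scores: np.ndarray  # integer risk-allele counts
    missing_counts: np.ndarray  # variants with missing genotype per sample
    n_snps: int


def risk_score(
    panel: GenotypePanel, risk_alleles: Mapping[VariantKey, str]
) -> ScoreResult:
    """Sum of risk-allele dosages per individual over the scored variants.

    ``risk_alleles`` maps each scored variant to its risk allele, which
    must belong to that variant's allele pair (else a configuration error
    naming the variant).  Missing genotypes contribute 0 to the score and
    are counted per sample in ``missing_counts``.
    """
    scores = np.zeros(panel.n_samples, dtype=np.int64)
    missing_counts = np.zeros(panel.n_samples, dtype=np.int64)
    for variant, allele in risk_alleles.items():
        if allele not in variant.alleles:
            raise ValueError(
                f"risk allele {allele} not in allele pair of {variant.rsid}"
            )
        d = panel.dosage_of_allele(variant, allele)
        missing = d == MISSING
        missing_counts += missing
        scores += np.where(missing, 0, d)
    return ScoreResult(
        sample_ids=tuple(panel.sample_ids),
        scores=scores,
        missing_counts=missing_counts,
        n_snps=len(risk_alleles),
    )


def stratify(
    scores: ScoreResult | Sequence[int],
    n_bands: int = 5,
    sample_ids: Sequence[str] | None = None,
    trait_label: str = "",
    n_snps: int | None = None,
) -> RiskBandTable:
    """Split individuals into ``n_bands`` contiguous score-ordered groups.

    Samples are sorted ascending by (score, sample_id) — the secondary key
    makes tie-breaking deterministic — and cut into consecutive groups
    whose sizes differ by at most one, the remainder going to the lowest
    bands first (503 samples in 5 bands -> 101/101/101/100/100).  Each band
    reports its observed min/max score; when equal scores straddle a
    boundary adjacent ranges may touch.
    """
    if isinstance(scores, ScoreResult):
        sample_ids = list(scores.sample_ids)
        n_snps = scores.n_snps if n_snps is None else n_snps
        values = np.asarray(scores.scores)
    else:
        values = np.asarray(list(scores))
        if sample_ids is None:
            sample_ids = [f"sample{i}" for i in range(len(values))]
    n = len(values)
    if n < n_bands:
        raise ValueError(f"need at least {n_bands} samples, have {n}")
    if n_snps is None:
        n_snps = int(values.max()) // 2 + 1 if n else 0

    order = sorted(range(n), key=lambda i: (values[i], sample_ids[i]))
    base, remainder = divmod(n, n_bands)
    sizes = [base + (1 if b < remainder else 0) for b in range(n_bands)]
    labels = (
        BAND_LABELS
        if n_bands == len(BAND_LABELS)
        else tuple(f"band{b + 1}" for b in range(n_bands))
    )

    bands = []
    assignment = [""] * n
    start = 0
    for label, size in zip(labels, sizes):
        members = order[start : start + size]
        start += size
        member_scores = values[members]
        bands.append(
            RiskBand(
                label=label,
                min_alleles=int(member_scores.min()),
                max_alleles=int(member_scores.max()),
                n_individuals=size,
            )
        )
        for i in members:
            assignment[i] = label
    return RiskBandTable(
        trait_label=trait_label,
        n_snps=int(n_snps),
        bands=tuple(bands),
        assignments=tuple(assignment),
    )
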