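"""Pairwise linkage disequilibrium (r-squared) and greedy pruning.

LD is estimated as the squared Pearson correlation of unphased dosage
vectors over pairwise-complete samples (composite LD), which is sign-free:
counting either allele at either variant gives the same r-squared.  Pruning
walks the candidates best-first and keeps a candidate only if its r-squared
with every already-kept candidate stays at or below the threshold, so no
retained pair exceeds it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .panel import MISSING, GenotypePanel
from .select import HarmonizedVariant
from .sumstats import VariantKey

logger = logging.getLogger(__name__)

R2_THRESHOLD = 0.2  # pairs above this are not counted as independent signals


@dataclass(frozen=True)
class LDResult:
    """r-squared between two variants plus the sample count it used.

    ``defined`` is False when a dosage vector is constant on the shared
    non-missing samples (correlation undefined); such pairs are treated as
    unlinked (r2 = 0) for pruning, with a log entry.
    """

    variant_i: VariantKey
    variant_j: VariantKey
    r2: float
    n_used: int
    defined: bool = True


def r_squared(
    panel: GenotypePanel, variant_i: VariantKey, variant_j: VariantKey
) -> LDResult:
    """Squared dosage correlation over pairwise-complete samples."""
    di = panel.dosages[:, panel.index_of(variant_i)].astype(float)
    dj = panel.dosages[:, panel.index_of(variant_j)].astype(float)
    mask = (di != MISSING) & (dj != MISSING)
    n_used = int(mask.sum())
    if n_used < 2:
        raise ValueError(
            f"r2({variant_i.rsid},{variant_j.rsid}): need >=2 shared samples, have {n_used}"
        )
    xi, xj = di[mask], dj[mask]
    if np.ptp(xi) == 0 or np.ptp(xj) == 0:
        logger.info(
            "r2(%s,%s): constant dosage vector; LD undefined, treated as 0",
            variant_i.rsid, variant_j.rsid,
        )
        return LDResult(variant_i, variant_j, 0.0, n_used, defined=False)
    r = np.corrcoef(xi, xj)[0, 1]
    return LDResult(variant_i, variant_j, min(float(r) ** 2, 1.0), n_used)


def _variant_of(candidate) -> VariantKey:
    return candidate.variant if isinstance(candidate, HarmonizedVariant) else candidate


def rank_by_min_p(candidates: Sequence[HarmonizedVariant]) -> list[HarmonizedVariant]:
    """Rank candidates by ascending minimum p across the sarcopenia
    categories (strongest signal first); ties broken by rsid."""
    return sorted(candidates, key=lambda hv: (hv.min_sarcopenia_p(), hv.variant.rsid))


def greedy_prune(
    candidates: Sequence,
    panel: GenotypePanel,
    r2_threshold: float = R2_THRESHOLD,
) -> list:
    """Best-first pruning so no retained pair has r-squared above threshold.

    ``candidates`` (HarmonizedVariant or bare VariantKey) must already be
    ranked best-first; output preserves that order.  Candidates absent from
    the panel cannot be tested for LD and pass through with a warning.
    """
    retained: list = []
    retained_in_panel: list[VariantKey] = []
    n_pruned = 0
    for candidate in candidates:
        variant = _variant_of(candidate)
        if variant not in panel:
            logger.warning(
                "prune: %s not in panel; retained without LD check", variant.rsid
            )
            retained.append(candidate)
            continue
        independent = all(
            r_squared(panel, variant, kept).r2 <= r2_threshold
            for kept in retained_in_panel
        )
        if independent:
            retained.append(candidate)
            retained_in_panel.append(variant)
        else:
            n_pruned += 1
    logger.info("prune: retained %d, pruned %d (r2>%g)", len(retained), n_pruned, r2_threshold)
    return retained


def ld_table(panel: GenotypePanel, variants: Sequence[VariantKey]) -> list[LDResult]:
    """All-pairs LD among ``variants`` present in the panel."""
    present = [v for v in variants if v in panel]
    results = []
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            results.append(r_squared(panel, present[i], present[j]))
    return results
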