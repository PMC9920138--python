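"""Nested tier classification: sarcopenia -> sarcopenic obesity -> diabesity.

Every pleiotropy-selected variant is a sarcopenia predictor.  If its *risk*
allele (the non-protective allele) is additionally associated with higher
body fat percentage at p < 0.005, the variant is upgraded to a sarcopenic-
obesity predictor; if on top of that the risk allele raises type-2-diabetes
risk at p < 0.005, to a sarcopenic-diabesity predictor.  The tiers are
nested by construction: diabesity requires the obesity condition first.
Auxiliary traits (tiredness, falls, bone mineral density, ...) are counted
with the direction of the association recorded against the risk allele.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .fixtures import NS, PanelRow
from .select import HarmonizedVariant
from .sumstats import AssociationRecord, TraitSpec, VariantKey, align_to_allele

logger = logging.getLogger(__name__)

TIER_THRESHOLD = 0.005

TIERS = ("sarcopenia", "sarcopenic_obesity", "sarcopenic_diabesity")


@dataclass(frozen=True)
class DirectionalEvidence:
    """Association evidence for one follow-up trait at one variant:
    the p-value and whether the *risk* allele associates with the higher
    trait value."""

    p: float
    risk_increases: bool


@dataclass(frozen=True)
class PleiotropyCall:
    """A selected variant with its tier and follow-up associations.

    ``p_fat``/``p_t2d`` hold the trait p-value when the association is a
    qualifying hit (p < 0.005 with the risk allele increasing the trait),
    otherwise the NS marker.  ``aux_hits`` maps auxiliary trait name to +1
    if the risk allele associates with the higher trait value, -1 if the
    protective allele does.
    """

    variant: VariantKey
    protective_allele: str
    risk_allele: str
    p_strength: float
    p_lean: float
    p_walk: float
    p_fat: object = NS
    p_t2d: object = NS
    tier: str = "sarcopenia"
    gene_label: str | None = None
    aux_hits: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protective_allele == self.risk_allele:
            raise ValueError(f"{self.variant.rsid}: protective == risk allele")
        for allele in (self.protective_allele, self.risk_allele):
            if allele not in self.variant.alleles:
                raise ValueError(f"{self.variant.rsid}: {allele} not in allele pair")
        if self.tier not in TIERS:
            raise ValueError(f"bad tier {self.tier}")
        if self.tier != "sarcopenia" and self.p_fat is NS:
            raise ValueError("obesity tier requires a body-fat hit")
        if self.tier == "sarcopenic_diabesity" and self.p_t2d is NS:
            raise ValueError("diabesity tier requires a T2D hit")


def assign_tier(
    variant: VariantKey,
    protective_allele: str,
    p_strength: float,
    p_lean: float,
    p_walk: float,
    fat: DirectionalEvidence | None = None,
    t2d: DirectionalEvidence | None = None,
    threshold: float = TIER_THRESHOLD,
    gene_label: str | None = None,
) -> PleiotropyCall:
    """Classify one selected variant into its nested tier.

    The base tier is sarcopenia.  A body-fat association with p < threshold
    whose risk allele increases adiposity upgrades to sarcopenic obesity; a
    further T2D association with p < threshold whose risk allele increases
    T2D risk upgrades to sarcopenic diabesity.  Missing follow-up evidence
    leaves the tier unchanged (logged).
    """
    risk_allele = variant.other_allele(protective_allele)
    p_fat: object = NS
    p_t2d: object = NS
    tier = "sarcopenia"
    if fat is None:
        logger.info("tier: %s has no body-fat evidence; stays sarcopenia", variant.rsid)
    elif fat.p < threshold and fat.risk_increases:
        p_fat = fat.p
        tier = "sarcopenic_obesity"
    if t2d is not None and t2d.p < threshold and t2d.risk_increases:
        p_t2d = t2d.p
        if tier == "sarcopenic_obesity":
            tier = "sarcopenic_diabesity"
    return PleiotropyCall(
        variant=variant,
        protective_allele=protective_allele,
        risk_allele=risk_allele,
        p_strength=p_strength,
        p_lean=p_lean,
        p_walk=p_walk,
        p_fat=p_fat,
        p_t2d=p_t2d,
        tier=tier,
        gene_label=gene_label,
    )


def call_from_selection(
    hv: HarmonizedVariant,
    threshold: float = TIER_THRESHOLD,
    gene_label: str | None = None,
) -> PleiotropyCall:
    """Tier-classify a pleiotropy-selected harmonized variant.

    Adiposity/T2D evidence in the harmonized record is aligned to the
    reference allele; the risk allele increases the trait iff the beta per
    protective-allele copy is negative.
    """
    if hv.protective_allele is None:
        raise ValueError(f"{hv.variant.rsid}: not a selected variant (no protective allele)")
    sign = 1.0 if hv.protective_allele == hv.reference_allele else -1.0

    def directional(category: str) -> DirectionalEvidence | None:
        ev = hv.evidence.get(category)
        if ev is None:
            return None
        return DirectionalEvidence(p=ev.p, risk_increases=sign * ev.beta < 0)

    return assign_tier(
        variant=hv.variant,
        protective_allele=hv.protective_allele,
        p_strength=hv.evidence["strength"].p,
        p_lean=hv.evidence["lean_mass"].p,
        p_walk=hv.evidence["walking_pace"].p,
        fat=directional("adiposity"),
        t2d=directional("t2d"),
        threshold=threshold,
        gene_label=gene_label,
    )


def calls_from_table2(rows: Iterable[PanelRow]) -> list[PleiotropyCall]:
    """Build tier-classified calls from the packaged variant panel.

    The table's construction already guarantees direction consistency
    (non-NS body-fat/T2D slots mean the risk allele increases the trait),
    so the tier follows from the NS pattern alone.
    """
    calls = []
    for row in rows:
        fat = None if row.p["fat"] is NS else DirectionalEvidence(row.p["fat"], True)
        t2d = None if row.p["t2d"] is NS else DirectionalEvidence(row.p["t2d"], True)
        calls.append(
            assign_tier(
                variant=row.variant,
                protective_allele=row.protective_allele,
                p_strength=row.p["grip"],
                p_lean=row.p["lean"],
                p_walk=row.p["walk"],
                fat=fat,
                t2d=t2d,
                gene_label=row.gene,
            )
        )
    return calls


def tier_counts(calls: Sequence[PleiotropyCall]) -> dict[str, int]:
    """Headline counters over a call set.

    ``all`` = number of calls; ``unique_loci`` = distinct gene labels;
    ``fat_associated``/``t2d_associated`` = calls whose body-fat/T2D slot is
    a hit (non-NS); ``diabesity`` = calls with both (equivalently, the
    diabesity tier).
    """
    return {
        "all": len(calls),
        "unique_loci": len({c.gene_label for c in calls}),
        "fat_associated": sum(c.p_fat is not NS for c in calls),
        "t2d_associated": sum(c.p_t2d is not NS for c in calls),
        "diabesity": sum(c.p_fat is not NS and c.p_t2d is not NS for c in calls),
    }


def annotate_auxiliary(
    calls: Sequence[PleiotropyCall],
    aux_records: Mapping[str, Iterable[AssociationRecord]],
    trait_specs: Sequence[TraitSpec],
    threshold: float = TIER_THRESHOLD,
) -> tuple[list[PleiotropyCall], Counter]:
    """Populate aux_hits on each call and tally per-trait hit counts.

    A trait enters a call's aux_hits iff its p-value at the call's variant
    is strictly below ``threshold``; the stored direction is +1 when the
    risk allele associates with the higher trait value, -1 when the
    protective allele does.  Records not alignable to a call's alleles are
    skipped with a log entry.
    """
    by_trait_variant: dict = {}
    for trait, records in aux_records.items():
        for record in records:
            by_trait_variant[(trait, record.variant.key)] = record

    per_trait_hits: Counter = Counter()
    annotated = []
    for call in calls:
        hits: dict[str, int] = {}
        for trait in aux_records:
            record = by_trait_variant.get((trait, call.variant.key))
            if record is None:
                continue
            if record.variant.alleles != call.variant.alleles:
                logger.info(
                    "aux: %s/%s allele pair mismatch; skipped", trait, call.variant.rsid
                )
                continue
            if not record.p < threshold:
                continue
            aligned = align_to_allele(record, call.risk_allele)
            if aligned.beta == 0.0:
                continue
            hits[trait] = 1 if aligned.beta > 0 else -1
            per_trait_hits[trait] += 1
        annotated.append(replace(call, aux_hits=hits))
    return annotated, per_trait_hits
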