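"""Two-stage cross-trait pleiotropy selection.

Stage one builds a discovery list: the union of variants reaching each
source GWAS's genome-wide discovery threshold across the handgrip-strength,
lean-mass and walking-pace studies.  Stage two harmonizes all evidence for
each discovery variant to a single reference allele, collapses each trait
*category* (several handgrip GWASes, two lean-mass GWASes, ...) to its
minimum-p record, and keeps variants that replicate at p < 0.005 in all
three sarcopenia categories with effect directions that are consistent —
the same allele protective (or deleterious) for strength, lean mass and
walking pace alike.  The allele whose aligned effects all point in the
benefit direction is reported as the protective allele.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .sumstats import (
    SARCOPENIA_CATEGORIES,
    AssociationRecord,
    TraitSpec,
    VariantKey,
    align_to_allele,
)

logger = logging.getLogger(__name__)

REPLICATION_P = 0.005  # cross-trait matching threshold


class CategoryMissingError(ValueError):
    """A variant has no evidence for a required trait category."""


@dataclass(frozen=True)
class CategoryEvidence:
    """The min-p representative of one trait category at one variant,
    aligned to the variant's reference allele."""

    trait: str
    beta: float
    se: float
    p: float


@dataclass(frozen=True)
class HarmonizedVariant:
    """All per-category evidence for one variant, on one reference allele.

    ``evidence`` maps trait category -> the category's minimum-p record
    (ties broken by trait name), with betas expressed per copy of
    ``reference_allele``.  ``discovery_p``/``discovery_trait`` record the
    strongest source-GWAS association that put the variant on the
    discovery list.  ``protective_allele`` is filled by
    :func:`select_pleiotropic` on the selected variants.
    """

    variant: VariantKey
    reference_allele: str
    evidence: Mapping[str, CategoryEvidence]
    discovery_p: float | None = None
    discovery_trait: str | None = None
    protective_allele: str | None = None

    @property
    def risk_allele(self) -> str | None:
        if self.protective_allele is None:
            return None
        return self.variant.other_allele(self.protective_allele)

    def min_sarcopenia_p(self) -> float:
        """Minimum p across the three sarcopenia categories (pruning rank key)."""
        return min(
            self.evidence[c].p for c in SARCOPENIA_CATEGORIES if c in self.evidence
        )

    def flipped(self) -> "HarmonizedVariant":
        """The same evidence expressed against the opposite allele."""
        other = self.variant.other_allele(self.reference_allele)
        return replace(
            self,
            reference_allele=other,
            evidence={
                c: replace(ev, beta=-ev.beta) for c, ev in self.evidence.items()
            },
        )


def build_discovery_list(
    per_trait_records: Mapping[str, Iterable[AssociationRecord]],
    trait_specs: Sequence[TraitSpec],
) -> list[VariantKey]:
    """Union of variants passing each source trait's discovery threshold.

    Only traits with a ``discovery_threshold`` contribute.  Duplicates are
    collapsed by variant identity (rsid + allele pair); per-trait
    contribution counts are logged.
    """
    specs = {s.name: s for s in trait_specs}
    seen: dict = {}
    any_input = False
    for trait, records in per_trait_records.items():
        spec = specs.get(trait)
        if spec is None or spec.discovery_threshold is None:
            continue
        contributed = 0
        for record in records:
            any_input = True
            if record.p < spec.discovery_threshold:
                if record.variant.key not in seen:
                    seen[record.variant.key] = record.variant
                contributed += 1
        logger.info(
            "discovery: %s contributed %d records below p<%g",
            trait, contributed, spec.discovery_threshold,
        )
    if not any_input:
        logger.warning("discovery: no input records; empty discovery list")
    logger.info("discovery list: %d distinct variants", len(seen))
    return list(seen.values())


def collapse_category(
    records: Sequence[AssociationRecord], reference_allele: str
) -> CategoryEvidence:
    """Collapse one variant's records within one trait category to the
    aligned record with minimal p (ties broken by trait name)."""
    if not records:
        raise CategoryMissingError("no records for category")
    aligned = [align_to_allele(r, reference_allele) for r in records]
    best = min(aligned, key=lambda r: (r.p, r.trait))
    return CategoryEvidence(trait=best.trait, beta=best.beta, se=best.se, p=best.p)


def harmonize(
    per_trait_records: Mapping[str, Iterable[AssociationRecord]],
    trait_specs: Sequence[TraitSpec],
    variants: Iterable[VariantKey] | None = None,
) -> list[HarmonizedVariant]:
    """Group per-trait records by variant and collapse each trait category.

    The reference allele is the lexicographically smaller allele of the
    pair, a convention that makes harmonization independent of input
    order (selection results are invariant to the choice).  If ``variants``
    is given, only those variants are harmonized.
    """
    specs = {s.name: s for s in trait_specs}
    wanted = {v.key for v in variants} if variants is not None else None

    by_variant: dict = defaultdict(lambda: defaultdict(list))
    variant_of: dict = {}
    for trait, records in per_trait_records.items():
        spec = specs.get(trait)
        if spec is None:
            logger.warning("harmonize: trait %s has no spec; skipped", trait)
            continue
        for record in records:
            key = record.variant.key
            if wanted is not None and key not in wanted:
                continue
            variant_of.setdefault(key, record.variant)
            by_variant[key][spec.category].append(record)

    harmonized = []
    for key, categories in by_variant.items():
        variant = variant_of[key]
        reference = min(variant.alleles)
        evidence = {
            category: collapse_category(records, reference)
            for category, records in categories.items()
        }
        discovery_p = None
        discovery_trait = None
        for category, records in categories.items():
            for record in records:
                spec = specs[record.trait]
                if spec.discovery_threshold is None:
                    continue
                if discovery_p is None or record.p < discovery_p:
                    discovery_p = record.p
                    discovery_trait = record.trait
        harmonized.append(
            HarmonizedVariant(
                variant=variant,
                reference_allele=reference,
                evidence=evidence,
                discovery_p=discovery_p,
                discovery_trait=discovery_trait,
            )
        )
    return harmonized


def select_pleiotropic(
    discovery: Iterable[VariantKey],
    harmonized: Iterable[HarmonizedVariant],
    trait_specs: Sequence[TraitSpec],
    replication_threshold: float = REPLICATION_P,
) -> list[HarmonizedVariant]:
    """Keep discovery variants replicating in all three sarcopenia
    categories with consistent effect directions.

    A variant passes iff it has evidence in the strength, lean-mass and
    walking-pace categories, each category's min-p is strictly below
    ``replication_threshold``, and the signs of beta x benefit_direction
    agree across the three (all protective or all deleterious for the
    reference allele).  On the selected variants the protective allele is
    inferred: the reference allele itself when its aligned effects point in
    the benefit direction, otherwise the other allele.  Variants with a
    zero beta in any category have undefined direction and are excluded
    (logged).
    """
    benefit = {s.category: s.benefit_direction for s in trait_specs}
    discovery_keys = {v.key for v in discovery}
    selected = []
    for hv in harmonized:
        if hv.variant.key not in discovery_keys:
            continue
        missing = [c for c in SARCOPENIA_CATEGORIES if c not in hv.evidence]
        if missing:
            logger.info(
                "select: %s excluded; no evidence for %s",
                hv.variant.rsid, ",".join(missing),
            )
            continue
        if not all(
            hv.evidence[c].p < replication_threshold for c in SARCOPENIA_CATEGORIES
        ):
            continue
        signs = set()
        zero = False
        for category in SARCOPENIA_CATEGORIES:
            beta = hv.evidence[category].beta
            if beta == 0.0:
                zero = True
                break
            signs.add((1 if beta > 0 else -1) * benefit.get(category, +1))
        if zero:
            logger.info("select: %s excluded; zero beta, direction undefined", hv.variant.rsid)
            continue
        if len(signs) != 1:
            continue
        benefit_sign = signs.pop()
        protective = (
            hv.reference_allele
            if benefit_sign > 0
            else hv.variant.other_allele(hv.reference_allele)
        )
        selected.append(replace(hv, protective_allele=protective))
    logger.info("select: %d pleiotropic variants", len(selected))
    return selected
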