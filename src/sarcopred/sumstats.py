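"""Reading, validation and allele harmonization of GWAS summary statistics.

A summary-statistic record reports a signed per-allele effect (beta, or
log-odds for binary traits) against a stated *effect allele*.  Before
evidence from several GWASes can be compared at one variant, every record
must be expressed against the same reference allele; flipping the effect
allele negates beta and leaves the standard error, p-value and sample size
untouched.  This module provides the record types, a strict TSV reader and
writer, and the sign-flipping alignment primitive the rest of the pipeline
is built on.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_ALLELE_ALPHABET = set("ACGT")

TraitCategory = Literal[
    "lean_mass", "strength", "walking_pace", "adiposity", "t2d", "auxiliary"
]

#: trait categories whose higher values protect against sarcopenia (+1)
#: versus categories where the higher value is the risk direction (-1)
CATEGORY_BENEFIT = {
    "lean_mass": +1,
    "strength": +1,
    "walking_pace": +1,
    "adiposity": -1,
    "t2d": -1,
}

SARCOPENIA_CATEGORIES = ("strength", "lean_mass", "walking_pace")


class AlignmentError(ValueError):
    """Raised when a record cannot be expressed against a requested allele."""


def _validate_allele(allele: str) -> None:
    if not allele or not set(allele) <= _ALLELE_ALPHABET:
        raise ValueError(f"invalid allele string {allele!r}")


@dataclass(frozen=True)
class VariantKey:
    """A genetic variant identified by rsid and its unordered allele pair.

    Chromosome and position are carried when known (VCF convention: 1-based,
    reference/alternate strings for indels) but are not part of variant
    identity, so rsid-plus-alleles tables can drive the pipeline without
    coordinates.  Multi-base allele strings (indels) are allowed.
    """

    rsid: str
    allele_a: str
    allele_b: str
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        _validate_allele(self.allele_a)
        _validate_allele(self.allele_b)
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.rsid}: alleles must differ")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.allele_a, self.allele_b))

    @property
    def key(self) -> tuple[str, frozenset[str]]:
        """Identity key: rsid + unordered allele pair."""
        return (self.rsid, self.alleles)

    def other_allele(self, allele: str) -> str:
        if allele == self.allele_a:
            return self.allele_b
        if allele == self.allele_b:
            return self.allele_a
        raise AlignmentError(f"{self.rsid}: allele {allele} not in {{{self.allele_a},{self.allele_b}}}")

    def is_palindromic(self) -> bool:
        """True for strand-ambiguous SNPs (A/T or C/G)."""
        return self.alleles in (frozenset("AT"), frozenset("CG"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantKey):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)


@dataclass(frozen=True)
class TraitSpec:
    """One source GWAS: trait name, category and selection thresholds.

    ``benefit_direction`` is the sign of effect that is protective against
    sarcopenia for this trait (+1 for strength/lean-mass/walking-pace-like
    traits where more is better, -1 for adiposity and type 2 diabetes where
    the higher value is the risk direction).  ``discovery_threshold`` is set
    only for the GWASes that seed the initial genome-wide-significant list;
    ``replication_threshold`` is the less stringent cross-trait matching
    threshold.
    """

    name: str
    category: TraitCategory
    benefit_direction: int
    discovery_threshold: float | None = None
    replication_threshold: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.benefit_direction not in (+1, -1):
            raise ValueError("benefit_direction must be +1 or -1")
        for thr in (self.discovery_threshold, self.replication_threshold):
            if thr is not None and not 0.0 < thr < 1.0:
                raise ValueError("thresholds must lie in (0,1)")
        if (
            self.discovery_threshold is not None
            and self.replication_threshold is not None
            and self.replication_threshold < self.discovery_threshold
        ):
            raise ValueError("replication_threshold must be >= discovery_threshold")
        expected = CATEGORY_BENEFIT.get(self.category)
        if expected is not None and self.benefit_direction != expected:
            raise ValueError(
                f"{self.name}: category {self.category} requires "
                f"benefit_direction {expected:+d}"
            )


@dataclass(frozen=True)
class AssociationRecord:
    """One variant x trait summary statistic.

    ``beta`` is signed per copy of ``effect_allele`` (trait units, or
    log-odds for binary traits).  ``p_text`` preserves the p-value exactly
    as printed in the source table, which matters for values near the
    floating-point underflow boundary.
    """

    variant: VariantKey
    trait: str
    effect_allele: str
    beta: float
    se: float
    p: float
    n: int | None = None
    p_text: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"{self.variant.rsid}/{self.trait}: p={self.p} not in (0,1]")
        if not self.se > 0.0:
            raise ValueError(f"{self.variant.rsid}/{self.trait}: se must be > 0")
        if self.effect_allele not in self.variant.alleles:
            raise ValueError(
                f"{self.variant.rsid}/{self.trait}: effect allele "
                f"{self.effect_allele} not in variant alleles"
            )

    @property
    def z(self) -> float:
        return self.beta / self.se


def parse_p(text: str) -> float:
    """Parse a p-value string, clamping underflow to the smallest normal float.

    Extremely significant associations can be printed with exponents beyond
    float range (e.g. 1e-400); ``float()`` rounds those to 0.0, which is not
    a valid probability.  Such values are clamped to the smallest positive
    normal double; subnormal but representable values are kept as parsed.
    """
    value = float(text)
    if value == 0.0 and _looks_like_underflow(text):
        value = sys.float_info.min
    return value


def _looks_like_underflow(text: str) -> bool:
    # a mantissa > 0 with a large negative exponent underflowed; a literal 0 did not
    try:
        mantissa = text.lower().split("e")[0]
        return float(mantissa) != 0.0
    except ValueError:
        return False


def align_to_allele(record: AssociationRecord, reference_allele: str) -> AssociationRecord:
    """Express ``record`` against ``reference_allele``, flipping beta if needed.

    Aligning to the record's current effect allele is the identity; aligning
    to the other allele of the pair negates beta and leaves se, p and n
    unchanged.  Aligning twice (to the opposite allele and back) is an exact
    involution.
    """
    if reference_allele == record.effect_allele:
        return record
    if reference_allele not in record.variant.alleles:
        raise AlignmentError(
            f"{record.variant.rsid}: cannot align to {reference_allele}; "
            f"alleles are {{{record.variant.allele_a},{record.variant.allele_b}}}"
        )
    return replace(record, effect_allele=reference_allele, beta=-record.beta)


DEFAULT_COLUMNS = ("rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p", "n")


@dataclass
class SumstatsRead:
    """Result of reading a summary-statistics table: valid records plus an audit."""

    records: list[AssociationRecord]
    n_rejected: int = 0
    rejections: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_sumstats(
    path,
    trait: str,
    column_map: Mapping[str, str] | None = None,
) -> SumstatsRead:
    """Read a TSV of per-variant summary statistics for one trait.

    ``column_map`` maps canonical field names (``rsid``, ``chrom``, ``pos``,
    ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``p``, ``n``) to
    the file's column names, for foreign dialects; unmapped canonical names
    are looked up literally.  Rows violating record invariants (p outside
    (0,1], non-positive se, malformed alleles or numbers) are rejected and
    counted, never aborting the read.  Missing file or missing mapped
    columns raise immediately.
    """
    column_map = dict(column_map or {})
    frame = pd.read_csv(path, sep="\t", dtype=str)

    def col(name: str) -> str:
        return column_map.get(name, name)

    required = ["rsid", "effect_allele", "other_allele", "beta", "se", "p"]
    missing = [col(c) for c in required if col(c) not in frame.columns]
    if missing:
        raise KeyError(f"{path}: missing mapped column(s) {missing}")
    has_chrom = col("chrom") in frame.columns
    has_pos = col("pos") in frame.columns
    has_n = col("n") in frame.columns

    def cell(row: dict, name: str):
        value = row.get(col(name))
        if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
            return None
        return value

    result = SumstatsRead(records=[])
    palindromic: list[str] = []
    for i, row in enumerate(frame.to_dict("records")):
        try:
            rsid = str(cell(row, "rsid"))
            ea = str(cell(row, "effect_allele")).upper()
            oa = str(cell(row, "other_allele")).upper()
            chrom = str(cell(row, "chrom")) if has_chrom and cell(row, "chrom") is not None else None
            pos = int(float(cell(row, "pos"))) if has_pos and cell(row, "pos") is not None else None
            n = int(float(cell(row, "n"))) if has_n and cell(row, "n") is not None else None
            p_text = str(cell(row, "p"))
            variant = VariantKey(rsid=rsid, allele_a=ea, allele_b=oa, chrom=chrom, pos=pos)
            record = AssociationRecord(
                variant=variant,
                trait=trait,
                effect_allele=ea,
                beta=float(cell(row, "beta")),
                se=float(cell(row, "se")),
                p=parse_p(p_text),
                n=n,
                p_text=p_text,
            )
        except (ValueError, TypeError, AlignmentError) as exc:
            result.n_rejected += 1
            result.rejections.append(f"row {i}: {exc}")
            continue
        if record.variant.is_palindromic():
            palindromic.append(record.variant.rsid)
        result.records.append(record)

    if palindromic:
        logger.warning(
            "%s: %d strand-ambiguous (A/T or C/G) variants matched by rsid+alleles "
            "without strand flipping: %s%s",
            path, len(palindromic), ",".join(palindromic[:10]),
            "..." if len(palindromic) > 10 else "",
        )
    logger.info("%s: read %d records, rejected %d rows", path, len(result.records), result.n_rejected)
    return result


def write_sumstats(records: Iterable[AssociationRecord], path) -> str:
    """Write records as a TSV with the canonical header; round-trips losslessly."""
    rows = []
    for r in records:
        rows.append(
            {
                "rsid": r.variant.rsid,
                "chrom": r.variant.chrom if r.variant.chrom is not None else "",
                "pos": r.variant.pos if r.variant.pos is not None else "",
                "effect_allele": r.effect_allele,
                "other_allele": r.variant.other_allele(r.effect_allele),
                "beta": repr(r.beta),
                "se": repr(r.se),
                "p": r.p_text if r.p_text is not None else repr(r.p),
                "n": r.n if r.n is not None else "",
            }
        )
    frame = pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)
    return str(path)


def load_trait_specs(source) -> list[TraitSpec]:
    """Load trait specifications from a YAML file path, stream or parsed list.

    Expected YAML: a list of mappings with keys name, category,
    benefit_direction, discovery_threshold, replication_threshold, n.
    """
    if isinstance(source, (list, tuple)):
        items = source
    else:
        if hasattr(source, "read"):
            items = yaml.safe_load(source)
        else:
            with open(source) as fh:
                items = yaml.safe_load(fh)
    specs = []
    for item in items:
        if isinstance(item, TraitSpec):
            specs.append(item)
        else:
            specs.append(TraitSpec(**item))
    return specs


def default_trait_specs() -> list[TraitSpec]:
    """The UK-Biobank-style study design: five discovery GWASes on
    handgrip strength, appendicular lean mass and walking pace, the
    cross-trait matching GWASes at p < 0.005, and the body-fat and
    type-2-diabetes GWASes used for the obesity/diabesity tiers.
    Sample sizes are the published per-GWAS participant counts.
    """
    return [
        TraitSpec("appendicular_lean_mass", "lean_mass", +1, 5e-9, 0.005, 450_243),
        TraitSpec("appendicular_lean_mass_older_adults", "lean_mass", +1, None, 5e-8, 181_862),
        TraitSpec("maximal_handgrip_strength", "strength", +1, 5e-8, 0.005, 195_180),
        TraitSpec("relative_handgrip_strength", "strength", +1, 5e-8, 0.005, 334_925),
        TraitSpec("handgrip_strength_older_adults", "strength", +1, 5e-8, 0.005, 256_523),
        TraitSpec("handgrip_strength_left", "strength", +1, None, 0.005, 359_704),
        TraitSpec("handgrip_strength_right", "strength", +1, None, 0.005, 359_729),
        TraitSpec("self_reported_walking_pace", "walking_pace", +1, 5e-8, 0.005, 450_967),
        TraitSpec("usual_walking_pace", "walking_pace", +1, None, 0.005, 358_974),
        TraitSpec("body_fat_percentage", "adiposity", -1, None, 0.005, 354_628),
        TraitSpec("type_2_diabetes", "t2d", -1, None, 0.005, 408_959),
    ]
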