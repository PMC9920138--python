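"""Packaged lookup tables: the pleiotropic-variant panel and gene evidence.

Three small TSVs ship with the package:

* ``table2.tsv`` — the 78-variant pleiotropic panel (gene label, rsid,
  protective/risk alleles, and p-values against handgrip strength,
  appendicular lean mass, usual walking pace, body fat percentage and type
  2 diabetes, with NS marking p > 0.005).
* ``mouse_knockouts.tsv`` — mouse knockout directions on lean mass and
  strength per gene plus the human eQTL direction of the protective allele.
  The tested-but-not-significant rows are synthetic placeholders (their
  identities are not published); see the file header.
* ``exercise_response.tsv`` — genes up/downregulated in skeletal muscle
  after a single bout of resistance exercise.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .concordance import GeneEvidence
from .sumstats import VariantKey, parse_p


class _NotSignificant:
    """Sentinel for a p-value slot printed as NS (p > 0.005); distinct from missing."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NS"

    def __reduce__(self):
        return (_NotSignificant, ())


#: the NS marker used throughout the package
NS = _NotSignificant()

#: ordered p-value slots of the pleiotropic-variant table
P_SLOTS = ("grip", "lean", "walk", "fat", "t2d")


@dataclass(frozen=True)
class PanelRow:
    """One row of the pleiotropic-variant panel table."""

    gene: str
    variant: VariantKey
    protective_allele: str
    risk_allele: str
    p: dict  # slot -> float or NS
    p_text: dict  # slot -> printed string

    def p_value(self, slot: str):
        return self.p[slot]


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("sarcopred.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype=str)


def table2_fixture() -> list[PanelRow]:
    """The packaged 78-variant pleiotropic panel, at printed precision.

    Each row carries the gene label, the variant (rsid + protective/risk
    allele pair), and five p-value slots (handgrip strength, appendicular
    lean mass, usual walking pace, body fat percentage, type 2 diabetes);
    a slot is either a parsed float or the :data:`NS` marker.
    """
    frame = _read_packaged_tsv("table2.tsv")
    rows = []
    for rec in frame.to_dict("records"):
        variant = VariantKey(
            rsid=rec["rsid"],
            allele_a=rec["protective_allele"],
            allele_b=rec["risk_allele"],
        )
        p, p_text = {}, {}
        for slot in P_SLOTS:
            text = rec[f"p_{slot}"]
            p_text[slot] = text
            p[slot] = NS if text == "NS" else parse_p(text)
        rows.append(
            PanelRow(
                gene=rec["gene"],
                variant=variant,
                protective_allele=rec["protective_allele"],
                risk_allele=rec["risk_allele"],
                p=p,
                p_text=p_text,
            )
        )
    return rows


def _parse_direction(text: str) -> int | None:
    if text in (".", "", None):
        return None
    return int(text)


def gene_evidence_fixture() -> list[GeneEvidence]:
    """Gene-level evidence for every distinct gene of the variant panel.

    Combines the mouse-knockout/eQTL table and the exercise-response table
    into one :class:`~sarcopred.concordance.GeneEvidence` per gene; genes
    absent from a lookup get unknown values for the corresponding fields.
    """
    genes = sorted({row.gene for row in table2_fixture()})
    ko = {
        rec["gene"]: rec
        for rec in _read_packaged_tsv("mouse_knockouts.tsv").to_dict("records")
    }
    exercise = {
        rec["gene"]: rec["exercise_response"]
        for rec in _read_packaged_tsv("exercise_response.tsv").to_dict("records")
    }
    evidence = []
    for gene in genes:
        rec = ko.get(gene)
        evidence.append(
            GeneEvidence(
                gene=gene,
                expression_direction=_parse_direction(rec["expression_direction"]) if rec else None,
                knockout_direction=_parse_direction(rec["knockout_direction"]) if rec else None,
                knockout_tested=bool(rec) and rec["knockout_tested"] == "yes",
                exercise_response=exercise.get(gene, "unknown"),
            )
        )
    return evidence
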