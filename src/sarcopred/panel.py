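"""Genotype reference panel: samples x variants dosage matrix backed by VCF.

The panel plays the role of a population reference (e.g. a few hundred
European-ancestry individuals) for two downstream jobs: estimating pairwise
linkage disequilibrium between candidate variants, and counting risk alleles
per individual for the unweighted polygenic score.  Dosages count copies of
a designated *counted allele* per variant (0/1/2, -1 for missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sumstats import VariantKey

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix with a designated counted allele.

    ``dosages[i, j]`` is the number of copies of ``counted_alleles[j]``
    carried by ``sample_ids[i]`` at ``variants[j]`` (0, 1 or 2), or -1 for
    a missing genotype.
    """

    sample_ids: list[str]
    variants: list[VariantKey]
    dosages: np.ndarray
    counted_alleles: list[str]
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValueError("dosage matrix shape does not match sample/variant counts")
        if len(self.counted_alleles) != m:
            raise ValueError("one counted allele required per variant")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")
        for v, a in zip(self.variants, self.counted_alleles):
            if a not in v.alleles:
                raise ValueError(f"{v.rsid}: counted allele {a} not in allele pair")
        self._index = {v.key: j for j, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, variant: VariantKey) -> bool:
        return variant.key in self._index

    def index_of(self, variant: VariantKey) -> int:
        try:
            return self._index[variant.key]
        except KeyError:
            raise KeyError(f"variant {variant.rsid} not in panel") from None

    def dosage_of_allele(self, variant: VariantKey, allele: str) -> np.ndarray:
        """Dosage vector counting ``allele`` (flipping 2-d if it is the other allele)."""
        j = self.index_of(variant)
        d = self.dosages[:, j]
        if allele == self.counted_alleles[j]:
            return d.copy()
        if allele != variant.other_allele(self.counted_alleles[j]):
            raise KeyError(f"{variant.rsid}: allele {allele} not in allele pair")
        flipped = 2 - d
        flipped[d == MISSING] = MISSING
        return flipped

    def allele_freq(self) -> np.ndarray:
        """Per-variant frequency of the counted allele over non-missing genotypes."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        return (d.sum(axis=0) / (2.0 * d.count(axis=0))).filled(np.nan)

    def missingness(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    # ------------------------------------------------------------------ I/O

    def to_vcf(self, path) -> str:
        """Write as a minimal VCF 4.2 (GT-only, './.' for missing).

        The counted allele is written as ALT; variants without coordinates
        get placeholder chrom '0' / pos 1-based running index so the file
        stays valid.
        """
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.sample_ids) + "\n")
            gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for j, v in enumerate(self.variants):
                alt = self.counted_alleles[j]
                ref = v.other_allele(alt)
                chrom = v.chrom if v.chrom is not None else "0"
                pos = v.pos if v.pos is not None else j + 1
                gts = "\t".join(gt_map[int(d)] for d in self.dosages[:, j])
                fh.write(f"{chrom}\t{pos}\t{v.rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
        return str(path)

    @classmethod
    def from_vcf(cls, path) -> "GenotypePanel":
        """Read a bi-allelic VCF, counting the ALT allele; multi-allelic sites
        and half-calls are rejected."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        sample_ids = list(vcf.samples)
        variants: list[VariantKey] = []
        counted: list[str] = []
        columns: list[np.ndarray] = []
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise ValueError(f"{rec.ID}: only bi-allelic sites are supported")
            alt = rec.ALT[0]
            variants.append(
                VariantKey(
                    rsid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                    allele_a=rec.REF,
                    allele_b=alt,
                    chrom=str(rec.CHROM),
                    pos=int(rec.POS),
                )
            )
            counted.append(alt)
            col = np.full(len(sample_ids), MISSING, dtype=np.int16)
            for i, g in enumerate(rec.genotypes):
                a = [x for x in g[:-1]]
                if any(x < 0 for x in a):
                    continue
                col[i] = sum(1 for x in a if x == 1)
            columns.append(col)
        vcf.close()
        dosages = (
            np.stack(columns, axis=1)
            if columns
            else np.empty((len(sample_ids), 0), dtype=np.int16)
        )
        return cls(sample_ids, variants, dosages, counted)

    def to_dosage_tsv(self, path) -> str:
        """Write as a TSV: one row per variant, one column per sample."""
        with open(path, "w") as fh:
            fh.write("rsid\tchrom\tpos\tother_allele\tcounted_allele\t")
            fh.write("\t".join(self.sample_ids) + "\n")
            for j, v in enumerate(self.variants):
                alt = self.counted_alleles[j]
                ref = v.other_allele(alt)
                chrom = v.chrom if v.chrom is not None else ""
                pos = v.pos if v.pos is not None else ""
                row = "\t".join("." if d == MISSING else str(int(d)) for d in self.dosages[:, j])
                fh.write(f"{v.rsid}\t{chrom}\t{pos}\t{ref}\t{alt}\t{row}\n")
        return str(path)

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypePanel":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            sample_ids = header[5:]
            variants, counted, columns = [], [], []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                rsid, chrom, pos, ref, alt = fields[:5]
                variants.append(
                    VariantKey(
                        rsid=rsid,
                        allele_a=ref,
                        allele_b=alt,
                        chrom=chrom or None,
                        pos=int(pos) if pos else None,
                    )
                )
                counted.append(alt)
                columns.append(
                    np.array(
                        [MISSING if x == "." else int(x) for x in fields[5:]],
                        dtype=np.int16,
                    )
                )
        dosages = (
            np.stack(columns, axis=1)
            if columns
            else np.empty((len(sample_ids), 0), dtype=np.int16)
        )
        return cls(sample_ids, variants, dosages, counted)
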