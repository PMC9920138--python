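"""Synthetic genotype panels and multi-trait GWAS summary statistics.

The generator produces the statistical structure the selection pipeline
assumes, with known ground truth:

* a genotype panel with block-diagonal LD — within each block of variants,
  haplotypes are drawn from a latent multivariate normal with exchangeable
  correlation ``ld_rho`` and thresholded at each variant's allele-frequency
  quantile, so allele frequencies and within-block LD are controlled;
* per-trait summary statistics under the standard Wald approximation: for a
  standardized phenotype, the per-allele standard error at allele frequency
  f and GWAS sample size n is 1/sqrt(2 n f (1-f)); the observed beta is the
  true effect plus N(0, se^2) noise and the p-value is the two-sided normal
  tail of beta/se;
* planted causal structure: direction-consistent pleiotropic variants
  loaded on every strength/lean-mass/walking-pace trait (and on body fat
  and type 2 diabetes for configured subsets), single-trait variants, and
  nulls everywhere else.

Default parameters mirror the study design the pipeline targets: a
503-individual European-style reference panel and UK-Biobank-scale GWAS
sample sizes (hundreds of thousands) per trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
import yaml
from scipy import stats

from .panel import GenotypePanel
from .sumstats import (
    SARCOPENIA_CATEGORIES,
    AssociationRecord,
    TraitSpec,
    VariantKey,
    default_trait_specs,
)

logger = logging.getLogger(__name__)

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the emulated study conditions: a 503-sample reference
    panel; 2000 variants in LD blocks of 10 with moderate within-block
    latent correlation; 20 planted pleiotropic variants of standardized
    effect 0.04 (14 of them also loaded on body fat, 5 of those on T2D,
    echoing the observed 55/78 and 21/78 tier proportions); 30 single-trait
    variants; UK-Biobank-scale GWAS sample sizes taken from each trait
    spec, falling back to ``gwas_n``.
    """

    n_samples: int = 503
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.3
    n_causal_pleiotropic: int = 20
    n_causal_single_trait: int = 30
    n_fat_loaded: int | None = None
    n_t2d_loaded: int | None = None
    effect_size: float = 0.04
    gwas_n: int = 450_000
    missing_rate: float = 0.0
    missing_cap: float = 0.1
    trait_specs: tuple[TraitSpec, ...] = field(
        default_factory=lambda: tuple(default_trait_specs())
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants <= 0 or self.n_samples <= 0:
            raise ValueError("n_samples and n_variants must be positive")
        if self.n_causal_pleiotropic + self.n_causal_single_trait > self.n_variants:
            raise ValueError("more causal variants than variants")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0,1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        # subsets default to the observed tier proportions (55/78 and 21/78)
        if self.n_fat_loaded is None:
            object.__setattr__(
                self, "n_fat_loaded", round(self.n_causal_pleiotropic * 55 / 78)
            )
        if self.n_t2d_loaded is None:
            object.__setattr__(
                self, "n_t2d_loaded", round(self.n_causal_pleiotropic * 21 / 78)
            )
        if not self.n_t2d_loaded <= self.n_fat_loaded <= self.n_causal_pleiotropic:
            raise ValueError("loaded subsets must nest: t2d <= fat <= pleiotropic")
        if not 0.0 <= self.missing_rate <= self.missing_cap <= 1.0:
            raise ValueError("missing_rate must not exceed missing_cap")

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        data = yaml.safe_load(source.read() if hasattr(source, "read") else open(source).read())
        if "trait_specs" in data:
            data["trait_specs"] = tuple(TraitSpec(**t) for t in data["trait_specs"])
        if "maf_range" in data:
            data["maf_range"] = tuple(data["maf_range"])
        return cls(**data)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted effects, keyed by rsid.

    ``pleiotropic`` maps rsid -> +1 if the panel's counted allele is the
    protective allele, -1 if it is the risk allele.  ``fat_loaded`` and
    ``t2d_loaded`` are the pleiotropic subsets additionally loaded on body
    fat / T2D.  ``single_trait`` maps rsid -> (category, sign).
    """

    pleiotropic: Mapping[str, int]
    fat_loaded: frozenset[str]
    t2d_loaded: frozenset[str]
    single_trait: Mapping[str, tuple[str, int]]

    def true_beta(self, rsid: str, spec: TraitSpec, effect_size: float) -> float:
        """True standardized per-allele effect of the counted allele on a trait."""
        if rsid in self.pleiotropic:
            sign = self.pleiotropic[rsid]
            if spec.category in SARCOPENIA_CATEGORIES:
                return sign * spec.benefit_direction * effect_size
            if spec.category == "adiposity" and rsid in self.fat_loaded:
                return sign * spec.benefit_direction * effect_size
            if spec.category == "t2d" and rsid in self.t2d_loaded:
                return sign * spec.benefit_direction * effect_size
            if spec.category == "auxiliary":
                return 0.0
            return 0.0
        if rsid in self.single_trait:
            category, sign = self.single_trait[rsid]
            if spec.category == category:
                return sign * spec.benefit_direction * effect_size
        return 0.0


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_panel(config: SimulationConfig) -> GenotypePanel:
    """Draw a genotype panel with block-exchangeable latent LD.

    Within each block of ``ld_block_size`` variants, each haplotype is a
    latent Gaussian vector with pairwise correlation ``ld_rho``; an allele
    indicator is the latent value falling below the variant's allele-
    frequency quantile, and the two haplotypes sum to the dosage of the
    counted allele.  Deterministic under a fixed seed.
    """
    rng = _rng(config, 1)
    n, m = config.n_samples, config.n_variants
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    thresholds = stats.norm.ppf(freqs)

    sqrt_rho = np.sqrt(config.ld_rho)
    sqrt_comp = np.sqrt(1.0 - config.ld_rho)
    dosages = np.empty((n, m), dtype=np.int16)
    for start in range(0, m, config.ld_block_size):
        width = min(config.ld_block_size, m - start)
        # two haplotypes per individual, exchangeable correlation within block
        shared = rng.standard_normal(size=(n, 2, 1))
        indiv = rng.standard_normal(size=(n, 2, width))
        latent = sqrt_rho * shared + sqrt_comp * indiv
        indicators = latent < thresholds[start : start + width]
        dosages[:, start : start + width] = indicators.sum(axis=1)

    if config.missing_rate > 0:
        mask = rng.random(size=dosages.shape) < config.missing_rate
        dosages[mask] = -1

    variants = []
    counted = []
    for j in range(m):
        ref, alt = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        variants.append(
            VariantKey(
                rsid=f"rs{1_000_000 + j}",
                allele_a=ref,
                allele_b=alt,
                chrom=str(j // config.ld_block_size % 22 + 1),
                pos=(j % config.ld_block_size + 1) * 10_000
                + (j // config.ld_block_size) * 1_000_000,
            )
        )
        counted.append(alt)
    sample_ids = [f"IND{i:05d}" for i in range(n)]
    panel = GenotypePanel(sample_ids, variants, dosages, counted)

    miss = panel.missingness()
    if (miss > config.missing_cap).any():
        logger.warning(
            "panel: %d variants exceed the missingness cap %.3f",
            int((miss > config.missing_cap).sum()), config.missing_cap,
        )
    return panel


def plant_truth(panel: GenotypePanel, config: SimulationConfig) -> PlantedTruth:
    """Deterministically choose the planted causal variants and their signs.

    Uses its own seed stream, so callers can recover the ground truth that
    :func:`simulate_sumstats` used without re-simulating.
    """
    rng = _rng(config, 2)
    rsids = [v.rsid for v in panel.variants]
    n_causal = config.n_causal_pleiotropic + config.n_causal_single_trait
    chosen = rng.choice(len(rsids), size=n_causal, replace=False)
    pleio_idx = chosen[: config.n_causal_pleiotropic]
    single_idx = chosen[config.n_causal_pleiotropic :]

    signs = rng.choice([1, -1], size=len(pleio_idx))
    pleiotropic = {rsids[j]: int(s) for j, s in zip(pleio_idx, signs)}
    pleio_rsids = [rsids[j] for j in pleio_idx]
    fat_loaded = frozenset(pleio_rsids[: config.n_fat_loaded])
    t2d_loaded = frozenset(pleio_rsids[: config.n_t2d_loaded])

    single = {}
    for k, j in enumerate(single_idx):
        category = SARCOPENIA_CATEGORIES[k % len(SARCOPENIA_CATEGORIES)]
        single[rsids[j]] = (category, int(rng.choice([1, -1])))
    return PlantedTruth(
        pleiotropic=pleiotropic,
        fat_loaded=fat_loaded,
        t2d_loaded=t2d_loaded,
        single_trait=single,
    )


def _p_from_z(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    # underflow guard: a p-value of exactly 0 is not a probability
    return np.maximum(p, np.finfo(float).tiny)


def simulate_sumstats(
    panel: GenotypePanel,
    config: SimulationConfig,
    truth: PlantedTruth | None = None,
) -> dict[str, list[AssociationRecord]]:
    """Simulate one summary-statistics table per configured trait.

    Effects are expressed against each variant's counted allele.  Monomorphic
    variants (panel allele frequency 0 or 1) cannot be tested and are
    skipped with a warning.  Binary-trait (T2D) effects are generated on the
    same standardized scale and labeled log-odds downstream; the pipeline
    consumes only signs and p-values.
    """
    if truth is None:
        truth = plant_truth(panel, config)
    rng = _rng(config, 3)
    freqs = panel.allele_freq()
    poly = (freqs > 0.0) & (freqs < 1.0) & ~np.isnan(freqs)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.warning("sumstats: skipped %d monomorphic variants", n_mono)

    out: dict[str, list[AssociationRecord]] = {}
    for spec in config.trait_specs:
        n = spec.n if spec.n is not None else config.gwas_n
        se = np.full(panel.n_variants, np.nan)
        se[poly] = 1.0 / np.sqrt(2.0 * n * freqs[poly] * (1.0 - freqs[poly]))
        true_beta = np.array(
            [truth.true_beta(v.rsid, spec, config.effect_size) for v in panel.variants]
        )
        beta_hat = true_beta + rng.standard_normal(panel.n_variants) * se
        p = np.full(panel.n_variants, np.nan)
        p[poly] = _p_from_z(beta_hat[poly] / se[poly])

        records = []
        for j, variant in enumerate(panel.variants):
            if not poly[j]:
                continue
            records.append(
                AssociationRecord(
                    variant=variant,
                    trait=spec.name,
                    effect_allele=panel.counted_alleles[j],
                    beta=float(beta_hat[j]),
                    se=float(se[j]),
                    p=float(p[j]),
                    n=n,
                )
            )
        out[spec.name] = records
    return out


def simulate_study(
    config: SimulationConfig,
) -> tuple[GenotypePanel, dict[str, list[AssociationRecord]], PlantedTruth]:
    """Convenience wrapper: panel, per-trait summary statistics and truth."""
    panel = simulate_panel(config)
    truth = plant_truth(panel, config)
    sumstats = simulate_sumstats(panel, config, truth)
    return panel, sumstats, truth
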