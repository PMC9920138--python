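"""End-to-end pipeline: simulate/load inputs, select, prune, classify, score.

The stage order mirrors the study design: build the discovery list from the
source GWASes, harmonize and select direction-consistent pleiotropic
variants, prune to LD-independent signals against the reference panel,
tier-classify, compute unweighted risk scores and risk bands per tier, and
summarize gene-evidence concordance.  Every run writes a manifest (config
echo, package/library versions, seed, per-stage row counts) sufficient to
reproduce it byte-for-byte from the same inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .concordance import concordance_summary
from .fixtures import NS, gene_evidence_fixture, table2_fixture
from .ld import greedy_prune, rank_by_min_p
from .panel import GenotypePanel
from .prs import risk_score, stratify
from .select import build_discovery_list, harmonize, select_pleiotropic
from .simulate import SimulationConfig, simulate_study
from .sumstats import TraitSpec, default_trait_specs, read_sumstats
from .tiers import call_from_selection, calls_from_table2, tier_counts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    In ``simulate`` mode the inputs are generated from ``simulation``;
    otherwise per-trait summary TSVs (``sumstats_paths``) and a panel
    (``panel_path``, VCF or dosage TSV) are read.  ``fixture_mode`` runs
    the packaged variant panel and gene-evidence tables through the
    classification and concordance stages without any GWAS inputs.
    """

    trait_specs: list[TraitSpec] = field(default_factory=default_trait_specs)
    sumstats_paths: dict[str, str] = field(default_factory=dict)
    panel_path: str | None = None
    fixture_mode: bool = False
    simulate: bool = True
    simulation: SimulationConfig | None = None
    replication_threshold: float = 0.005
    ld_r2: float = 0.2
    n_bands: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for thr in (self.replication_threshold, self.ld_r2):
            if not 0.0 < thr <= 1.0:
                raise ValueError("thresholds must lie in (0,1]")
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if obj is NS:
        return "NS"
    return obj


def _write_calls_tsv(calls, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\trsid\tprotective_allele\trisk_allele\t"
            "p_strength\tp_lean\tp_walk\tp_fat\tp_t2d\ttier\n"
        )
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.gene_label or "",
                        c.variant.rsid,
                        c.protective_allele,
                        c.risk_allele,
                        repr(c.p_strength),
                        repr(c.p_lean),
                        repr(c.p_walk),
                        "NS" if c.p_fat is NS else repr(c.p_fat),
                        "NS" if c.p_t2d is NS else repr(c.p_t2d),
                        c.tier,
                    ]
                )
                + "\n"
            )


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages, writing stage outputs and a manifest under out_dir.

    Returns the manifest dict.  Any stage error is recorded in the manifest
    (which is always written) and re-raised with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "sarcopred",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "stages": {},
        "status": "running",
    }
    stage = "setup"
    try:
        results: dict = {}

        stage = "concordance"
        evidence = gene_evidence_fixture()
        results["concordance"] = concordance_summary(evidence)
        manifest["stages"][stage] = {"genes": len(evidence)}

        if config.fixture_mode:
            stage = "classify_fixture"
            calls = calls_from_table2(table2_fixture())
            _write_calls_tsv(calls, out / "classified_calls.tsv")
            results["tier_counts"] = tier_counts(calls)
            manifest["stages"][stage] = {"calls": len(calls)}
        else:
            stage = "inputs"
            if config.simulate:
                sim = config.simulation or SimulationConfig(seed=config.seed)
                panel, sumstats, _truth = simulate_study(sim)
            else:
                panel = (
                    GenotypePanel.from_vcf(config.panel_path)
                    if str(config.panel_path).endswith(".vcf")
                    else GenotypePanel.from_dosage_tsv(config.panel_path)
                )
                sumstats = {
                    trait: read_sumstats(path, trait=trait).records
                    for trait, path in config.sumstats_paths.items()
                }
            manifest["stages"][stage] = {
                "panel_samples": panel.n_samples,
                "panel_variants": panel.n_variants,
                "traits": {t: len(r) for t, r in sumstats.items()},
            }

            stage = "discovery"
            discovery = build_discovery_list(sumstats, config.trait_specs)
            manifest["stages"][stage] = {"variants": len(discovery)}

            stage = "select"
            harmonized = harmonize(sumstats, config.trait_specs, variants=discovery)
            selected = select_pleiotropic(
                discovery, harmonized, config.trait_specs, config.replication_threshold
            )
            manifest["stages"][stage] = {"selected": len(selected)}

            stage = "prune"
            pruned = greedy_prune(rank_by_min_p(selected), panel, config.ld_r2)
            manifest["stages"][stage] = {
                "retained": len(pruned),
                "pruned": len(selected) - len(pruned),
            }

            stage = "classify"
            calls = [call_from_selection(hv) for hv in pruned]
            _write_calls_tsv(calls, out / "classified_calls.tsv")
            results["tier_counts"] = tier_counts(calls)
            manifest["stages"][stage] = {"calls": len(calls)}

            stage = "prs"
            tiers = {
                "sarcopenia": calls,
                "sarcopenic_obesity": [c for c in calls if c.p_fat is not NS],
                "sarcopenic_diabesity": [
                    c for c in calls if c.p_fat is not NS and c.p_t2d is not NS
                ],
            }
            results["risk_bands"] = {}
            for label, tier_calls in tiers.items():
                scored = {
                    c.variant: c.risk_allele
                    for c in tier_calls
                    if c.variant in panel
                }
                if len(scored) == 0:
                    continue
                scores = risk_score(panel, scored)
                table = stratify(scores, n_bands=config.n_bands, trait_label=label)
                results["risk_bands"][label] = _jsonable(table)
            manifest["stages"][stage] = {
                t: len(c) for t, c in tiers.items()
            }

        with open(out / "summary.json", "w") as fh:
            json.dump(_jsonable(results), fh, indent=2)
        manifest["status"] = "ok"
        return manifest
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        logger.error("pipeline failed at stage %s:\n%s", stage, traceback.format_exc())
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2)
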