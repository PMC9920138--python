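"""Two-stage pleiotropy selection: discovery union, category collapse,
replication + direction-consistency filtering."""

import numpy as np
import pytest

from sarcopred import (
    AssociationRecord,
    TraitSpec,
    VariantKey,
    build_discovery_list,
    collapse_category,
    harmonize,
    select_pleiotropic,
)
from sarcopred.select import CategoryMissingError

SPECS = [
    TraitSpec("grip_a", "strength", +1, 5e-8, 0.005),
    TraitSpec("grip_b", "strength", +1, None, 0.005),
    TraitSpec("lean", "lean_mass", +1, 5e-9, 0.005),
    TraitSpec("walk", "walking_pace", +1, 5e-8, 0.005),
    TraitSpec("fat", "adiposity", -1, None, 0.005),
]


def _rec(rsid, trait, beta, p, ea="A", alleles=("A", "G")):
    return AssociationRecord(
        VariantKey(rsid, *alleles), trait, ea, beta, 0.01, p
    )


class TestDiscovery:
    def test_union_counts_shared_variants_once(self):
        shared = _rec("rs1", "grip_a", 0.1, 1e-10)
        per_trait = {
            "grip_a": [shared, _rec("rs2", "grip_a", 0.1, 1e-9)],
            "walk": [_rec("rs1", "walk", 0.1, 1e-12), _rec("rs3", "walk", 0.1, 1e-9)],
        }
        assert len(build_discovery_list(per_trait, SPECS)) == 3

    def test_subthreshold_records_excluded(self):
        per_trait = {"grip_a": [_rec("rs1", "grip_a", 0.1, 1e-7)]}
        assert build_discovery_list(per_trait, SPECS) == []

    def test_per_trait_thresholds_apply(self):
        # 1e-8 passes the grip threshold (5e-8) but not the lean one (5e-9)
        per_trait = {
            "grip_a": [_rec("rs1", "grip_a", 0.1, 1e-8)],
            "lean": [_rec("rs2", "lean", 0.1, 1e-8)],
        }
        found = {v.rsid for v in build_discovery_list(per_trait, SPECS)}
        assert found == {"rs1"}

    def test_non_discovery_traits_do_not_contribute(self):
        per_trait = {"grip_b": [_rec("rs1", "grip_b", 0.1, 1e-20)]}
        assert build_discovery_list(per_trait, SPECS) == []


class TestCollapse:
    def test_single_record_is_identity(self):
        r = _rec("rs1", "grip_a", 0.2, 0.01)
        ev = collapse_category([r], "A")
        assert (ev.trait, ev.beta, ev.p) == ("grip_a", 0.2, 0.01)

    def test_min_p_wins_and_is_aligned(self):
        left = _rec("rs1", "grip_a", 0.2, 0.01, ea="A")
        right = _rec("rs1", "grip_b", 0.3, 0.001, ea="A")
        ev = collapse_category([left, right], "G")
        assert ev.trait == "grip_b"
        assert ev.beta == -0.3  # aligned to G

    def test_ties_break_by_trait_name(self):
        a = _rec("rs1", "grip_b", 0.1, 0.01)
        b = _rec("rs1", "grip_a", 0.2, 0.01)
        assert collapse_category([a, b], "A").trait == "grip_a"

    def test_empty_category_signals(self):
        with pytest.raises(CategoryMissingError):
            collapse_category([], "A")

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            records = [
                _rec("rs1", f"grip_{chr(97 + k)}", float(rng.normal()),
                     float(rng.uniform(1e-6, 1)))
                for k in range(5)
            ]
            ev = collapse_category(records, "A")
            best = min(records, key=lambda r: (r.p, r.trait))
            assert (ev.trait, ev.p) == (best.trait, best.p)


def _full_evidence(rsid, betas, p=1e-4, discovery_p=1e-10, fat_beta=None):
    """Records giving one variant evidence in all three sarcopenia
    categories with the given aligned-to-A betas."""
    grip, lean, walk = betas
    records = {
        "grip_a": [_rec(rsid, "grip_a", grip, discovery_p)],
        "lean": [_rec(rsid, "lean", lean, p)],
        "walk": [_rec(rsid, "walk", walk, p)],
    }
    if fat_beta is not None:
        records["fat"] = [_rec(rsid, "fat", fat_beta, p)]
    return records


def _merge(*dicts):
    out = {}
    for d in dicts:
        for trait, records in d.items():
            out.setdefault(trait, []).extend(records)
    return out


class TestSelect:
    def test_consistent_benefit_positive_variant_selected(self):
        per_trait = _full_evidence("rs1", (0.1, 0.1, 0.1))
        discovery = build_discovery_list(per_trait, SPECS)
        harmonized = harmonize(per_trait, SPECS)
        selected = select_pleiotropic(discovery, harmonized, SPECS)
        assert len(selected) == 1
        assert selected[0].protective_allele == "A"
        assert selected[0].risk_allele == "G"

    def test_all_negative_betas_mean_other_allele_protective(self):
        per_trait = _full_evidence("rs1", (-0.1, -0.1, -0.1))
        selected = select_pleiotropic(
            build_discovery_list(per_trait, SPECS), harmonize(per_trait, SPECS), SPECS
        )
        assert selected[0].protective_allele == "G"

    def test_inconsistent_direction_excluded(self):
        per_trait = _full_evidence("rs1", (0.1, 0.1, -0.1))
        selected = select_pleiotropic(
            build_discovery_list(per_trait, SPECS), harmonize(per_trait, SPECS), SPECS
        )
        assert selected == []

    def test_zero_beta_direction_undefined(self):
        per_trait = _full_evidence("rs1", (0.1, 0.0, 0.1))
        selected = select_pleiotropic(
            build_discovery_list(per_trait, SPECS), harmonize(per_trait, SPECS), SPECS
        )
        assert selected == []

    def test_missing_category_excluded(self):
        per_trait = {
            "grip_a": [_rec("rs1", "grip_a", 0.1, 1e-10)],
            "lean": [_rec("rs1", "lean", 0.1, 1e-4)],
        }
        selected = select_pleiotropic(
            build_discovery_list(per_trait, SPECS), harmonize(per_trait, SPECS), SPECS
        )
        assert selected == []

    def test_replication_threshold_is_strict_and_monotone(self):
        per_trait = _merge(
            _full_evidence("rs1", (0.1, 0.1, 0.1), p=0.004),
            _full_evidence("rs2", (0.1, 0.1, 0.1), p=0.04,
                           discovery_p=1e-10),
        )
        discovery = build_discovery_list(per_trait, SPECS)
        harmonized = harmonize(per_trait, SPECS)
        at_005 = {v.variant.rsid for v in
                  select_pleiotropic(discovery, harmonized, SPECS, 0.005)}
        at_05 = {v.variant.rsid for v in
                 select_pleiotropic(discovery, harmonized, SPECS, 0.05)}
        assert at_005 == {"rs1"}
        assert at_05 == {"rs1", "rs2"}
        assert at_005 <= at_05

    def test_allele_reference_invariance(self):
        per_trait = _merge(
            _full_evidence("rs1", (0.1, 0.1, 0.1)),
            _full_evidence("rs2", (-0.2, -0.2, -0.2)),
        )
        discovery = build_discovery_list(per_trait, SPECS)
        harmonized = harmonize(per_trait, SPECS)
        flipped = [hv.flipped() for hv in harmonized]
        a = {(v.variant.rsid, v.protective_allele)
             for v in select_pleiotropic(discovery, harmonized, SPECS)}
        b = {(v.variant.rsid, v.protective_allele)
             for v in select_pleiotropic(discovery, flipped, SPECS)}
        assert a == b

    def test_selected_variants_replicate_in_all_categories(self, default_study):
        config, _, sumstats, _ = default_study
        discovery = build_discovery_list(sumstats, config.trait_specs)
        harmonized = harmonize(sumstats, config.trait_specs, variants=discovery)
        selected = select_pleiotropic(discovery, harmonized, config.trait_specs)
        for hv in selected:
            for category in ("strength", "lean_mass", "walking_pace"):
                assert hv.evidence[category].p < 0.005

    def test_recovers_planted_pleiotropic_set(self, default_study):
        config, _, sumstats, truth = default_study
        discovery = build_discovery_list(sumstats, config.trait_specs)
        harmonized = harmonize(sumstats, config.trait_specs, variants=discovery)
        selected = select_pleiotropic(discovery, harmonized, config.trait_specs)
        got = {hv.variant.rsid for hv in selected}
        planted = set(truth.pleiotropic)
        assert len(got & planted) >= 0.9 * len(planted)
        # no direction-inconsistent admissions, by exhaustive post-check
        benefit = {s.category: s.benefit_direction for s in config.trait_specs}
        for hv in selected:
            signs = {
                (1 if hv.evidence[c].beta > 0 else -1) * benefit[c]
                for c in ("strength", "lean_mass", "walking_pace")
            }
            assert len(signs) == 1
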