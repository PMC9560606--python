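import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import truncnorm

from mosaicstage.core import ConfigError
from mosaicstage.io import truth_to_frame
from mosaicstage.synthetic import (
    CohortConfig,
    TruthRecord,
    draw_vaf,
    expected_filtered_manifest,
    generate_blacklists,
    generate_gene_models,
    simulate_cohort,
    simulate_read_counts,
)


def test_zero_rates_give_empty_cohort():
    cfg = CohortConfig(
        n_individuals=5,
        early_rate=0.0,
        late_rate_by_organ={},
        blood_rate_intercept=0.0,
        blood_rate_slope=0.0,
        tumor_fraction=0.0,
        oxog_rate=0.0,
        blacklist_artifact_rate=0.0,
        seed=3,
    )
    cohort = simulate_cohort(cfg)
    assert cohort.truth == []
    assert all(not t.observations for t in cohort.tissues)


def test_zero_organs_rejected():
    cfg = CohortConfig(organs_per_individual=())
    with pytest.raises(ConfigError):
        cfg.validate()


def test_unknown_organ_rejected():
    cfg = CohortConfig(organs_per_individual=("brain", "spleen"))
    with pytest.raises(ConfigError):
        cfg.validate()


def test_bad_signature_mix_rejected():
    cfg = CohortConfig()
    cfg.signature_mix["early"] = {"clocklike_cpg": 0.7}
    with pytest.raises(ConfigError):
        cfg.validate()


def test_blood_late_count_correlates_with_age():
    # oracle: recompute the Pearson correlation from the emitted truth table
    cfg = CohortConfig(
        n_individuals=200,
        early_rate=0.0,
        tumor_fraction=0.0,
        oxog_rate=0.0,
        blacklist_artifact_rate=0.0,
        late_rate_by_organ={"brain": 0.2, "heart": 0.2, "liver": 0.2},
        blood_rate_intercept=0.2,
        blood_rate_slope=0.08,
        seed=17,
    )
    cohort = simulate_cohort(cfg)
    ages, counts = [], []
    for individual in cohort.individuals():
        tissues = cohort.tissues_of(individual)
        blood = next(t for t in tissues if t.organ == "blood")
        ages.append(blood.age)
        counts.append(
            sum(
                1
                for r in cohort.truth
                if r.individual == individual
                and r.stage == "late"
                and blood.tissue_id in r.clone_vaf_by_tissue
            )
        )
    ages, counts = np.array(ages), np.array(counts, dtype=float)
    r = np.corrcoef(ages, counts)[0, 1]
    assert r > 0.3


def test_early_count_within_poisson_band():
    # 190 individuals x rate 2 -> Poisson(380); 3 sigma band from the rate
    cfg = CohortConfig(
        n_individuals=190,
        early_rate=2.0,
        late_rate_by_organ={},
        blood_rate_intercept=0.0,
        blood_rate_slope=0.0,
        tumor_fraction=0.0,
        oxog_rate=0.0,
        blacklist_artifact_rate=0.0,
        seed=23,
    )
    cohort = simulate_cohort(cfg)
    n_early = sum(1 for r in cohort.truth if r.stage == "early")
    lam = 190 * 2.0
    assert abs(n_early - lam) <= 3 * np.sqrt(lam)


def test_determinism_byte_identical(default_config):
    a = simulate_cohort(default_config)
    b = simulate_cohort(CohortConfig(n_individuals=10, seed=1))
    fa, fb = truth_to_frame(a.truth), truth_to_frame(b.truth)
    assert fa.equals(fb)
    oa = [
        (o.site, o.depth, o.alt_count, o.alt_f1r2)
        for t in a.tissues
        for o in t.observations.values()
    ]
    ob = [
        (o.site, o.depth, o.alt_count, o.alt_f1r2)
        for t in b.tissues
        for o in t.observations.values()
    ]
    assert oa == ob


def test_observation_conservation(small_cohort):
    # every tissue of an individual observes every truth site of that individual
    for individual in small_cohort.individuals():
        tissues = small_cohort.tissues_of(individual)
        my_truth = [r for r in small_cohort.truth if r.individual == individual]
        for t in tissues:
            assert len(t.observations) == len(my_truth)
            for rec in my_truth:
                assert rec.site in t.observations


def test_truth_record_stage_invariants(small_cohort):
    by_tissue = {t.tissue_id: t for t in small_cohort.tissues}
    for rec in small_cohort.truth:
        carriers = rec.carrier_tissues
        organs = {by_tissue[t].organ for t in carriers if not by_tissue[t].is_tumor}
        if rec.stage == "early":
            assert len(organs) >= 2
            vafs = set(rec.clone_vaf_by_tissue.values())
            assert len(vafs) == 1  # identical clone VAF across tissues
        elif rec.stage == "late":
            assert len(organs) == 1
        elif rec.stage == "tumor":
            assert organs == set()
            assert all(by_tissue[t].is_tumor for t in carriers)
        else:
            assert rec.artifact and carriers == []


def test_planted_vaf_means_recovered():
    cfg = CohortConfig(n_individuals=60, seed=29, tumor_fraction=0.0)
    cohort = simulate_cohort(cfg)
    for stage in ("early", "late"):
        mean, sd = cfg.vaf_params[stage]
        a = (cfg.vaf_floor - mean) / sd
        b = (1.0 - mean) / sd
        expected = truncnorm.mean(a, b, loc=mean, scale=sd)
        vafs = [
            next(iter(r.clone_vaf_by_tissue.values()))
            for r in cohort.truth
            if r.stage == stage
        ]
        se = np.std(vafs, ddof=1) / np.sqrt(len(vafs))
        assert abs(np.mean(vafs) - expected) < 3 * se


class TestReadCounts:
    def _truth(self, cfg, vaf):
        from mosaicstage.core import Site, SiteAnnotation

        return TruthRecord(
            individual="I",
            site=Site("chr1", 2_000_000, "C", "T"),
            annotation=SiteAnnotation(context="ACA"),
            stage="late",
            clone_vaf_by_tissue={"I_blood": vaf},
        )

    def test_zero_vaf_zero_error_gives_zero_alt(self, rng):
        from tests.conftest import make_tissue

        cfg = CohortConfig(seq_error_rate=0.0)
        rec = self._truth(cfg, 0.0)
        rec.clone_vaf_by_tissue = {}
        tissue = make_tissue("I", "I_blood", "blood")
        obs = simulate_read_counts(rec, tissue, cfg, rng)
        assert obs.alt_count == 0

    def test_vaf_one_zero_error_gives_all_alt(self, rng):
        from tests.conftest import make_tissue

        cfg = CohortConfig(seq_error_rate=0.0)
        rec = self._truth(cfg, 1.0)
        tissue = make_tissue("I", "I_blood", "blood")
        obs = simulate_read_counts(rec, tissue, cfg, rng)
        assert obs.alt_count == obs.depth
        assert obs.vaf == 1.0

    def test_monte_carlo_mean_matches_binomial_expectation(self, rng):
        from tests.conftest import make_tissue

        cfg = CohortConfig(seq_error_rate=0.0, depth_mean=500)
        rec = self._truth(cfg, 0.0617)
        tissue = make_tissue("I", "I_blood", "blood")
        vafs = [
            simulate_read_counts(rec, tissue, cfg, rng).vaf for _ in range(10_000)
        ]
        assert abs(np.mean(vafs) - 0.0617) / 0.0617 < 0.01

    def test_true_variant_orientation_is_balanced(self, rng):
        from tests.conftest import make_tissue

        cfg = CohortConfig(depth_mean=500)
        rec = self._truth(cfg, 0.2)
        tissue = make_tissue("I", "I_blood", "blood")
        f1 = f2 = 0
        for _ in range(500):
            obs = simulate_read_counts(rec, tissue, cfg, rng)
            f1 += obs.alt_f1r2
            f2 += obs.alt_f2r1
        assert abs(f1 - f2) / (f1 + f2) < 0.05

    def test_oxog_artifact_orientation_bias(self, rng):
        from mosaicstage.core import Site, SiteAnnotation
        from tests.conftest import make_tissue

        cfg = CohortConfig(depth_mean=500)
        rec = TruthRecord(
            individual="I",
            site=Site("chr1", 2_000_001, "C", "A"),
            annotation=SiteAnnotation(context="ACA"),
            stage="artifact",
            clone_vaf_by_tissue={},
            artifact=True,
            artifact_kind="oxog",
            artifact_tissue="I_blood",
            apparent_vaf=0.02,
        )
        tissue = make_tissue("I", "I_blood", "blood")
        prone = total = 0
        for _ in range(500):
            obs = simulate_read_counts(rec, tissue, cfg, rng)
            prone += obs.alt_f2r1  # C>A artifacts load F2R1
            total += obs.alt_count
        assert prone / total >= 0.9


class TestBlacklists:
    def test_zero_fraction_all_empty(self):
        cfg = CohortConfig(fraction_blacklisted=0.0)
        tracks = generate_blacklists(cfg)
        assert all(ivs == [] for ivs in tracks.values())

    def test_total_bases_match_configured_fraction(self):
        cfg = CohortConfig(fraction_blacklisted=0.02, seed=31)
        tracks = generate_blacklists(cfg)
        total = sum(e - s for ivs in tracks.values() for _, s, e in ivs)
        target = 0.02 * cfg.contig_length
        assert abs(total - target) / target < 0.02

    def test_tracks_are_disjoint(self):
        cfg = CohortConfig(fraction_blacklisted=0.05, seed=31)
        tracks = generate_blacklists(cfg)
        ivs = sorted(
            (s, e) for track in tracks.values() for _, s, e in track
        )
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2

    def test_planted_artifacts_appear_in_manifest(self):
        cfg = CohortConfig(n_individuals=10, blacklist_artifact_rate=3.0, seed=37)
        cohort = simulate_cohort(cfg)
        manifest = expected_filtered_manifest(cohort.truth, cohort.blacklists)
        planted = [
            r
            for r in cohort.truth
            if r.artifact and r.artifact_kind not in (None, "oxog")
        ]
        assert planted  # the generator did plant some
        manifest_keys = {(r.individual, r.site) for r in manifest}
        for rec in planted:
            assert (rec.individual, rec.site) in manifest_keys


class TestGeneModels:
    def test_cds_lengths_divisible_by_three(self, gene_models):
        genes, _, _ = gene_models
        for g in genes:
            assert g.cds_length % 3 == 0
            spanned = sum(e - s for s, e in g.cds_intervals)
            assert spanned >= g.cds_length

    def test_reference_signatures_normalized(self, gene_models):
        _, _, refs = gene_models
        for name, col in refs.items():
            assert col.shape == (96,)
            assert abs(col.sum() - 1.0) < 1e-9
            assert (col >= 0).all()

    def test_protein_tag_matches_independent_translation(self, gene_models):
        genes, _, _ = gene_models
        for g in genes:
            assert str(Seq(g.cds_seq).translate()) == g.protein

    def test_pli_scores_in_unit_interval(self, gene_models):
        _, pli, _ = gene_models
        assert pli
        assert all(0.0 <= v <= 1.0 for v in pli.values())


def test_draw_vaf_respects_truncation(rng):
    cfg = CohortConfig()
    draws = [draw_vaf(cfg, "late", rng) for _ in range(2000)]
    assert min(draws) >= cfg.vaf_floor
    assert max(draws) <= 1.0
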