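"""Simulator determinism, study-design arithmetic, Mendelian transmission
statistics, annotation injection, and the genotyping-error process."""

import numpy as np
import pytest
from scipy import stats

from trioforge.model import HET, HOM_ALT, HOM_REF
from trioforge.synthetic_cohort import (
    ConfigError,
    SimulationConfig,
    generate_cohort,
    inject_annotations,
    perturb_genotypes,
    simulate_cohort,
)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(seed=7, variants_per_exome=300)
        a, ta = generate_cohort(cfg)
        b, tb = generate_cohort(SimulationConfig(seed=7, variants_per_exome=300))
        assert a.variants == b.variants
        assert np.array_equal(a.gt, b.gt)
        assert np.array_equal(a.depth, b.depth)
        assert a.profiles == b.profiles
        assert ta.labels == tb.labels and ta.planted == tb.planted

    def test_different_seed_differs(self):
        a, _ = simulate_cohort(SimulationConfig(seed=1, variants_per_exome=300))
        b, _ = simulate_cohort(SimulationConfig(seed=2, variants_per_exome=300))
        assert not np.array_equal(a.gt, b.gt)


class TestStudyDesign:
    def test_16_quads_give_64_samples(self):
        cfg = SimulationConfig(n_families=16, n_quads=16, variants_per_exome=100)
        cohort, _ = simulate_cohort(cfg)
        assert cohort.n_samples == 64

    @pytest.mark.parametrize("n_fam,n_quads", [(16, 0), (16, 5), (4, 4)])
    def test_sample_count_formula(self, n_fam, n_quads):
        cfg = SimulationConfig(n_families=n_fam, n_quads=n_quads,
                               n_male_probands=min(11, n_fam), variants_per_exome=80)
        cohort, _ = simulate_cohort(cfg)
        assert cohort.n_samples == 3 * (n_fam - n_quads) + 4 * n_quads

    def test_proband_sex_ratio(self):
        cohort, _ = simulate_cohort(SimulationConfig(variants_per_exome=80))
        sexes = [f.proband_sex for f in cohort.families]
        assert sexes.count("male") == 11 and sexes.count("female") == 5

    def test_site_count_equals_config(self, small_cohort):
        cohort, _, cfg = small_cohort
        assert cohort.n_variants == cfg.variants_per_exome

    def test_planted_sites_constructed_correctly(self, small_cohort):
        cohort, truth, _ = small_cohort
        fam_by_id = {f.family_id: f for f in cohort.families}
        for (key, fam_id), label in truth.planted.items():
            i = cohort.variant_index(key)
            fam = fam_by_id[fam_id]
            pb = cohort.gt[i, cohort.sample_index(fam.proband)]
            fa = cohort.gt[i, cohort.sample_index(fam.father)]
            mo = cohort.gt[i, cohort.sample_index(fam.mother)]
            if label == "de_novo":
                assert (pb, fa, mo) == (HET, HOM_REF, HOM_REF)
                assert all(cohort.gt[i, cohort.sample_index(s)] == HOM_REF
                           for s in fam.siblings)
            else:
                assert (pb, fa, mo) == (HOM_ALT, HET, HET)
                assert all(cohort.gt[i, cohort.sample_index(s)] != HOM_ALT
                           for s in fam.siblings)

    @pytest.mark.parametrize("bad", [
        dict(n_quads=20),
        dict(n_male_probands=17),
        dict(genotyping_error_rate=1.5),
        dict(variants_per_exome=10),  # cannot hold 64 planted sites
        dict(n_recessive_per_proband=1, candidate_af_max=0.0),
    ])
    def test_infeasible_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            SimulationConfig(**bad).validate()


class TestTransmissionStatistics:
    def test_mendel_ratios_at_het_x_het_sites(self):
        # chi-square goodness of fit for the 1:2:1 ratio over >= 10,000
        # child draws at background het x het parent pairs
        cfg = SimulationConfig(seed=23, variants_per_exome=5000)
        cohort, truth = simulate_cohort(cfg)
        planted = {key for (key, _f) in truth.planted}
        counts = np.zeros(3, dtype=int)
        for fam in cohort.families:
            fa = cohort.gt[:, cohort.sample_index(fam.father)]
            mo = cohort.gt[:, cohort.sample_index(fam.mother)]
            hh = (fa == HET) & (mo == HET)
            hh &= np.array([v.key not in planted for v in cohort.variants])
            for child in (fam.proband, *fam.siblings):
                cg = cohort.gt[hh, cohort.sample_index(child)]
                counts += np.bincount(cg, minlength=3)
        assert counts.sum() >= 10_000
        _, p = stats.chisquare(counts, f_exp=counts.sum() * np.array([0.25, 0.5, 0.25]))
        assert p > 0.01

    def test_hardy_weinberg_at_common_site(self):
        # 1,000 parent pairs at af=0.3: genotype frequencies within 3 SE
        rng_cfg = SimulationConfig(
            n_families=1000, n_quads=0, n_male_probands=500, variants_per_exome=70,
            n_de_novo_per_proband=0, n_recessive_per_proband=0,
            af_common_range=(0.3, 0.3), rare_fraction=0.0, seed=5,
        )
        cohort, _ = simulate_cohort(rng_cfg)
        parents = [s for f in cohort.families for s in (f.father, f.mother)]
        cols = [cohort.sample_index(s) for s in parents]
        g = cohort.gt[:, cols]
        n = g.size
        p = 0.3
        expected = {HOM_REF: (1 - p) ** 2, HET: 2 * p * (1 - p), HOM_ALT: p**2}
        for code, freq in expected.items():
            obs = (g == code).mean()
            se = np.sqrt(freq * (1 - freq) / n)
            assert abs(obs - freq) <= 3 * se


class TestAnnotations:
    def test_planted_candidates_are_rare_and_deleterious(self, small_cohort):
        cohort, truth, _ = small_cohort
        for (key, _fam) in truth.planted:
            p = cohort.profiles[cohort.variant_index(key)]
            assert p.af_pop <= 1e-4
            assert p.cadd_phred >= 25
            assert p.sift == "deleterious" and p.polyphen == "damaging"
            assert p.consequence == "missense"

    def test_rare_fraction_zero_makes_background_common(self):
        cfg = SimulationConfig(variants_per_exome=200, rare_fraction=0.0, seed=9)
        cohort, truth = simulate_cohort(cfg)
        cohort = inject_annotations(cohort, truth, cfg)
        planted = {key for (key, _f) in truth.planted}
        bg = [p.af_pop for v, p in zip(cohort.variants, cohort.profiles)
              if v.key not in planted]
        assert min(bg) >= 0.05

    def test_every_variant_annotated(self, small_cohort):
        cohort, _, _ = small_cohort
        assert all(p is not None for p in cohort.profiles)

    def test_depth_mean_near_configured(self, small_cohort):
        cohort, _, cfg = small_cohort
        assert cohort.depth.mean() == pytest.approx(cfg.depth_mean, rel=0.05)


class TestPerturbation:
    def test_zero_rate_is_identity(self, trio_cohort):
        cohort, _, _ = trio_cohort
        out = perturb_genotypes(cohort, 0.0, seed=4)
        assert np.array_equal(out.gt, cohort.gt)

    def test_rate_one_changes_every_genotype(self, trio_cohort):
        cohort, _, _ = trio_cohort
        out = perturb_genotypes(cohort, 1.0, seed=4)
        assert np.all(out.gt != cohort.gt)

    def test_perturbed_fraction_matches_rate(self):
        cfg = SimulationConfig(n_families=16, n_quads=16, variants_per_exome=200, seed=2)
        cohort, _ = simulate_cohort(cfg)  # 200 x 64 = 12,800 genotypes
        out = perturb_genotypes(cohort, 0.1, seed=8)
        frac = (out.gt != cohort.gt).mean()
        assert 0.09 <= frac <= 0.11  # 99% binomial interval at n=12,800

    def test_truth_set_unchanged(self, trio_cohort):
        cohort, truth, _ = trio_cohort
        before = dict(truth.planted)
        perturb_genotypes(cohort, 0.5, seed=1)
        assert truth.planted == before
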