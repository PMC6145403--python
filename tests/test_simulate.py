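"""One-generation and multi-generation invasion simulator."""

import numpy as np
import pytest

from rdinvade.genetics import HET, RD_HOM, WT_HOM, Individual, Sex
from rdinvade.simulate import (
    DemographicFailureError,
    FitnessScheme,
    SimulationConfig,
    form_pairs,
    genotype_weight,
    make_founders,
    recruit,
    run_trajectory,
    step_generation,
    viability_select,
)


class TestGenotypeWeight:
    def test_homozygote_weights_give_alpha_odds(self):
        # a pool of one Rd/Rd and one WT/WT yields probabilities
        # 1/(alpha+1) and alpha/(alpha+1)
        assert genotype_weight(RD_HOM, 2.0) == 1.0
        assert genotype_weight(WT_HOM, 2.0) == 2.0

    def test_heterozygote_intermediate(self):
        assert genotype_weight(HET, 3.0) == pytest.approx(2.0)
        assert genotype_weight(HET, 4.0, het_mode="geometric") == pytest.approx(2.0)

    def test_neutral_alpha(self):
        for g in (RD_HOM, HET, WT_HOM):
            assert genotype_weight(g, 1.0) == 1.0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            genotype_weight(WT_HOM, 0.0)
        with pytest.raises(ValueError):
            FitnessScheme(alpha=-1.0)


def test_make_founders_design():
    founders = make_founders(SimulationConfig())
    assert len(founders) == 100
    females = [f for f in founders if f.sex is Sex.FEMALE]
    males = [m for m in founders if m.sex is Sex.MALE]
    assert len(females) == len(males) == 50  # 1:1 sex ratio
    wt_hom = [f for f in founders if f.genotype.n_wt == 2]
    assert len(wt_hom) == 10  # 10% WT colonists
    assert all(i.sex is Sex.MALE for i in wt_hom)  # no WT females introduced
    assert all(f.genotype.n_wt == 0 for f in females)


class TestFormPairs:
    def test_founder_pairs_all_rd_mothers(self, rng):
        founders = make_founders(SimulationConfig())
        females = [f for f in founders if f.sex is Sex.FEMALE]
        males = [m for m in founders if m.sex is Sex.MALE]
        pairs = form_pairs(females, males, FitnessScheme(alpha=5, male_effect=True), 0, rng)
        assert len(pairs) == 50
        assert all(mother.genotype.n_wt == 0 for mother, _ in pairs)

    def test_male_weighting_oracle(self, rng):
        # 10 WT/WT among 90 Rd/Rd males at alpha=10: expected WT-sire
        # fraction = 100/(100+90); tolerance 3 binomial SDs at n=10000
        males = [Individual(Sex.MALE, RD_HOM)] * 90 + [Individual(Sex.MALE, WT_HOM)] * 10
        females = [Individual(Sex.FEMALE, RD_HOM)] * 10_000
        scheme = FitnessScheme(alpha=10, male_effect=True)
        pairs = form_pairs(females, males, scheme, 0, rng)
        frac = sum(father.genotype.n_wt == 2 for _, father in pairs) / len(pairs)
        p = 100 / 190
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 10_000)

    def test_neutral_sampling_matches_pool_fraction(self, rng):
        males = [Individual(Sex.MALE, RD_HOM)] * 90 + [Individual(Sex.MALE, WT_HOM)] * 10
        females = [Individual(Sex.FEMALE, RD_HOM)] * 10_000
        pairs = form_pairs(females, males, FitnessScheme(), 0, rng)
        frac = sum(father.genotype.n_wt == 2 for _, father in pairs) / len(pairs)
        assert abs(frac - 0.10) < 3 * np.sqrt(0.1 * 0.9 / 10_000)

    def test_female_effect_only_after_first_generation(self, rng):
        # at generation 0 female weighting must be inactive
        females = [Individual(Sex.FEMALE, RD_HOM)] * 50 + [Individual(Sex.FEMALE, WT_HOM)] * 50
        males = [Individual(Sex.MALE, RD_HOM)] * 10
        scheme = FitnessScheme(alpha=10, female_effect=True)
        for generation_index, p in [(0, 0.5), (1, 10 / 11)]:
            fracs = []
            for _ in range(40):
                pairs = form_pairs(females, males, scheme, generation_index, rng)
                fracs.append(
                    sum(m.genotype.n_wt == 2 for m, _ in pairs) / len(pairs)
                )
            n = 40 * len(females)
            assert abs(np.mean(fracs) - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_empty_pool_is_demographic_failure(self, rng):
        females = [Individual(Sex.FEMALE, RD_HOM)]
        with pytest.raises(DemographicFailureError):
            form_pairs(females, [], FitnessScheme(), 0, rng)


class TestViabilitySelect:
    def test_thirty_percent_of_full_clutch(self, rng):
        offspring = [HET] * 2600  # 50 pairs x 52 offspring
        survivors = viability_select(offspring, FitnessScheme(), 0.30, rng)
        assert len(survivors) == 780

    def test_uniform_thinning_preserves_proportions(self, rng):
        offspring = [RD_HOM] * 5000 + [HET] * 5000
        scheme = FitnessScheme(alpha=5, offspring_effect=False)
        fracs = [
            sum(g.n_wt == 1 for g in viability_select(offspring, scheme, 0.3, rng)) / 3000
            for _ in range(20)
        ]
        assert abs(np.mean(fracs) - 0.5) < 3 * np.sqrt(0.25 / (20 * 3000))

    def test_weighted_selection_favours_het_over_rd(self, rng):
        offspring = [RD_HOM] * 5000 + [HET] * 5000
        scheme = FitnessScheme(alpha=5, offspring_effect=True)
        fracs = [
            sum(g.n_wt == 1 for g in viability_select(offspring, scheme, 0.3, rng)) / 3000
            for _ in range(10)
        ]
        assert min(fracs) > 0.5

    def test_empty_offspring_rejected(self, rng):
        with pytest.raises(DemographicFailureError):
            viability_select([], FitnessScheme(), 0.3, rng)


class TestRecruit:
    def test_default_quotas(self, rng):
        adults = recruit([HET] * 3588, 230, 230, rng)
        assert len(adults) == 460
        assert sum(a.sex is Sex.MALE for a in adults) == 230
        assert sum(a.sex is Sex.FEMALE for a in adults) == 230

    def test_insufficient_survivors_fail(self, rng):
        with pytest.raises(DemographicFailureError) as err:
            recruit([HET] * 100, 230, 230, rng, generation_index=3)
        assert err.value.generation == 3

    def test_genotypes_preserved(self, rng):
        adults = recruit([WT_HOM] * 2000, 230, 230, rng)
        assert all(a.genotype.n_wt == 2 for a in adults)


class TestStepGeneration:
    def test_no_wt_homozygotes_in_first_generation(self, rng):
        # founder mothers carry no WT allele, so WT/WT cannot appear in F1
        founders = make_founders(SimulationConfig())
        scheme = FitnessScheme(alpha=10, male_effect=True, female_effect=True, offspring_effect=True)
        nxt = step_generation(founders, scheme, SimulationConfig(), 0, rng)
        assert len(nxt) == 460
        assert sum(a.genotype.n_wt == 2 for a in nxt) == 0

    def test_all_rd_stays_all_rd(self, rng):
        adults = [Individual(Sex.FEMALE, RD_HOM)] * 50 + [Individual(Sex.MALE, RD_HOM)] * 50
        nxt = step_generation(adults, FitnessScheme(alpha=10, male_effect=True), SimulationConfig(), 0, rng)
        assert all(a.genotype.n_wt == 0 for a in nxt)


class TestRunTrajectory:
    def test_population_size_and_generation1(self):
        for seed in (0, 1, 2):
            for scheme in (FitnessScheme(), FitnessScheme(alpha=10, male_effect=True,
                                                          female_effect=True, offspring_effect=True)):
                traj = run_trajectory(scheme, SimulationConfig(), np.random.default_rng(seed))
                assert traj.prop_wt_homozygote[1] == 0.0
                assert (traj.n_adults[1:] == 460).all()
                assert traj.n_adults[0] == 100
                assert traj.prop_wt_homozygote[0] == pytest.approx(0.10)

    def test_neutral_drift_preserves_allele_frequency(self):
        # martingale: replicate-mean WT allele frequency stays at 0.10
        freqs = np.array([
            run_trajectory(FitnessScheme(), SimulationConfig(),
                           np.random.default_rng(seed)).wt_allele_frequency[-1]
            for seed in range(200)
        ])
        se = freqs.std(ddof=1) / np.sqrt(len(freqs))
        assert abs(freqs.mean() - 0.10) < 3 * se

    def test_stronger_alpha_invades_more(self):
        def gen8_median(alpha):
            props = [
                run_trajectory(
                    FitnessScheme(alpha=alpha, male_effect=True, female_effect=True,
                                  offspring_effect=True),
                    SimulationConfig(),
                    np.random.default_rng(seed),
                ).prop_wt_homozygote[-1]
                for seed in range(60)
            ]
            return np.median(props)

        assert gen8_median(10.0) > gen8_median(1.5)
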