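import numpy as np
import pytest

from introsim import (
    ExperimentDesign,
    ExtinctionError,
    Haplotype,
    Individual,
    InsufficientSurvivorsError,
    Population,
    SelectionParams,
    expected_trajectory,
    genotype_fitness,
    make_founder_population,
    make_gamete,
    marker_frequency,
    reproduce,
    run_replicate,
    sample_marker_frequency,
    viability_selection,
)
from introsim.simulate import HAP_SECH_COUPLING, HAP_SIM_COUPLING, SECH, SIM

COUPLING_HET = Individual(
    Haplotype(SECH, SECH), Haplotype(SIM, SIM), sex="female"
)


def single_locus_recursion(s, h, q0, n):
    """Independent brute-force oracle: classic viability-selection recursion."""
    q = q0
    out = [q]
    for _ in range(n):
        p = 1 - q
        mean_w = p * p + 2 * p * q * (1 - h * s) + q * q * (1 - s)
        q = (q * q * (1 - s) + p * q * (1 - h * s)) / mean_w
        out.append(q)
    return np.array(out)


class TestFounder:
    def test_default_design(self, default_design):
        pop = make_founder_population(default_design)
        assert pop.size == 300
        assert pop.generation == 0
        assert marker_frequency(pop) == 0.5

    def test_minimal_design(self):
        d = ExperimentDesign(
            n_males=1, n_females=1, n_generations=1, sample_generations=(1,),
            sample_males=1, sample_females=1,
        )
        pop = make_founder_population(d)
        assert pop.size == 2
        for ind in pop.individuals():
            assert ind.n_sech_fitness == 1
            assert ind.n_sech_marker == 1

    def test_full_coupling_no_repulsion(self, default_design):
        pop = make_founder_population(default_design)
        haps = np.concatenate([pop.males, pop.females]).ravel()
        assert set(haps.tolist()) == {HAP_SECH_COUPLING, HAP_SIM_COUPLING}


class TestGenotypeFitness:
    def test_sim_homozygote_unaffected(self):
        ind = Individual(Haplotype(SECH, SIM), Haplotype(SECH, SIM), sex="male")
        assert genotype_fitness(ind, SelectionParams(s=0.9, h=1.0)) == 1.0

    def test_heterozygote(self):
        assert genotype_fitness(COUPLING_HET, SelectionParams(s=0.3, h=1.0)) == pytest.approx(0.7)

    def test_sech_homozygote(self):
        ind = Individual(Haplotype(SIM, SECH), Haplotype(SIM, SECH), sex="female")
        assert genotype_fitness(ind, SelectionParams(s=0.43, h=0.0)) == pytest.approx(0.57)

    def test_marker_does_not_affect_fitness(self):
        p = SelectionParams(s=0.5, h=0.5)
        a = Individual(Haplotype(SECH, SIM), Haplotype(SECH, SIM), sex="male")
        b = Individual(Haplotype(SIM, SIM), Haplotype(SIM, SIM), sex="male")
        assert genotype_fitness(a, p) == genotype_fitness(b, p) == 1.0

    def test_literal_scheme_switch(self):
        assert genotype_fitness(COUPLING_HET, SelectionParams(s=0.3, h=1.0), "literal") == (
            pytest.approx(0.3)
        )


class TestViabilitySelection:
    def test_neutral_everyone_survives(self, default_design, rng):
        pop = make_founder_population(default_design)
        out = viability_selection(pop, SelectionParams(s=0.0, h=0.5), rng)
        assert out.size == pop.size
        assert out.generation == pop.generation

    def test_lethal_dominant_keeps_only_sim_homozygotes(self, rng):
        males = np.array([[0, 0], [1, 0], [1, 1], [0, 0]])
        females = np.array([[0, 0], [3, 1], [0, 0]])
        pop = Population(males=males, females=females, generation=3)
        out = viability_selection(pop, SelectionParams(s=1.0, h=1.0), rng)
        assert out.n_males == 2 and out.n_females == 2
        assert ((np.concatenate([out.males, out.females]) & 1) == 0).all()

    def test_founder_extinction_at_lethal_dominant(self, default_design, rng):
        pop = make_founder_population(default_design)
        with pytest.raises(ExtinctionError):
            viability_selection(pop, SelectionParams(s=1.0, h=1.0), rng)


class TestMakeGamete:
    def draw_codes(self, parent, c, rng, n=4000):
        return np.array([make_gamete(parent, c, rng).code for _ in range(n)])

    def test_male_heterozygote_transmits_parentals_only(self, rng):
        male = Individual(Haplotype(SECH, SECH), Haplotype(SIM, SIM), sex="male")
        codes = self.draw_codes(male, 0.5, rng)
        counts = np.bincount(codes, minlength=4)
        assert counts[1] == counts[2] == 0
        assert abs(counts[3] / len(codes) - 0.5) < 0.03

    def test_female_no_recombination(self, rng):
        codes = self.draw_codes(COUPLING_HET, 0.0, rng)
        assert set(np.unique(codes)) == {HAP_SIM_COUPLING, HAP_SECH_COUPLING}

    def test_female_free_recombination_quarter_each(self, rng):
        # gamete classes occur at (1-c)/2 and c/2; at c = 0.5 all four are 1/4
        codes = self.draw_codes(COUPLING_HET, 0.5, rng, n=8000)
        freqs = np.bincount(codes, minlength=4) / 8000
        assert np.allclose(freqs, 0.25, atol=0.02)

    def test_female_intermediate_c_class_frequencies(self, rng):
        c = 0.2
        codes = self.draw_codes(COUPLING_HET, c, rng, n=8000)
        freqs = np.bincount(codes, minlength=4) / 8000
        parental = freqs[HAP_SIM_COUPLING] + freqs[HAP_SECH_COUPLING]
        assert abs(parental - (1 - c)) < 0.02


class TestReproduce:
    def test_monomorphic_preserved(self, small_design, rng):
        n = np.zeros((10, 2), dtype=int)
        pop = Population(males=n.copy(), females=n.copy(), generation=2)
        out = reproduce(pop, small_design, SelectionParams(s=0.3, h=0.5, c=0.3), rng)
        assert (np.concatenate([out.males, out.females]) == 0).all()

    def test_census_restored_exactly(self, default_design, rng):
        pop = make_founder_population(default_design)
        survivors = Population(males=pop.males[:17], females=pop.females[:31], generation=0)
        out = reproduce(survivors, default_design, SelectionParams(s=0.2, h=0.5), rng)
        assert out.n_males == default_design.n_males
        assert out.n_females == default_design.n_females
        assert out.generation == 1

    def test_single_pair_no_recombination_parental_haplotypes(self, small_design, rng):
        pop = Population(males=np.array([[3, 0]]), females=np.array([[2, 1]]), generation=0)
        out = reproduce(pop, small_design, SelectionParams(s=0.1, h=0.5, c=0.0), rng)
        kids = np.concatenate([out.males, out.females])
        assert set(kids[:, 0].tolist()) <= {2, 1}  # maternal gametes
        assert set(kids[:, 1].tolist()) <= {3, 0}  # paternal gametes

    def test_extinct_sex_raises(self, small_design, rng):
        pop = Population(males=np.zeros((0, 2)), females=np.zeros((3, 2)), generation=0)
        with pytest.raises(ExtinctionError):
            reproduce(pop, small_design, SelectionParams(s=0.1, h=0.5), rng)


class TestSampleMarkerFrequency:
    def test_monomorphic_sech_marker(self, default_design, rng):
        arr = np.tile([2, 3], (150, 1))  # every haplotype carries the sech marker
        pop = Population(males=arr.copy(), females=arr.copy(), generation=7)
        obs, rest = sample_marker_frequency(pop, default_design, rng)
        assert obs.frequency == 1.0
        assert obs.sech_marker_count == 80
        assert obs.n_alleles == 80

    def test_population_reduced_by_sample(self, default_design, rng):
        pop = make_founder_population(default_design)
        obs, rest = sample_marker_frequency(pop, default_design, rng)
        assert rest.size == pop.size - 40
        assert obs.generation == pop.generation

    def test_insufficient_survivors(self, default_design, rng):
        pop = Population(
            males=np.zeros((20, 2)), females=np.zeros((150, 2)), generation=7
        )
        with pytest.raises(InsufficientSurvivorsError):
            sample_marker_frequency(pop, default_design, rng)

    def test_counts_match_sampled_composition(self, default_design, rng):
        pop = make_founder_population(default_design)  # every fly has exactly 2 sech alleles? no: 1
        obs, _ = sample_marker_frequency(pop, default_design, rng)
        # founders are all single-sech-marker heterozygotes: exactly 40 of 80
        assert obs.sech_marker_count == 40


class TestRunReplicate:
    def test_default_schedule_three_observations(self, default_design, rng):
        obs = run_replicate(SelectionParams(s=0.4, h=0.5, c=0.0001), default_design, rng)
        assert [o.generation for o in obs] == [7, 14, 20]
        assert all(o.n_alleles == 80 for o in obs)

    def test_lethal_dominant_coupling_goes_to_zero(self, default_design, rng):
        obs = run_replicate(SelectionParams(s=1.0, h=1.0, c=0.0), default_design, rng)
        assert [o.frequency for o in obs] == [0.0, 0.0, 0.0]

    def test_neutral_mean_near_half(self, default_design):
        # individual-based engine at reduced replicate count; the 2,000-replicate
        # version runs on the batch engine in the acceptance suite
        n = 300
        means = []
        for i in range(n):
            rng = np.random.default_rng(1000 + i)
            obs = run_replicate(SelectionParams(s=0.0, h=0.5, c=0.0), default_design, rng)
            means.append(obs[-1].frequency)
        se = np.std(means, ddof=1) / np.sqrt(n)
        assert abs(np.mean(means) - 0.5) < 3 * se + 1e-12

    def test_terminal_states_absorbed_full_schedule(self):
        # tiny census at strong selection: sexes frequently dwindle below the
        # sample size or die out, yet every replicate must still report the
        # full schedule with in-range frequencies
        design = ExperimentDesign(
            n_males=3, n_females=3, n_generations=10, sample_generations=(2, 6, 10),
            sample_males=1, sample_females=1,
        )
        params = SelectionParams(s=0.9, h=1.0, c=0.0)
        for i in range(50):
            rng = np.random.default_rng(i)
            obs = run_replicate(params, design, rng)
            assert [o.generation for o in obs] == [2, 6, 10]
            assert all(0.0 <= o.frequency <= 1.0 for o in obs)


class TestExpectedTrajectory:
    def test_neutral_constant(self):
        tr = expected_trajectory(SelectionParams(s=0.0, h=0.5, c=0.3), p0=0.37, n_generations=10)
        assert np.allclose(tr, 0.37)

    def test_lethal_dominant_zero_from_generation_one(self):
        tr = expected_trajectory(SelectionParams(s=1.0, h=1.0, c=0.0), p0=0.5)
        assert tr[0] == 0.5
        assert np.allclose(tr[1:], 0.0)

    def test_hand_computed_first_generation(self):
        tr = expected_trajectory(SelectionParams(s=0.4, h=0.5, c=0.0), p0=0.5)
        assert tr[1] == pytest.approx(0.4375, abs=1e-12)

    @pytest.mark.parametrize("s,h", [(0.4, 0.5), (0.43, 0.5), (0.2, 0.0), (0.7, 1.0)])
    def test_c_zero_matches_single_locus_recursion(self, s, h):
        tr = expected_trajectory(SelectionParams(s=s, h=h, c=0.0), p0=0.5, n_generations=20)
        oracle = single_locus_recursion(s, h, 0.5, 20)
        assert np.allclose(tr, oracle, atol=1e-12)

    def test_recombination_slows_marker_decline(self):
        tight = expected_trajectory(SelectionParams(s=0.6, h=0.5, c=0.0))
        loose = expected_trajectory(SelectionParams(s=0.6, h=0.5, c=0.5))
        assert loose[7] > tight[7]


class TestLargeCensusAgreement:
    def test_individual_engine_tracks_oracle(self):
        # census 5,000 per sex keeps drift tiny; replicate means should sit on
        # the deterministic trajectory
        params = SelectionParams(s=0.4, h=0.5, c=0.0)
        design = ExperimentDesign(
            n_males=5000, n_females=5000, n_generations=7, sample_generations=(7,),
        )
        n = 20
        freqs = []
        for i in range(n):
            rng = np.random.default_rng(7000 + i)
            obs = run_replicate(params, design, rng)
            freqs.append(obs[0].frequency)
        se = np.std(freqs, ddof=1) / np.sqrt(n)
        expected = expected_trajectory(params, n_generations=7)[7]
        assert abs(np.mean(freqs) - expected) < 3 * se + 1e-9
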