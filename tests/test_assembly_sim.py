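import numpy as np
import pytest

from feediv.assembly_sim import (
    AssemblyConfig,
    init_assembly,
    recruitment_weights,
    run_forward,
    step,
    uniform_pool_traits,
)


@pytest.fixture
def pool_traits(rng):
    return uniform_pool_traits(200, 1, rng)


class TestConfig:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="p_local"):
            AssemblyConfig(p_local=0.8, p_immigration=0.3)

    def test_initial_richness_bounded_by_pool(self):
        with pytest.raises(ValueError, match="pool"):
            AssemblyConfig(pool_size=20, n_init=30)

    def test_unknown_process_rejected(self):
        with pytest.raises(ValueError, match="process"):
            AssemblyConfig(process="magic")


class TestInit:
    def test_default_community_size(self, rng):
        abund = init_assembly(AssemblyConfig(), rng)
        assert abund.sum() == 150  # 30 species x 5 individuals
        assert (abund > 0).sum() == 30
        assert set(abund[abund > 0]) == {5}

    def test_full_pool_boundary(self, rng):
        cfg = AssemblyConfig(pool_size=30, n_init=30)
        abund = init_assembly(cfg, rng)
        assert (abund > 0).all()

    def test_seeded_determinism(self):
        a = init_assembly(AssemblyConfig(), np.random.default_rng(5))
        b = init_assembly(AssemblyConfig(), np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestRecruitmentWeights:
    def test_neutral_all_ones(self, pool_traits):
        cfg = AssemblyConfig(process="neutral")
        abund = init_assembly(cfg, np.random.default_rng(0))
        assert (recruitment_weights(pool_traits, abund, cfg) == 1.0).all()

    def test_nf_maximal_at_optimum(self):
        cfg = AssemblyConfig(process="nf", t_opt=0.5, sigma_env=0.1)
        traits = np.array([[0.5], [0.6], [0.9]])
        cfg = AssemblyConfig(
            process="nf", t_opt=0.5, sigma_env=0.1, pool_size=3, n_init=2
        )
        w = recruitment_weights(traits, np.array([1, 1, 0]), cfg)
        assert w[0] == pytest.approx(1.0)
        assert w[0] > w[1] > w[2]

    def test_ls_trait_duplicate_of_resident_penalized(self):
        cfg = AssemblyConfig(process="ls", pool_size=3, n_init=2)
        traits = np.array([[0.2], [0.2], [0.8]])
        # species 0 resident; candidate 1 shares its trait exactly and
        # carries a full unit of competition load
        w = recruitment_weights(traits, np.array([4, 0, 0]), cfg)
        assert w[1] == pytest.approx(np.exp(-1.0))
        assert w[2] > 0.99  # far away: nearly unhindered
        assert w[2] > w[1]

    def test_ls_resident_does_not_compete_with_itself(self):
        cfg = AssemblyConfig(process="ls", pool_size=3, n_init=2)
        traits = np.array([[0.2], [0.5], [0.8]])
        w = recruitment_weights(traits, np.array([4, 0, 2]), cfg)
        # species 0's only competitor is at distance 0.6, far beyond
        # the competition width
        assert w[0] > 0.99

    def test_ls_load_accumulates_over_residents(self):
        cfg = AssemblyConfig(process="ls", pool_size=4, n_init=2)
        traits = np.array([[0.5], [0.52], [0.48], [0.5]])
        # candidate 3 sits between two close residents: double load
        w = recruitment_weights(traits, np.array([2, 1, 1, 0]), cfg)
        assert w[3] < recruitment_weights(
            traits, np.array([2, 1, 0, 0]), cfg
        )[3]

    def test_ls_sole_resident_weight_one(self):
        cfg = AssemblyConfig(process="ls", pool_size=2, n_init=2)
        traits = np.array([[0.2], [0.9]])
        w = recruitment_weights(traits, np.array([3, 0]), cfg)
        assert w[0] == pytest.approx(1.0)


class TestStep:
    def test_individual_count_conserved(self, pool_traits, rng):
        cfg = AssemblyConfig()
        abund = init_assembly(cfg, rng)
        for _ in range(30):
            abund = step(abund, pool_traits, cfg, rng)
            assert abund.sum() == 150

    def test_death_count_is_rounded_fraction(self, pool_traits):
        # J = 150, 2% -> exactly 3 deaths; with immigration possible the
        # change in any species' abundance is bounded by 3
        cfg = AssemblyConfig()
        rng = np.random.default_rng(1)
        abund = init_assembly(cfg, rng)
        after = step(abund, pool_traits, cfg, rng)
        assert (abund - after).clip(min=0).sum() <= 3
        assert after.sum() == abund.sum()

    def test_extinct_community_rejected(self, pool_traits, rng):
        with pytest.raises(ValueError, match="extinct"):
            step(np.zeros(200, dtype=int), pool_traits, AssemblyConfig(), rng)


class TestRunForward:
    def test_zero_generations_identity(self, pool_traits):
        cfg = AssemblyConfig(generations=0)
        rng = np.random.default_rng(3)
        init = init_assembly(cfg, np.random.default_rng(9))
        res = run_forward(pool_traits, cfg, rng=rng, initial_abundances=init)
        np.testing.assert_array_equal(res.abundances, init)
        assert res.richness_trajectory.tolist() == [30]

    def test_same_seed_identical_results(self, pool_traits):
        cfg = AssemblyConfig(generations=40, process="ls")
        a = run_forward(pool_traits, cfg, seed=17)
        b = run_forward(pool_traits, cfg, seed=17)
        np.testing.assert_array_equal(a.abundances, b.abundances)
        np.testing.assert_array_equal(
            a.richness_trajectory, b.richness_trajectory
        )

    def test_pure_drift_loses_species_on_average(self):
        # without immigration, neutral drift can only lose founders
        rng = np.random.default_rng(7)
        cfg = AssemblyConfig(
            generations=150, p_local=1.0, p_immigration=0.0
        )
        finals = []
        for _ in range(60):
            traits = uniform_pool_traits(200, 1, rng)
            finals.append(run_forward(traits, cfg, rng=rng).final_richness)
        assert np.mean(finals) < 30

    def test_immigration_rebuilds_richness_above_drift(self):
        # with 20% immigration from a 200-species pool, novel immigrants
        # arrive faster than slow drift removes species
        rng = np.random.default_rng(7)
        finals = []
        for _ in range(60):
            traits = uniform_pool_traits(200, 1, rng)
            finals.append(
                run_forward(
                    traits, AssemblyConfig(generations=150), rng=rng
                ).final_richness
            )
        assert 30 < np.mean(finals) < 200

    def test_nf_compresses_traits_relative_to_neutral(self):
        rng = np.random.default_rng(21)
        spreads = {"neutral": [], "nf": []}
        for _ in range(30):
            traits = uniform_pool_traits(200, 1, rng)
            init = init_assembly(AssemblyConfig(), rng)
            for process in spreads:
                cfg = AssemblyConfig(
                    process=process, generations=150, sigma_env=0.1
                )
                res = run_forward(
                    traits, cfg,
                    rng=np.random.default_rng(rng.integers(2**31)),
                    initial_abundances=init,
                )
                spreads[process].append(traits[res.members, 0].std())
        assert np.mean(spreads["nf"]) < np.mean(spreads["neutral"])
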