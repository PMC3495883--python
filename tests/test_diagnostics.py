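"""Transition matrices, equilibrium waves, stabilisation curves and chain
statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from webrds import (
    RecruitmentForest,
    SimulationConfig,
    TransitionMatrix,
    cross_group_recruitment_fraction,
    estimate_transition_matrix,
    fabricate_submissions,
    last_k_comparison,
    rdsii_mean_degree,
    rdsii_proportion,
    running_composition,
    simulate_recruitment,
    stationary_distribution,
    wave_stats,
    waves_to_equilibrium,
)

from conftest import make_records


def tm(matrix, states=None):
    matrix = np.asarray(matrix, dtype=float)
    states = states or [chr(65 + i) for i in range(matrix.shape[0])]
    return TransitionMatrix(variable="v", states=states, counts=matrix * 100)


def chain_records(categories):
    """A single chain s -> 1 -> 2 ... with the given category sequence."""
    parent = {i: (None if i == 0 else i - 1) for i in range(len(categories))}
    forest = RecruitmentForest(parent=parent, timestamp={i: float(i) for i in parent})
    records = pd.DataFrame({"id": list(parent), "cat": list(categories)})
    return forest, records


class TestEstimateTransitionMatrix:
    def test_count_and_normalize_by_hand(self):
        # events: A->A, A->B, B->A, B->A
        parent = {"s": None, "a": "s", "b": "s", "c": "b", "d": "b"}
        forest = RecruitmentForest(parent=parent)
        records = pd.DataFrame(
            {"id": ["s", "a", "b", "c", "d"], "cat": ["A", "A", "B", "A", "A"]}
        )
        t = estimate_transition_matrix(forest, records, "cat")
        assert t.states == ["A", "B"]
        np.testing.assert_allclose(t.probs, [[0.5, 0.5], [1.0, 0.0]])

    def test_perfect_homophily_gives_identity(self):
        forest, records = chain_records(["A", "A", "B", "B"])
        # two chains would be needed for two states; build explicitly
        parent = {"s1": None, "a": "s1", "s2": None, "b": "s2"}
        forest = RecruitmentForest(parent=parent)
        records = pd.DataFrame(
            {"id": ["s1", "a", "s2", "b"], "cat": ["A", "A", "B", "B"]}
        )
        t = estimate_transition_matrix(forest, records, "cat")
        np.testing.assert_allclose(t.probs, np.eye(2))

    def test_independent_recruitment_rows_match_marginal(self, small_population):
        """With zero homophily every row approximates the recruit marginal."""
        sim = SimulationConfig(n_seeds=8, participation_probability=0.6, rng_seed=21)
        forest = simulate_recruitment(small_population, sim)
        fab = fabricate_submissions(forest, small_population, sim)
        table = fab.table.copy()
        rng = np.random.default_rng(0)
        table["coin"] = rng.choice(["h", "t"], p=[0.7, 0.3], size=len(table))
        t = estimate_transition_matrix(forest, table, "coin")
        for row in t.probs:
            assert row[t.states.index("h")] == pytest.approx(0.7, abs=0.12)

    def test_no_events_raises(self):
        forest = RecruitmentForest(parent={"s": None})
        records = pd.DataFrame({"id": ["s"], "cat": ["A"]})
        with pytest.raises(ValueError, match="no recruitment events"):
            estimate_transition_matrix(forest, records, "cat")

    def test_recruit_only_categories_are_dropped_states(self):
        forest, records = chain_records(["A", "A", "C"])
        t = estimate_transition_matrix(forest, records, "cat")
        assert t.states == ["A"] and t.dropped_states == ["C"]


class TestStationaryDistribution:
    def test_identical_rows_give_that_row(self):
        pi = stationary_distribution(tm([[0.3, 0.7], [0.3, 0.7]]))
        np.testing.assert_allclose(pi, [0.3, 0.7], atol=1e-12)

    def test_two_state_worked_example(self):
        pi = stationary_distribution(tm([[0.8, 0.2], [0.3, 0.7]]))
        np.testing.assert_allclose(pi, [0.6, 0.4], atol=1e-12)

    def test_doubly_stochastic_is_uniform(self):
        pi = stationary_distribution(tm([[0.5, 0.25, 0.25], [0.25, 0.5, 0.25], [0.25, 0.25, 0.5]]))
        np.testing.assert_allclose(pi, [1 / 3] * 3, atol=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        """Independent route: leading left eigenvector via scipy."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            P = rng.uniform(0.05, 1.0, size=(4, 4))
            P /= P.sum(axis=1, keepdims=True)
            pi = stationary_distribution(tm(P))
            w, vl = scipy.linalg.eig(P, left=True, right=False)
            lead = np.argmin(np.abs(w - 1.0))
            oracle = np.real(vl[:, lead])
            oracle /= oracle.sum()
            np.testing.assert_allclose(pi, oracle, atol=1e-9)
            np.testing.assert_allclose(pi @ P, pi, atol=1e-10)

    def test_reducible_chain_raises_with_states(self):
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(tm(np.eye(2)))

    def test_periodic_chain_raises(self):
        with pytest.raises(ValueError, match="periodic"):
            stationary_distribution(tm([[0.0, 1.0], [1.0, 0.0]]))


def two_state_waves_closed_form(P, tol=0.02):
    """Eigenvalue-decay oracle: worst-case relative deviation after n steps
    of a two-state chain is |lambda|^n * max(pi_A/pi_B, pi_B/pi_A) with
    lambda = P11 + P22 - 1."""
    lam = abs(P[0][0] + P[1][1] - 1.0)
    pi_a = P[1][0] / (P[0][1] + P[1][0])
    ratio = max(pi_a / (1 - pi_a), (1 - pi_a) / pi_a)
    n = 1
    while lam**n * ratio >= tol:
        n += 1
    return n


class TestWavesToEquilibrium:
    def test_one_step_mixing(self):
        assert waves_to_equilibrium(tm([[0.3, 0.7], [0.3, 0.7]])) == 1

    def test_two_state_worked_example(self):
        assert waves_to_equilibrium(tm([[0.8, 0.2], [0.3, 0.7]])) == 7

    def test_identity_is_reducible(self):
        with pytest.raises(ValueError, match="reducible"):
            waves_to_equilibrium(tm(np.eye(2)))

    def test_matches_closed_form_on_random_two_state_chains(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p12, p21 = rng.uniform(0.05, 0.95, size=2)
            P = [[1 - p12, p12], [p21, 1 - p21]]
            assert waves_to_equilibrium(tm(P)) == two_state_waves_closed_form(P)

    def test_nonincreasing_in_tolerance(self):
        t = tm([[0.9, 0.1], [0.2, 0.8]])
        waves = [waves_to_equilibrium(t, tolerance) for tolerance in (0.01, 0.02, 0.05, 0.2)]
        assert waves == sorted(waves, reverse=True)

    def test_seed_composition_start_option(self):
        t = tm([[0.8, 0.2], [0.3, 0.7]])
        pi = stationary_distribution(t)
        assert waves_to_equilibrium(t, start=pi) == 1
        assert waves_to_equilibrium(t, start=[0.0, 1.0]) == 7


class TestRunningComposition:
    def test_constant_stream_is_flat(self):
        records = make_records([{"education": "university"} for _ in range(30)])
        curves = running_composition(records, np.full(30, 3.0), "education", step=10)
        assert (curves["rdsii_estimate"] == 1.0).all()
        assert (curves["sample_proportion"] == 1.0).all()

    def test_midpoint_switch_crosses_half(self):
        rows = [{"education": "a"} for _ in range(20)] + [
            {"education": "b"} for _ in range(20)
        ]
        records = make_records(rows)
        curves = running_composition(records, np.full(40, 2.0), "education", step=10)
        a = curves[curves["category"] == "a"].set_index("sample_size")["rdsii_estimate"]
        assert a.loc[20] == 1.0
        assert a.loc[40] == 0.5

    def test_final_point_equals_full_sample_estimate(self, injected_run):
        _, fab = injected_run
        table = fab.table[~fab.table["is_seed"]]
        degrees = np.asarray(
            [5.0 + (i % 7) for i in range(len(table))]
        )
        curves = running_composition(table, degrees, "group", step=17)
        final = curves[curves["sample_size"] == len(table)]
        order = table.sort_values(["timestamp", "id"], kind="mergesort")
        d_sorted = degrees[table.reset_index(drop=True).sort_values(
            ["timestamp", "id"], kind="mergesort").index]
        full = rdsii_proportion(order["group"], d_sorted).proportions
        for _, row in final.iterrows():
            assert row["rdsii_estimate"] == full[row["category"]]


class TestLastKComparison:
    def test_repeated_block_gives_zero_difference(self):
        block = [{"education": e, "reported_network_size": d}
                 for e, d in [("a", 1), ("a", 2), ("b", 4), ("b", 8)]]
        records = make_records(block * 10)
        degrees = records["reported_network_size"].to_numpy(float)
        diff = last_k_comparison(records, degrees, ["education"], k=8)
        assert diff["education"] == pytest.approx(0.0, abs=1e-12)

    def test_two_window_hand_computation(self):
        rows = [
            {"education": "a", "reported_network_size": 1},
            {"education": "b", "reported_network_size": 2},
            {"education": "a", "reported_network_size": 4},
            {"education": "b", "reported_network_size": 4},
        ]
        records = make_records(rows)
        degrees = records["reported_network_size"].to_numpy(float)
        diff = last_k_comparison(records, degrees, ["education"], k=2)
        # full: p_a = (1 + 1/4)/(1 + 1/2 + 1/4 + 1/4) = 0.625
        # last 2: p_a = (1/4)/(1/4 + 1/4) = 0.5
        assert diff["education"] == pytest.approx(0.125)

    def test_numeric_variables_compare_weighted_means(self):
        rows = [{"stated_age": a, "reported_network_size": 1} for a in (20, 20, 30, 30)]
        records = make_records(rows)
        d = np.ones(4)
        diff = last_k_comparison(records, d, [], numeric_variables=["stated_age"], k=2)
        assert diff["stated_age"] == pytest.approx(5.0)  # |25 - 30|

    def test_shrinks_with_sample_size(self):
        """Monte-Carlo: for i.i.d.-like streams the last-k discrepancy
        shrinks as the sample grows."""
        rng = np.random.default_rng(5)

        def mean_diff(n, reps=12):
            out = []
            for _ in range(reps):
                records = make_records(
                    [{"education": rng.choice(["a", "b"]),
                      "reported_network_size": int(rng.integers(1, 9))}
                     for _ in range(n)]
                )
                d = records["reported_network_size"].to_numpy(float)
                out.append(
                    last_k_comparison(records, d, ["education"], k=n // 4)["education"]
                )
            return np.mean(out)

        assert mean_diff(800) < mean_diff(80)

    def test_requires_more_than_k_records(self):
        records = make_records([{} for _ in range(5)])
        with pytest.raises(ValueError, match="more than k"):
            last_k_comparison(records, np.ones(5), ["education"], k=5)


class TestWaveStats:
    def test_isolated_seeds(self):
        forest = RecruitmentForest(
            parent={i: None for i in range(20)},
            timestamp={i: float(i % 3) for i in range(20)},
        )
        stats = wave_stats(forest, wave_threshold=5)
        assert stats["n_chains"] == 20
        assert stats["max_wave"] == 0
        assert stats["n_chains_exceeding_threshold"] == 0
        assert stats["cumulative_submissions_by_day"][2] == 20

    def test_single_path_max_wave(self):
        parent = {i: (None if i == 0 else i - 1) for i in range(25)}
        forest = RecruitmentForest(parent=parent, timestamp={i: float(i) for i in parent})
        assert wave_stats(forest)["max_wave"] == 24

    def test_agrees_with_brute_force_traversal(self, injected_run):
        forest, _ = injected_run
        stats = wave_stats(forest, wave_threshold=3)
        # independent oracle: recursive descent from each seed
        def descend(node, depth, children):
            sizes, max_w = 1, depth
            for child in children[node]:
                s, w = descend(child, depth + 1, children)
                sizes += s
                max_w = max(max_w, w)
            return sizes, max_w

        children = forest.children()
        for seed in forest.seeds:
            size, max_w = descend(seed, 0, children)
            assert stats["chain_sizes"][seed] == size
            assert stats["chain_max_wave"][seed] == max_w
        assert stats["n_chains_exceeding_threshold"] == sum(
            1 for s in forest.seeds if descend(s, 0, children)[1] > 3
        )


class TestCrossGroupRecruitment:
    def test_within_group_only(self):
        forest, records = chain_records(["X", "X", "X"])
        records = records.rename(columns={"cat": "province"})
        assert cross_group_recruitment_fraction(forest, records, "province") == 0.0

    def test_alternating_path(self):
        forest, records = chain_records(["X", "Y", "X"])
        records = records.rename(columns={"cat": "province"})
        assert cross_group_recruitment_fraction(forest, records, "province") == 1.0

    def test_direct_count(self):
        parent = {"s": None}
        provinces = {"s": "X"}
        for i in range(10):
            parent[i] = "s"
            provinces[i] = "Y" if i < 3 else "X"
        forest = RecruitmentForest(parent=parent)
        records = pd.DataFrame({"id": list(parent), "province": [provinces[k] for k in parent]})
        assert cross_group_recruitment_fraction(forest, records, "province") == pytest.approx(0.3)

    def test_no_events_raises(self):
        forest = RecruitmentForest(parent={"s": None})
        records = pd.DataFrame({"id": ["s"], "province": ["X"]})
        with pytest.raises(ValueError, match="no recruitment events"):
            cross_group_recruitment_fraction(forest, records, "province")


class TestEmpiricalEquilibrium:
    def test_higher_homophily_slows_composition_convergence(self):
        """Over 30 replicates, the first wave at which the cumulative
        sample composition settles near its final value comes later when
        recruitment is strongly homophilous."""
        from webrds import PopulationConfig, TraitSpec, generate_population

        def empirical_waves(h, seed):
            cfg = PopulationConfig(
                n_individuals=600,
                degree_model="poisson",
                degree_params={"mean": 8.0},
                trait_specs=[TraitSpec("t", ["x", "y"], [0.5, 0.5], h)],
                province_distribution={"p": 1.0},
            )
            pop = generate_population(cfg, seed)
            sim = SimulationConfig(
                n_seeds=4,
                participation_probability=0.6,
                rng_seed=seed,
                seed_selection="by_trait",
                seed_trait=("t", "x"),
            )
            forest = simulate_recruitment(pop, sim)
            values = pop.attributes["t"]
            waves = [forest.wave[v] for v in forest.nodes]
            max_w = max(waves)
            cats = pd.DataFrame(
                {"w": waves, "x": [values[forest.person[v]] == "x" for v in forest.nodes]}
            )
            final = cats["x"].mean()
            for w in range(max_w + 1):
                prop = cats[cats["w"] <= w]["x"].mean()
                if final > 0 and abs(prop - final) / final < 0.05:
                    return w
            return max_w

        low = np.mean([empirical_waves(0.05, s) for s in range(30)])
        high = np.mean([empirical_waves(0.9, s) for s in range(30)])
        assert np.isfinite(low) and np.isfinite(high)
        assert high > low
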