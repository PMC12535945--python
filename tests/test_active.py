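import math

import numpy as np
import pytest

from bmlp.active import (
    Experiment,
    LearningTrace,
    PredictionMatrix,
    TraceStep,
    VersionSpace,
    aggregate_complexity_curves,
    empirical_phi,
    expected_cost,
    minimal_reduction_ratio,
    outcome_probability,
    prediction_matrix,
    prune,
    run_active_learning,
    run_random_baseline,
    sample_complexity_ratios,
    select_experiment,
)
from bmlp.engine import forward_chain_oracle
from bmlp.network import reaction_mask
from bmlp.scoring import Hypothesis, entropy_term


def exp(i, cost=0.0, deleted=(), nutrients=()):
    return Experiment(f"e{i}", frozenset(deleted), frozenset(nutrients), cost)


# ---------------------------------------------------------------------------
# Prediction matrix on the 5-metabolite fixture
# ---------------------------------------------------------------------------


class TestPredictionMatrix:
    @pytest.fixture
    def setup(self, pathway_fixture):
        fx = pathway_fixture
        hypotheses = [
            Hypothesis.empty(),
            Hypothesis.from_facts([("g3", "Rx")]),
            Hypothesis.from_facts([("g4", "Rx")]),
        ]
        experiments = [
            exp(0),
            exp(1, deleted={"g3"}),
            exp(2, deleted={"g1"}),
            exp(3, deleted={"g1", "g2"}),
            exp(4, deleted={"g4"}),
        ]
        pm = prediction_matrix(
            fx["network"], hypotheses, experiments, fx["base_medium"], fx["essential"]
        )
        return fx, hypotheses, experiments, pm

    def test_control_always_negative(self, setup):
        _, _, _, pm = setup
        assert not pm.values[:, 0].any()

    def test_hypothesis_gene_deletion_is_lethal(self, setup):
        _, hyps, _, pm = setup
        i = hyps.index(Hypothesis.from_facts([("g3", "Rx")]))
        assert pm.values[i, 1]  # deleting the supplied gene kills Rx

    def test_isoenzyme_single_deletion_not_lethal(self, setup):
        _, hyps, _, pm = setup
        i = hyps.index(Hypothesis.from_facts([("g3", "Rx")]))
        assert not pm.values[i, 2]

    def test_empty_hypothesis_row_all_zero(self, setup):
        # control cannot grow without any catalyst for Rx -> never an effect
        _, hyps, _, pm = setup
        assert not pm.values[hyps.index(Hypothesis.empty())].any()

    def test_matches_forward_chaining_oracle(self, setup):
        fx, hyps, experiments, pm = setup
        net, essential = fx["network"], fx["essential"]
        for i, h in enumerate(hyps):
            for j, t in enumerate(experiments):
                medium = fx["base_medium"] | t.nutrients
                mut = forward_chain_oracle(net, medium, reaction_mask(net, h, t.deleted))
                ctl = forward_chain_oracle(net, medium, reaction_mask(net, h, frozenset()))
                expected = any(m not in mut for m in essential) and all(
                    m in ctl for m in essential
                )
                assert pm.values[i, j] == expected, (h.id, t.id)


# ---------------------------------------------------------------------------
# Selection primitives
# ---------------------------------------------------------------------------


class TestOutcomeProbability:
    def test_all_positive(self):
        assert outcome_probability(np.ones(3, bool), np.array([0.2, 0.3, 0.5])) == 1.0

    def test_uniform_split(self):
        assert outcome_probability(np.array([1, 0], bool), np.array([0.5, 0.5])) == 0.5

    def test_skewed(self):
        p = outcome_probability(np.array([0, 1], bool), np.array([2 / 3, 1 / 3]))
        assert p == pytest.approx(1 / 3)

    def test_misaligned(self):
        with pytest.raises(ValueError):
            outcome_probability(np.ones(2, bool), np.array([1.0]))


class TestExpectedCost:
    def test_substitution(self):
        t, other = exp(0, cost=1.0), exp(1, cost=1.0)
        assert expected_cost(t, [t, other], (0.5, 0.5, 0.5)) == pytest.approx(1.5)

    def test_non_discriminative_is_worse(self):
        t, other = exp(0, cost=1.0), exp(1, cost=1.0)
        assert expected_cost(t, [t, other], (1.0, 0.0, 1.0)) == pytest.approx(2.0)

    def test_last_experiment_is_pure_cost(self):
        t = exp(0, cost=3.25)
        assert expected_cost(t, [t], (1.0, 1.0, 0.5)) == pytest.approx(3.25)


class TestMinimalReductionRatio:
    def test_two_of_five(self):
        assert minimal_reduction_ratio(np.array([1, 1, 0, 0, 0], bool)) == pytest.approx(0.4)

    def test_unanimous(self):
        assert minimal_reduction_ratio(np.ones(4, bool)) == 0.0

    def test_even_split(self):
        assert minimal_reduction_ratio(np.array([1, 1, 1, 0, 0, 0], bool)) == 0.5

    def test_empty_alive_set(self):
        with pytest.raises(ValueError):
            minimal_reduction_ratio(np.array([], bool))


class TestPrune:
    def _vs(self, n=4):
        return VersionSpace.full([Hypothesis.from_facts([(f"g{i}", "R")]) for i in range(n)])

    def test_keeps_matching(self):
        V = prune(self._vs(), np.array([1, 0, 1, 0], bool), 1)
        assert V.alive.tolist() == [True, False, True, False]

    def test_label_matching_all_is_noop(self):
        V0 = self._vs()
        V = prune(V0, np.ones(4, bool), 1)
        assert V.alive.all() and V.hypotheses == V0.hypotheses

    def test_idempotent(self):
        col = np.array([1, 0, 1, 1], bool)
        V1 = prune(self._vs(), col, 0)
        V2 = prune(V1, col, 0)
        assert np.array_equal(V1.alive, V2.alive)


def _random_state(rng, n_h=6, n_t=8, uniform_cost=None):
    hyps = [Hypothesis.empty()] + [
        Hypothesis.from_facts([(f"g{i}", "R")]) for i in range(n_h - 1)
    ]
    costs = (
        np.full(n_t, uniform_cost)
        if uniform_cost is not None
        else rng.uniform(0, 5, size=n_t)
    )
    exps = [exp(j, cost=float(costs[j])) for j in range(n_t)]
    values = rng.random((n_h, n_t)) < 0.4
    pm = PredictionMatrix(values, hyps, exps)
    alive = rng.random(n_h) < 0.8
    if not alive.any():
        alive[0] = True
    w = rng.random(int(alive.sum()))
    posts = w / w.sum()
    return pm, alive, posts


class TestSelectExperiment:
    def _naive(self, pm, alive, posts, labelled, budget, order):
        """Loop-based reference built from the spec-level primitives."""
        remaining = [t for t in pm.experiments if t.id not in labelled]
        rank = {j: r for r, j in enumerate(order)}
        best = None
        for j, t in enumerate(pm.experiments):
            if t.id in labelled or t.cost > budget:
                continue
            col = pm.values[alive, j]
            p = outcome_probability(col, posts)
            ec = expected_cost(t, remaining, (entropy_term(posts[col]), entropy_term(posts[~col]), p))
            key = (ec, rank[j])
            if best is None or key < best[0]:
                best = (key, j)
        return None if best is None else best[1]

    def test_matches_naive_reference(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pm, alive, posts = _random_state(rng)
            order = list(rng.permutation(len(pm.experiments)))
            labelled = {t.id for t in pm.experiments if rng.random() < 0.3}
            budget = float(rng.uniform(0, 6))
            got = select_experiment(pm, alive, posts, labelled, budget, order)
            want = self._naive(pm, alive, posts, labelled, budget, order)
            if want is None:
                assert got is None
            else:
                # equal up to expected-cost ties, which both break by order
                assert got == want or math.isclose(
                    self._ec_of(pm, alive, posts, labelled, got),
                    self._ec_of(pm, alive, posts, labelled, want),
                    rel_tol=1e-9,
                    abs_tol=1e-12,
                )

    def _ec_of(self, pm, alive, posts, labelled, j):
        remaining = [t for t in pm.experiments if t.id not in labelled]
        col = pm.values[alive, j]
        p = outcome_probability(col, posts)
        return expected_cost(
            pm.experiments[j],
            remaining,
            (entropy_term(posts[col]), entropy_term(posts[~col]), p),
        )

    def test_lower_ec_wins(self):
        hyps = [Hypothesis.empty(), Hypothesis.from_facts([("g", "R")])]
        exps = [exp(0, cost=1.0), exp(1, cost=1.0)]
        # e0 splits 1/1 (discriminative), e1 unanimous positive
        pm = PredictionMatrix(np.array([[1, 1], [0, 1]], bool), hyps, exps)
        alive = np.ones(2, bool)
        posts = np.array([0.5, 0.5])
        j = select_experiment(pm, alive, posts, set(), math.inf, [1, 0])
        assert j == 0

    def test_all_over_budget(self):
        rng = np.random.default_rng(3)
        pm, alive, posts = _random_state(rng, uniform_cost=5.0)
        assert select_experiment(pm, alive, posts, set(), 4.99, list(range(8))) is None

    def test_tie_broken_by_shuffled_order(self):
        hyps = [Hypothesis.empty(), Hypothesis.from_facts([("g", "R")])]
        exps = [exp(0, cost=1.0), exp(1, cost=1.0)]
        pm = PredictionMatrix(np.array([[1, 1], [0, 0]], bool), hyps, exps)  # identical columns
        posts = np.array([0.5, 0.5])
        assert select_experiment(pm, np.ones(2, bool), posts, set(), math.inf, [1, 0]) == 1
        assert select_experiment(pm, np.ones(2, bool), posts, set(), math.inf, [0, 1]) == 0

    def test_uniform_costs_reduce_to_entropy_selection(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            pm, alive, posts = _random_state(rng, uniform_cost=2.0)
            order = list(rng.permutation(len(pm.experiments)))
            got = select_experiment(pm, alive, posts, set(), math.inf, order)
            scores = []
            for j in range(len(pm.experiments)):
                col = pm.values[alive, j]
                p = outcome_probability(col, posts)
                scores.append(p * entropy_term(posts[col]) + (1 - p) * entropy_term(posts[~col]))
            best = min(scores[j] for j in range(len(scores)))
            assert scores[got] == pytest.approx(best, abs=1e-12)


# ---------------------------------------------------------------------------
# Learning loops
# ---------------------------------------------------------------------------


def _fixture_task(pathway_fixture):
    fx = pathway_fixture
    hyps = [Hypothesis.empty()] + [
        Hypothesis.from_facts([(g, "Rx")]) for g in fx["network"].genes
    ]
    exps = [exp(0)] + [exp(i + 1, deleted={g}) for i, g in enumerate(fx["network"].genes)]
    hstar = Hypothesis.from_facts(fx["true_facts"])
    pm = prediction_matrix(fx["network"], hyps, exps, fx["base_medium"], fx["essential"])
    truth = {t.id: int(pm.values[hyps.index(hstar), j]) for j, t in enumerate(exps)}
    return fx, hyps, exps, hstar, (lambda t: truth[t.id])


class TestLearningLoops:
    def test_single_hypothesis_terminates_immediately(self, pathway_fixture):
        fx = pathway_fixture
        h = Hypothesis.from_facts(fx["true_facts"])
        trace = run_active_learning(
            fx["network"], [h], [exp(0)], lambda t: 0, fx["base_medium"], fx["essential"]
        )
        assert trace.steps == [] and trace.final_hypothesis == h and trace.converged

    def test_soundness_on_fixture(self, pathway_fixture):
        fx, hyps, exps, hstar, oracle = _fixture_task(pathway_fixture)
        for seed in range(5):
            trace = run_active_learning(
                fx["network"], hyps, exps, oracle, fx["base_medium"], fx["essential"], seed=seed
            )
            assert trace.final_hypothesis == hstar
            assert trace.converged

    def test_zero_budget_returns_smallest_hypothesis(self, pathway_fixture):
        fx, hyps, _, _, oracle = _fixture_task(pathway_fixture)
        exps = [exp(i, cost=1.0 + i, deleted={g}) for i, g in enumerate(fx["network"].genes)]
        trace = run_active_learning(
            fx["network"], hyps, exps, oracle, fx["base_medium"], fx["essential"], budget=0.0
        )
        assert trace.steps == []
        assert trace.final_hypothesis == Hypothesis.empty()
        assert not trace.converged

    def test_random_baseline_deterministic_under_seed(self, pathway_fixture):
        fx, hyps, exps, hstar, oracle = _fixture_task(pathway_fixture)
        t1 = run_random_baseline(
            fx["network"], hyps, exps, oracle, fx["base_medium"], fx["essential"], seed=9
        )
        t2 = run_random_baseline(
            fx["network"], hyps, exps, oracle, fx["base_medium"], fx["essential"], seed=9
        )
        assert [s.experiment_id for s in t1.steps] == [s.experiment_id for s in t2.steps]
        assert t1.final_hypothesis == t2.final_hypothesis == hstar

    def test_version_space_non_increasing(self, pathway_fixture):
        fx, hyps, exps, _, oracle = _fixture_task(pathway_fixture)
        for runner in (run_active_learning, run_random_baseline):
            trace = runner(
                fx["network"], hyps, exps, oracle, fx["base_medium"], fx["essential"], seed=2
            )
            sizes = [len(hyps)] + [s.version_space_size for s in trace.steps]
            assert all(a >= b for a, b in zip(sizes, sizes[1:]))
            costs = [s.cumulative_cost for s in trace.steps]
            assert all(a <= b for a, b in zip(costs, costs[1:]))

    def test_oracle_failure_flags_aborted(self, pathway_fixture):
        fx, hyps, exps, _, _ = _fixture_task(pathway_fixture)

        def bad_oracle(t):
            raise RuntimeError("lab on fire")

        trace = run_active_learning(
            fx["network"], hyps, exps, bad_oracle, fx["base_medium"], fx["essential"]
        )
        assert trace.aborted


# ---------------------------------------------------------------------------
# Expected-cost recurrence oracle (heuristic is an approximation)
# ---------------------------------------------------------------------------


class TestExactRecurrenceAgreement:
    def _exact_ec(self, pm, alive_idx, t_idx_set):
        """Exhaustive evaluation of the optimal-expected-cost recurrence."""
        if len(alive_idx) <= 1 or not t_idx_set:
            return 0.0, None
        posts = np.full(len(alive_idx), 1.0 / len(alive_idx))
        best = (math.inf, None)
        for j in sorted(t_idx_set):
            col = pm.values[np.array(alive_idx), j]
            p = float(posts[col].sum())
            pos = tuple(a for a, c in zip(alive_idx, col) if c)
            neg = tuple(a for a, c in zip(alive_idx, col) if not c)
            rest = t_idx_set - {j}
            ec = (
                pm.experiments[j].cost
                + p * self._exact_ec(pm, pos, rest)[0]
                + (1 - p) * self._exact_ec(pm, neg, rest)[0]
            )
            if ec < best[0]:
                best = (ec, j)
        return best

    def test_heuristic_agreement_rate(self):
        rng = np.random.default_rng(17)
        agree = total = 0
        for _ in range(60):
            pm, _, _ = _random_state(rng, n_h=4, n_t=4)
            alive = np.ones(4, bool)
            posts = np.full(4, 0.25)
            order = list(range(4))
            chosen = select_experiment(pm, alive, posts, set(), math.inf, order)
            _, exact = self._exact_ec(pm, tuple(range(4)), frozenset(range(4)))
            if exact is not None:
                total += 1
                agree += chosen == exact
        # the heuristic approximates the recurrence; it should agree on a
        # clear majority of tiny instances but exactness is not required
        assert total > 0 and agree / total >= 0.5


# ---------------------------------------------------------------------------
# Sample-complexity diagnostics
# ---------------------------------------------------------------------------


def _trace(strategy, accuracies, ratios=None):
    tr = LearningTrace(strategy=strategy, seed=0)
    ratios = ratios or [0.25] * len(accuracies)
    for s, (acc, ratio) in enumerate(zip(accuracies, ratios), start=1):
        tr.steps.append(
            TraceStep(s, f"e{s}", 0.0, 0, 1, ratio, "h", 0.0, 0.0, acc)
        )
    return tr


class TestSampleComplexityRatios:
    def test_identical_traces_with_zero_phi_give_equal_curves(self):
        tr = _trace("active", [0.6, 0.9, 1.0])
        df = sample_complexity_ratios(tr, _trace("random", [0.6, 0.9, 1.0]), phi=0.0)
        assert df["ratio_active"].tolist() == pytest.approx(df["ratio_passive"].tolist())

    def test_substitution_example(self):
        active = _trace("active", [0.5, 0.8, 0.9])
        passive = _trace("random", [0.5] * 24 + [0.9])
        df = sample_complexity_ratios(active, passive, phi=0.05)
        row = df[np.isclose(df["epsilon"], 0.1)].iloc[0]
        assert row["s_active"] == 3 and row["s_passive"] == 25
        assert row["ratio_active"] == pytest.approx(0.1 / 3, rel=1e-3)
        assert row["ratio_passive"] == pytest.approx(0.15 / 25, rel=1e-3)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="accuracy"):
            sample_complexity_ratios(LearningTrace("active", 0), _trace("random", [1.0]), 0.0)

    def test_empirical_phi(self):
        tr = _trace("active", [0.5, 1.0], ratios=[0.4, 0.1])
        assert empirical_phi(tr) == 0.1

    def test_aggregate_curves_shape(self):
        actives = [_trace("active", [0.7, 1.0]), _trace("active", [0.8, 1.0])]
        passives = [_trace("random", [0.6, 0.9, 1.0])]
        df = aggregate_complexity_curves(actives, passives)
        assert {"epsilon", "s_active", "s_passive", "ratio_active", "ratio_passive"} <= set(df.columns)
        assert (df["epsilon"] >= 0).all()
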