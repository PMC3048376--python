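"""Transfer functions, gate/node evaluation, simulation, MSE scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cflnet.data import Dataset, ExperimentalCondition
from cflnet.model import CFLModel
from cflnet.network import PKN, CandidateGate, expand
from cflnet.simulate import (SimConfig, SimulationResult, compute_mse,
                             eval_gate, eval_node, simulate)
from cflnet.transfer import (ALPHABET_SIZE, HILL_LIBRARY, LINEAR_LIBRARY,
                             TransferFunctionSpec, apply_edge_tf,
                             gate_sensitivity, hill_tf, linear_tf)
from .conftest import boolean_truth_table, random_acyclic_pkn


class TestHill:
    @pytest.mark.parametrize("n,k", [(1.0, 0.5), (3.0, 0.2), (1.01, 68.5098)])
    def test_anchors(self, n, k):
        assert hill_tf(0.0, n, k) == 0.0
        assert hill_tf(1.0, n, k) == pytest.approx(1.0)

    def test_worked_value(self):
        # x^n (1+k^n)/(x^n+k^n) at x=0.5, n=3, k=0.5
        assert hill_tf(0.5, 3, 0.5) == pytest.approx(0.5625)

    def test_near_linear_library_member(self):
        # the (n=1.01, k=68.5098) member behaves linearly on [0,1]
        assert hill_tf(0.5, 1.01, 68.5098) == pytest.approx(0.5, abs=0.005)
        for x in np.linspace(0, 1, 11):
            assert hill_tf(x, 1.01, 68.5098) == pytest.approx(x, abs=0.005)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1),
           st.floats(1, 5), st.floats(0.01, 2))
    def test_monotone(self, x1, x2, n, k):
        lo, hi = sorted([x1, x2])
        assert hill_tf(lo, n, k) <= hill_tf(hi, n, k) + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill_tf(1.5, 3, 0.5)
        with pytest.raises(ValueError):
            hill_tf(0.5, 0.5, 0.5)  # n < 1


class TestLinearAndEdges:
    def test_linear(self):
        assert linear_tf(1.0, 0.5) == 0.5
        assert linear_tf(0.5, 0.8) == pytest.approx(0.4)
        assert linear_tf(0.0, 0.3) == 0.0
        with pytest.raises(ValueError):
            linear_tf(0.5, 1.2)

    def test_inhibitory_inversion(self):
        spec = TransferFunctionSpec("hill", n=3.0, k=0.5)
        assert apply_edge_tf(0.0, spec, -1) == pytest.approx(1.0)
        assert apply_edge_tf(1.0, spec, -1) == pytest.approx(0.0)
        assert apply_edge_tf(0.8, spec, -1) == pytest.approx(0.0958, abs=1e-4)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_inversion_is_antitone(self, x1, x2):
        spec = TransferFunctionSpec("hill", n=3.0, k=0.4)
        lo, hi = sorted([x1, x2])
        assert apply_edge_tf(lo, spec, -1) >= apply_edge_tf(hi, spec, -1) - 1e-12

    def test_absent_spec_is_usage_error(self):
        with pytest.raises(ValueError, match="absent"):
            apply_edge_tf(0.5, None, 1)


class TestGateAndNode:
    hill = TransferFunctionSpec("hill", n=3.0, k=0.5)

    def gate2(self):
        return CandidateGate("C", (("A", 1), ("B", -1)))

    def test_one_input_gate_is_degenerate_and(self):
        g = CandidateGate("C", (("A", 1),))
        for mode in ("minmax", "prodsum"):
            assert eval_gate(g, [self.hill], {"A": 0.5}, mode) == \
                pytest.approx(0.5625)

    def test_two_input_and_minmax_and_prodsum(self):
        vals = {"A": 0.5, "B": 0.8}
        got_min = eval_gate(self.gate2(), [self.hill, self.hill], vals, "minmax")
        got_prod = eval_gate(self.gate2(), [self.hill, self.hill], vals, "prodsum")
        assert got_min == pytest.approx(0.0958, abs=1e-4)   # min(0.5625, 0.0958)
        assert got_prod == pytest.approx(0.5625 * 0.0958, abs=1e-4)

    def test_or_combination(self):
        g1 = CandidateGate("C", (("A", 1),))
        g2 = CandidateGate("C", (("B", 1),))
        lin6, lin7 = LINEAR_LIBRARY[5], LINEAR_LIBRARY[6]
        vals = {"A": 1.0, "B": 1.0}
        gws = [(g1, [lin6]), (g2, [lin7])]
        assert eval_node("C", gws, vals, "minmax") == pytest.approx(0.7)
        assert eval_node("C", gws, vals, "prodsum") == pytest.approx(1.0)  # capped
        assert eval_node("C", [], vals) == 0.0

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_operator_orderings(self, a, b):
        """prodsum AND <= minmax AND <= each input; OR the reverse."""
        vals = {"A": a, "B": b}
        g = self.gate2()
        specs = [self.hill, self.hill]
        v1 = apply_edge_tf(a, self.hill, 1)
        v2 = apply_edge_tf(b, self.hill, -1)
        and_min = eval_gate(g, specs, vals, "minmax")
        and_prod = eval_gate(g, specs, vals, "prodsum")
        assert and_prod <= and_min + 1e-12
        assert and_min <= min(v1, v2) + 1e-12


def _chain_model():
    pkn = PKN(frozenset({"S", "A", "B"}),
              frozenset({("S", "A", 1), ("A", "B", 1)}),
              stimuli=frozenset({"S"}), measured=frozenset({"A", "B"}))
    hs = expand(pkn)
    return CFLModel(hs, {
        "A|0|S": TransferFunctionSpec("linear", slope=0.5),
        "B|0|A": TransferFunctionSpec("hill", n=1.01, k=68.5098),
    })


class TestSimulate:
    def test_zero_stimuli_zero_everywhere(self, toy_truth):
        cond = ExperimentalCondition({"TGFA": 0.0, "TNFA": 0.0}, {})
        res = simulate(toy_truth, cond)
        assert res.converged.all()
        # no basal activity except constitutive inhibition-only targets
        for node in ("AKT", "ERK", "JNK", "P38", "MEK", "PI3K"):
            assert res.value(node) == pytest.approx(0.0, abs=1e-4)

    def test_chain_composition(self):
        model = _chain_model()
        res = simulate(model, ExperimentalCondition({"S": 1.0}, {}))
        assert res.value("A") == pytest.approx(0.5)
        assert res.value("B") == pytest.approx(0.5, abs=0.005)

    def test_inhibitor_clamps_to_zero(self, toy_truth):
        cond = ExperimentalCondition({"TGFA": 1.0}, {"PI3K": 1, "MEK": 0})
        res = simulate(toy_truth, cond)
        assert res.value("PI3K") == 0.0
        assert res.value("AKT") == pytest.approx(0.0, abs=1e-4)
        assert res.value("ERK") > 0.9  # MEK branch unaffected

    def test_converged_state_is_fixed_point(self, toy_truth, toy_dataset):
        cfg = SimConfig()
        res = simulate(toy_truth, toy_dataset.conditions(), cfg)
        assert res.converged.all()
        # one further synchronous sweep changes nothing beyond tol
        res2 = simulate(toy_truth, toy_dataset.conditions(),
                        SimConfig(max_iter=int(res.iterations.max()) + 1))
        assert np.abs(res.x - res2.x).max() < cfg.tol

    @pytest.mark.parametrize("mode", ["minmax", "prodsum", "boolean"])
    def test_values_stay_in_unit_interval(self, toy_hs, toy_dataset, mode):
        rng = np.random.default_rng(5)
        from cflnet.training import decode
        for _ in range(10):
            genome = rng.integers(0, ALPHABET_SIZE, size=toy_hs.h)
            model = decode(genome, toy_hs)
            res = simulate(model, toy_dataset.conditions(),
                           SimConfig(operator_mode=mode))
            assert res.x.min() >= 0.0 and res.x.max() <= 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_boolean_mode_matches_truth_table_oracle(self, seed):
        """All-1-input-gate models in boolean mode reproduce the classical
        Boolean steady state (exhaustive truth table on small DAGs)."""
        rng = np.random.default_rng(100 + seed)
        pkn = random_acyclic_pkn(rng, n_nodes=7, n_designated=4)
        hs = expand(pkn, "all_pairs")
        assignment = {}
        for output, gates in hs.gates.items():
            for gi, g in enumerate(gates):
                for sid in hs.gate_slots(output, gi):
                    lib = hs.slot_library[sid]
                    assignment[sid] = (HILL_LIBRARY[5] if lib == "hill"
                                       else LINEAR_LIBRARY[7]) \
                        if g.arity == 1 else None
        model = CFLModel(hs, assignment)
        table = boolean_truth_table(pkn)
        stimuli = sorted(pkn.stimuli)
        for bits, expected in table.items():
            cond = ExperimentalCondition(
                {s: float(b) for s, b in zip(stimuli, bits)}, {})
            res = simulate(model, cond, SimConfig(operator_mode="boolean"))
            assert res.converged.all()
            for node, val in expected.items():
                if node in pkn.stimuli:
                    continue
                assert res.value(node) == float(val), (bits, node)


def _result(preds, nodes=("A", "B")):
    x = np.array(preds, dtype=float).reshape(len(nodes), -1)
    c = x.shape[1]
    return SimulationResult(tuple(nodes), x, np.ones(c, bool), np.ones(c, int))


def _obs(values, nodes=("A", "B")):
    frame = pd.DataFrame({n: [v] for n, v in zip(nodes, values)})
    return Dataset(pd.DataFrame({"S": [1.0]}), pd.DataFrame(index=[0]), frame)


class TestMse:
    def test_printed_toy_comparison(self):
        """Boolean predictions (1,1) against graded observations (0.32,
        0.19) score 0.56; omitting the branch, (0,0) scores 0.07."""
        assert compute_mse(_result([1.0, 1.0]), _obs([0.32, 0.19])) == \
            pytest.approx(0.56, abs=0.005)
        assert compute_mse(_result([0.0, 0.0]), _obs([0.32, 0.19])) == \
            pytest.approx(0.07, abs=0.005)

    def test_exact_match_is_zero(self):
        assert compute_mse(_result([0.3, 0.7]), _obs([0.3, 0.7])) == 0.0

    def test_missing_cells_excluded(self):
        ds = _obs([0.5, np.nan])
        assert compute_mse(_result([1.0, 0.0]), ds) == pytest.approx(0.25)

    def test_no_cells_is_error(self):
        ds = _obs([np.nan, np.nan])
        with pytest.raises(ValueError, match="undefined"):
            compute_mse(_result([1.0, 0.0]), ds)

    def test_nonconverged_penalty(self):
        res = _result([0.3, 0.7])
        res.converged[:] = False
        assert compute_mse(res, _obs([0.3, 0.7])) == pytest.approx(1.0)

    def test_signal_subset_restriction(self):
        res = _result([1.0, 0.0])
        ds = _obs([0.5, 0.5])
        assert compute_mse(res, ds, signals=["A"]) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        n_cond, n_sig = 4, 3
        pred = rng.random((n_sig, n_cond))
        obs = rng.random((n_cond, n_sig))
        obs[rng.random(obs.shape) < 0.25] = np.nan
        nodes = tuple(f"M{i}" for i in range(n_sig))
        res = SimulationResult(nodes, pred, np.ones(n_cond, bool),
                               np.ones(n_cond, int))
        ds = Dataset(pd.DataFrame({"S": np.linspace(0, 1, n_cond)}),
                     pd.DataFrame(index=range(n_cond)),
                     pd.DataFrame(obs, columns=list(nodes)))
        total, count = 0.0, 0
        for i, node in enumerate(nodes):
            for j in range(n_cond):
                if not np.isnan(obs[j, i]):
                    total += (pred[i, j] - obs[j, i]) ** 2
                    count += 1
        assert compute_mse(res, ds) == pytest.approx(total / count)


class TestSensitivity:
    def test_formulas(self):
        assert gate_sensitivity(TransferFunctionSpec("hill", n=3.0, k=0.3)) \
            == pytest.approx(0.7)
        assert gate_sensitivity(TransferFunctionSpec("linear", slope=0.6)) \
            == pytest.approx(0.3)
        assert gate_sensitivity(TransferFunctionSpec("hill", n=3.0, k=1.0)) \
            == pytest.approx(0.0)

    def test_k_above_one_floored(self):
        assert gate_sensitivity(HILL_LIBRARY[1]) == 0.0
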