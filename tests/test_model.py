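"""Branch training, gate selection rule, and late fusion."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stresscare.errors import ConfigurationError, ValidationError
from stresscare.model import (
    BranchSpec,
    GatedEnsemble,
    late_fuse,
    load_branch_registry,
    select_branches,
    train_branch,
    train_gate,
)


def _separable_table(n=60, seed=0, n_features=4):
    """Two linearly separable classes with meta columns attached."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_features))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y == 1, 5.0, -5.0)
    df = pd.DataFrame(X, columns=[f"EDA__f{i}" for i in range(n_features)])
    df["subject_id"] = "s"
    df["segment_start_s"] = np.arange(n) * 8.0
    df["label"] = y
    df["degenerate_count"] = 0
    return df


WB2 = BranchSpec("WB2", "wrist", ("sweat", "EDA", "BVP"))


class TestRegistry:
    def test_wrist_branches(self):
        reg = load_branch_registry()
        assert reg["wrist"]["WB1"] == ["EDA", "BVP", "TEMP"]
        assert reg["wrist"]["WB2"] == ["sweat", "EDA", "BVP"]
        assert reg["wrist"]["WB3"] == ["EDA", "BVP"]

    def test_chest_registry_reproduces_published_rows(self):
        reg = load_branch_registry()["chest"]
        assert len(reg) == 28
        assert reg["CB1"] == ["ECG", "RESP", "EMG", "EDA", "TEMP"]
        assert reg["CB28"] == ["sweat", "RESP"]
        # duplicates are reproduced verbatim
        assert reg["CB3"] == reg["CB4"]
        assert reg["CB10"] == reg["CB11"]


class TestTrainBranch:
    @pytest.mark.parametrize(
        "backend",
        ["decision_tree", "random_forest", "support_vector_machine", "gradient_boosting"],
    )
    def test_probabilities_sum_to_one(self, backend):
        table = _separable_table()
        model = train_branch(WB2, backend, table, seed=0)
        proba = model.predict_proba(table)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_separable_data_tree_training_accuracy(self):
        table = _separable_table()
        model = train_branch(WB2, "decision_tree", table, seed=0)
        assert np.mean(model.predict(table) == table["label"].to_numpy()) == 1.0

    def test_same_seed_identical_predictions(self):
        table = _separable_table()
        probe = _separable_table(seed=9)
        p1 = train_branch(WB2, "random_forest", table, seed=5).predict_proba(probe)
        p2 = train_branch(WB2, "random_forest", table, seed=5).predict_proba(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_unknown_backend_rejected(self):
        with pytest.raises(ConfigurationError):
            train_branch(WB2, "neural_net", _separable_table(), seed=0)

    def test_single_class_rejected(self):
        table = _separable_table()
        table["label"] = 0
        with pytest.raises(ValidationError):
            train_branch(WB2, "decision_tree", table, seed=0)


class TestGate:
    def test_probability_vector_length_and_sum(self):
        table = _separable_table(n=90)
        sup = table["label"].to_numpy() % 3
        sup[:3] = [0, 1, 2]  # all three branches appear
        gate = train_gate(table, sup, ["WB1", "WB2", "WB3"], "random_forest", seed=0)
        proba = gate.predict_proba(table)
        assert proba.shape == (90, 3)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_constant_supervision_warns_and_pins_branch(self):
        table = _separable_table()
        sup = np.zeros(len(table), dtype=int)
        with pytest.warns(UserWarning, match="degenerate"):
            gate = train_gate(table, sup, ["WB1", "WB2", "WB3"], "decision_tree", seed=0)
        proba = gate.predict_proba(table)
        assert np.all(proba[:, 0] == 1.0)

    def test_same_seed_identical_gate(self):
        table = _separable_table(n=90)
        sup = np.arange(90) % 3
        g1 = train_gate(table, sup, ["A", "B", "C"], "random_forest", seed=2)
        g2 = train_gate(table, sup, ["A", "B", "C"], "random_forest", seed=2)
        np.testing.assert_array_equal(g1.predict_proba(table), g2.predict_proba(table))


class TestSelectBranches:
    def test_stated_endpoints(self):
        p = np.array([0.5, 0.3, 0.2])
        assert select_branches(p, 0.0) == [0]  # argmax only
        assert select_branches(p, 1.0) == [0, 1, 2]  # all branches

    def test_intermediate_threshold(self):
        # cutoff (1-0.5)*0.5 = 0.25 keeps 0.5 and 0.3
        assert select_branches(np.array([0.5, 0.3, 0.2]), 0.5) == [0, 1]

    def test_max_ties_all_selected_at_zero(self):
        assert select_branches(np.array([0.4, 0.4, 0.2]), 0.0) == [0, 1]

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValidationError):
            select_branches(np.array([1.0]), 1.3)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        probs=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=8),
        b1=st.floats(min_value=0.0, max_value=1.0),
        b2=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_selection_nested_in_threshold(self, probs, b1, b2):
        p = np.array(probs) / np.sum(probs)
        lo, hi = sorted((b1, b2))
        assert set(select_branches(p, lo)) <= set(select_branches(p, hi))
        assert int(np.argmax(p)) in select_branches(p, lo)


class TestLateFuse:
    def test_single_branch_identity(self):
        res = late_fuse([np.array([0.7, 0.3])], np.array([0, 1]))
        np.testing.assert_allclose(res.probabilities, [0.7, 0.3])
        assert res.predicted_class == 0

    def test_tie_breaks_to_lowest_class(self):
        res = late_fuse([np.array([1.0, 0.0]), np.array([0.0, 1.0])], np.array([0, 1]))
        np.testing.assert_allclose(res.probabilities, [0.5, 0.5])
        assert res.predicted_class == 0

    def test_hand_computed_mean(self):
        vecs = [np.array([0.6, 0.4]), np.array([0.9, 0.1]), np.array([0.3, 0.7])]
        res = late_fuse(vecs, np.array([0, 1]))
        np.testing.assert_allclose(res.probabilities, [0.6, 0.4])
        assert res.predicted_class == 0

    def test_fusing_copies_returns_vector_exactly(self):
        v = np.array([0.25, 0.35, 0.4])
        res = late_fuse([v, v, v], np.array([0, 1, 2]))
        np.testing.assert_array_equal(res.probabilities, v)

    def test_mismatched_class_lists_rejected(self):
        with pytest.raises(ValidationError):
            late_fuse([np.array([0.7, 0.3]), np.array([0.2, 0.3, 0.5])], np.array([0, 1]))

    def test_majority_voting_option(self):
        vecs = [np.array([0.6, 0.4]), np.array([0.4, 0.6]), np.array([0.3, 0.7])]
        res = late_fuse(vecs, np.array([0, 1]), method="majority")
        assert res.predicted_class == 1


def _toy_ensemble(b_branches=3, seed=0):
    specs = [BranchSpec(f"B{i}", "wrist", ("EDA",)) for i in range(b_branches)]
    table = _separable_table(n=90, seed=seed)
    models = {
        sp.branch_id: train_branch(sp, "decision_tree", table, seed=seed + i)
        for i, sp in enumerate(specs)
    }
    sup = np.arange(90) % b_branches
    gate = train_gate(table, sup, [sp.branch_id for sp in specs], "decision_tree", seed=seed)
    return GatedEnsemble(gate, models, np.array([0, 1])), table, specs


class TestGatedEnsemble:
    def test_b_one_equals_soft_voting(self):
        ens, table, specs = _toy_ensemble()
        fused = ens.predict(table, {sp.branch_id: table for sp in specs}, b=1.0)
        all_probas = [ens.branches[sp.branch_id].predict_proba(table) for sp in specs]
        expected = np.mean(all_probas, axis=0)
        got = np.vstack([r.probabilities for r in fused])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_b_zero_equals_argmax_branch(self):
        ens, table, specs = _toy_ensemble()
        tables = {sp.branch_id: table for sp in specs}
        gate_probs = ens.gate.predict_proba(table)
        fused = ens.predict(table, tables, b=0.0)
        for row, res in enumerate(fused):
            sel = select_branches(gate_probs[row], 0.0)
            if len(sel) == 1:
                solo = ens.branches[ens.gate.branch_ids[sel[0]]].predict_proba(table)[row]
                np.testing.assert_allclose(res.probabilities, solo, atol=1e-12)

    def test_branch_registration_order_irrelevant(self):
        ens, table, specs = _toy_ensemble()
        tables = {sp.branch_id: table for sp in specs}
        base = ens.predict(table, tables, b=1.0)
        ens.branches = dict(reversed(list(ens.branches.items())))
        flipped = ens.predict(table, tables, b=1.0)
        for a, b_ in zip(base, flipped):
            np.testing.assert_allclose(a.probabilities, b_.probabilities, atol=1e-12)

    def test_missing_branch_table_named(self):
        ens, table, specs = _toy_ensemble()
        tables = {sp.branch_id: table for sp in specs}
        del tables["B1"]
        with pytest.raises(ValidationError, match="B1"):
            ens.predict(table, tables, b=1.0)
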