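"""Abstraction operators: state merging, condensation, transitivity
resolution, binarization, noisy-OR compilation, complexity accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opscc_cdm import (
    BayesianNetwork,
    CPT,
    CondensationRule,
    DiscreteVariable,
    LearningConfig,
    ModelError,
    NoisyOrSpec,
    PatientDataset,
    StatePartition,
    apply_noisy_or,
    binarize_target,
    compile_noisy_or,
    complexity_report,
    condense_variables,
    count_table,
    enumerate_posterior,
    free_parameter_count,
    learn_cpts,
    merge_states,
    reference_models,
    resolve_transitivity,
)


def _nodal_net():
    """8-state nodal-status node feeding a binary treatment node."""
    n = DiscreteVariable(
        "nodal", tuple(f"N{i}" for i in range(8)), role="diagnostic"
    )
    t = DiscreteVariable("treat", ("yes", "no"), role="target")
    return BayesianNetwork([n, t], edges=[("nodal", "treat")])


def _nodal_data(n_rows=20, seed=0):
    rng = np.random.default_rng(seed)
    return PatientDataset(
        pd.DataFrame(
            {
                "nodal": rng.choice([f"N{i}" for i in range(8)], n_rows),
                "treat": rng.choice(["yes", "no"], n_rows),
            }
        )
    )


class TestMergeStates:
    def test_identity_partition_is_noop(self):
        net = _nodal_net()
        ds = _nodal_data()
        partition = StatePartition(
            "nodal",
            tuple((s,) for s in net.variable("nodal").states),
            net.variable("nodal").states,
        )
        merged, new_ds, step = merge_states(net, ds, partition, relearn=False)
        assert merged.variable("nodal").states == net.variable("nodal").states
        assert new_ds.df.equals(ds.df)
        assert np.allclose(merged.cpt("treat").table, net.cpt("treat").table)
        assert step.before_parameters == step.after_parameters

    def test_eight_state_nodal_condensed_to_dichotomy(self):
        """The eight TNM nodal states cluster into a resectable /
        unresectable dichotomy and every dataset cell is remapped."""
        net, ds = _nodal_net(), _nodal_data()
        partition = StatePartition(
            "nodal",
            (("N0", "N1", "N2", "N3"), ("N4", "N5", "N6", "N7")),
            ("resectable", "unresectable"),
        )
        merged, new_ds, step = merge_states(net, ds, partition)
        assert merged.variable("nodal").states == ("resectable", "unresectable")
        assert set(new_ds.df["nodal"]) <= {"resectable", "unresectable"}
        assert new_ds.n_records == ds.n_records
        assert step.after_parameters < step.before_parameters

    def test_merged_marginal_counts_are_additive(self):
        net, ds = _nodal_net(), _nodal_data()
        partition = StatePartition(
            "nodal",
            (("N0", "N1", "N2", "N3"), ("N4", "N5", "N6", "N7")),
            ("lo", "hi"),
        )
        before = count_table(net, ds, "nodal", ())
        merged, new_ds, _ = merge_states(net, ds, partition)
        after = count_table(merged, new_ds, "nodal", ())
        assert after[0, 0] == before[0, :4].sum()
        assert after[0, 1] == before[0, 4:].sum()

    def test_merge_then_learn_equals_learn_on_remapped(self):
        """Commutation: merging and re-learning is exactly learning on the
        remapped dataset."""
        net, ds = _nodal_net(), _nodal_data()
        partition = StatePartition(
            "nodal", (("N0", "N1"), tuple(f"N{i}" for i in range(2, 8))),
            ("early", "late"),
        )
        config = LearningConfig(alpha=1.0)
        merged, new_ds, _ = merge_states(net, ds, partition, config=config)
        relearned = learn_cpts(merged, new_ds, config)
        for name in merged.variable_names:
            assert np.array_equal(
                merged.cpt(name).table, relearned.cpt(name).table
            )

    def test_overlapping_groups_rejected(self):
        net = _nodal_net()
        with pytest.raises(ModelError, match="overlap"):
            merge_states(
                net,
                None,
                StatePartition(
                    "nodal",
                    (("N0", "N1"), ("N1", "N2", "N3", "N4", "N5", "N6", "N7")),
                    ("a", "b"),
                ),
            )

    def test_incomplete_groups_rejected(self):
        net = _nodal_net()
        with pytest.raises(ModelError, match="partition"):
            merge_states(
                net, None,
                StatePartition("nodal", (("N0",), ("N1",)), ("a", "b")),
            )


class TestCondenseVariables:
    def test_single_source_identity_is_rename(self):
        net, ds = _nodal_net(), _nodal_data()
        states = net.variable("nodal").states
        rule = CondensationRule(
            ("nodal",),
            DiscreteVariable("nodal_status", states, "diagnostic"),
            {(s,): s for s in states},
        )
        new_net, new_ds, _ = condense_variables(net, ds, rule)
        assert "nodal" not in new_net
        assert new_net.variable("nodal_status").states == states
        assert list(new_ds.df["nodal_status"]) == list(ds.df["nodal"])
        # the treatment child is rewired to the renamed summary
        assert new_net.parents("treat") == ("nodal_status",)

    def test_or_mapping_rowwise(self):
        """Three binary risk factors condensed by OR on a 10-row table."""
        variables = [
            DiscreteVariable(n, ("yes", "no")) for n in ("f1", "f2", "f3")
        ]
        net = BayesianNetwork(variables)
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {n: rng.choice(["yes", "no"], 10) for n in ("f1", "f2", "f3")}
        )
        ds = PatientDataset(df)
        rule = CondensationRule(
            ("f1", "f2", "f3"),
            DiscreteVariable("any_risk", ("yes", "no")),
            {
                (a, b, c): "yes" if "yes" in (a, b, c) else "no"
                for a in ("yes", "no")
                for b in ("yes", "no")
                for c in ("yes", "no")
            },
        )
        _net2, new_ds, _ = condense_variables(net, ds, rule)
        expected = [
            "yes" if "yes" in row else "no"
            for row in df.itertuples(index=False)
        ]
        assert list(new_ds.df["any_risk"]) == expected

    def test_missing_tuple_reported(self):
        net = _nodal_net()
        rule_states = net.variable("nodal").states
        with pytest.raises(ModelError, match="misses"):
            CondensationRule(
                ("nodal",),
                DiscreteVariable("x", ("a", "b")),
                {(s,): "a" for s in rule_states[:-1]},  # one tuple missing
            ).validate_for(net)

    def test_derived_name_collision_rejected(self):
        net = _nodal_net()
        rule = CondensationRule(
            ("nodal",),
            DiscreteVariable("treat", ("a", "b")),
            {(s,): "a" for s in net.variable("nodal").states},
        )
        with pytest.raises(ModelError, match="already in use"):
            condense_variables(net, None, rule)


class TestResolveTransitivity:
    def _ici_violating_net(self):
        """Two target families whose parents are linked P_X -> P_Y."""
        px = DiscreteVariable("px", ("0", "1"))
        py = DiscreteVariable("py", ("0", "1"))
        x = DiscreteVariable("x", ("true", "false"), role="target")
        y = DiscreteVariable("y", ("true", "false"), role="target")
        return BayesianNetwork(
            [px, py, x, y],
            edges=[("px", "x"), ("py", "y"), ("px", "py")],
        )

    def test_removes_inter_family_edge(self):
        net = self._ici_violating_net()
        resolved, step = resolve_transitivity(net, ["x", "y"])
        assert ("px", "py") not in resolved.edges
        assert step.details["removed_edges"] == [("px", "py")]
        assert ("px", "x") in resolved.edges and ("py", "y") in resolved.edges

    def test_idempotent_fixed_point(self):
        net = self._ici_violating_net()
        once, step1 = resolve_transitivity(net, ["x", "y"])
        twice, step2 = resolve_transitivity(once, ["x", "y"])
        assert step1.details["removed_edges"] != []
        assert step2.details["removed_edges"] == []
        assert twice.structure_signature() == once.structure_signature()

    def test_zero_removals_when_already_independent(self):
        px = DiscreteVariable("px", ("0", "1"))
        py = DiscreteVariable("py", ("0", "1"))
        x = DiscreteVariable("x", ("true", "false"), role="target")
        y = DiscreteVariable("y", ("true", "false"), role="target")
        net = BayesianNetwork(
            [px, py, x, y], edges=[("px", "x"), ("py", "y")]
        )
        resolved, step = resolve_transitivity(net, ["x", "y"])
        assert step.details["removed_edges"] == []
        assert resolved.structure_signature() == net.structure_signature()


class TestBinarize:
    def test_three_state_therapy_node_becomes_boolean(self):
        net, ds = _nodal_net(), _nodal_data()
        three = DiscreteVariable(
            "option", ("eligible", "optional", "excluded"), role="target"
        )
        net = BayesianNetwork(
            list(net.variables) + [three], edges=list(net.edges)
        )
        ds = PatientDataset(
            ds.df.assign(
                option=np.random.default_rng(1).choice(
                    ["eligible", "optional", "excluded"], ds.n_records
                )
            )
        )
        new_net, new_ds, _ = binarize_target(net, ds, "option", {"eligible"})
        assert new_net.variable("option").is_boolean
        assert set(new_ds.df["option"]) <= {"true", "false"}

    def test_degenerate_true_sets_rejected(self):
        net = _nodal_net()
        with pytest.raises(ModelError):
            binarize_target(net, None, "treat", set())
        with pytest.raises(ModelError):
            binarize_target(net, None, "treat", {"yes", "no"})

    def test_agrees_with_merge_states_cell_for_cell(self):
        net, ds = _nodal_net(), _nodal_data()
        b_net, b_ds, _ = binarize_target(net, ds, "nodal", {"N0", "N1"})
        partition = StatePartition(
            "nodal",
            (("N0", "N1"), tuple(f"N{i}" for i in range(2, 8))),
            ("true", "false"),
        )
        m_net, m_ds, _ = merge_states(net, ds, partition)
        assert b_ds.df.equals(m_ds.df)
        for name in b_net.variable_names:
            assert np.array_equal(b_net.cpt(name).table, m_net.cpt(name).table)


class TestNoisyOr:
    def test_closed_form_rows(self):
        spec = NoisyOrSpec("e", ("c1", "c2"), (0.6, 0.5), leak=0.1)
        cpt = compile_noisy_or(spec)
        assert cpt.table.shape == (4, 2)
        # both causes active: 1 - 0.9*0.4*0.5 = 0.82
        assert cpt.table[0, 0] == pytest.approx(0.82)
        # no cause active: the leak alone
        assert cpt.table[3, 0] == pytest.approx(0.1)
        assert np.allclose(cpt.table.sum(axis=1), 1.0)

    def test_leakless_base_cases(self):
        spec = NoisyOrSpec("e", ("c",), (0.8,), leak=0.0)
        cpt = compile_noisy_or(spec)
        assert cpt.table[0, 0] == pytest.approx(0.8)  # single active cause
        assert cpt.table[1, 0] == 0.0  # empty product, no leak

    def test_matches_explicit_or_gate_decomposition(self):
        """Compiled gate equals inference on an explicitly decomposed OR
        network with per-cause inhibitors and a leak node."""
        p1, p2, leak = 0.6, 0.5, 0.1
        c1 = DiscreteVariable("c1", ("true", "false"))
        c2 = DiscreteVariable("c2", ("true", "false"))
        a1 = DiscreteVariable("a1", ("true", "false"))
        a2 = DiscreteVariable("a2", ("true", "false"))
        lk = DiscreteVariable("lk", ("true", "false"))
        e = DiscreteVariable("e", ("true", "false"))
        net = BayesianNetwork(
            [c1, c2, a1, a2, lk, e],
            cpts={
                "c1": CPT("c1", (), np.array([[0.5, 0.5]])),
                "c2": CPT("c2", (), np.array([[0.5, 0.5]])),
                "a1": CPT("a1", ("c1",), np.array([[p1, 1 - p1], [0.0, 1.0]])),
                "a2": CPT("a2", ("c2",), np.array([[p2, 1 - p2], [0.0, 1.0]])),
                "lk": CPT("lk", (), np.array([[leak, 1 - leak]])),
                "e": CPT(
                    "e", ("a1", "a2", "lk"),
                    np.array(
                        [[1.0, 0.0]] * 7 + [[0.0, 1.0]]  # OR: false only if all false
                    ),
                ),
            },
        )
        compiled = compile_noisy_or(NoisyOrSpec("e", ("c1", "c2"), (p1, p2), leak))
        for i, (s1, s2) in enumerate(
            [(a, b) for a in ("true", "false") for b in ("true", "false")]
        ):
            post = enumerate_posterior(net, {"c1": s1, "c2": s2}, "e")
            assert post["true"] == pytest.approx(compiled.table[i, 0], abs=1e-9)

    def test_apply_requires_boolean_nodes(self):
        net = _nodal_net()
        with pytest.raises(ModelError, match="Boolean"):
            apply_noisy_or(net, NoisyOrSpec("treat", ("nodal",), (0.5,)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        probs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=5),
        leak=st.floats(0.0, 1.0),
    )
    def test_rows_normalized_and_monotone_in_active_causes(self, probs, leak):
        """Gate rows sum to 1 exactly, and activating an additional cause
        never lowers the effect probability."""
        n = len(probs)
        cpt = compile_noisy_or(
            NoisyOrSpec("e", tuple(f"c{i}" for i in range(n)), probs, leak)
        )
        assert np.array_equal(cpt.table.sum(axis=1), np.ones(2**n))
        p_true = cpt.table[:, 0]
        for row in range(2**n):
            for bit in range(n):
                # row-major with "true" first: a set bit marks an inactive
                # cause, so clearing it activates that cause
                if row & (1 << (n - 1 - bit)):
                    assert p_true[row] <= p_true[row & ~(1 << (n - 1 - bit))] + 1e-15

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ModelError):
            NoisyOrSpec("e", ("c",), (1.2,))
        with pytest.raises(ModelError):
            NoisyOrSpec("e", ("c1", "c2"), (0.5,))


class TestComplexityReport:
    def test_identical_models_zero_delta(self):
        net = _nodal_net()
        report = complexity_report(net, net)
        assert all(v == 0 for v in report["reduction"].values())

    def test_fixture_versions_strictly_reduced(self):
        models = reference_models()
        report = complexity_report(models["v1"], models["v3"])
        assert report["reduction"]["free_parameters"] > 0
        assert report["reduction"]["total_states"] > 0
        assert report["reduction"]["n_edges"] > 0

    def test_ten_cause_gate_parameter_economy(self):
        """A 10-cause noisy-OR needs 11 numbers; the compiled CPT has 1024
        rows — the parameter blow-up the canonical model avoids."""
        spec = NoisyOrSpec("e", tuple(f"c{i}" for i in range(10)),
                           (0.5,) * 10, leak=0.01)
        assert len(spec.link_probabilities) + 1 == 11
        assert compile_noisy_or(spec).table.shape == (1024, 2)
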