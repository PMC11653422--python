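"""Learner-model tests: topology, CPTs, inference, updates, profiles, state."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citutor.beliefs import BeliefVector
from citutor.errors import (
    ContractError,
    DegenerateEvidenceError,
    NetworkValidationError,
    NodeLookupError,
    StateParseError,
)
from citutor.network import (
    TYPE_OBSERVABLE,
    apply_profile,
    belief_to_difficulty,
    build_default_network,
    cpt_row,
    default_profiles,
    infer_marginals,
    load_state,
    save_state,
    update_observable,
)


class TestTopology:
    def test_default_network_shape(self, default_net):
        assert len(default_net.nodes) == 12
        assert len(default_net.observables) == 7
        sinks = [n for n in default_net.nodes if default_net.graph.out_degree(n) == 0]
        assert sinks == ["hearing"]
        # one observable per task type, in canonical order
        assert {default_net.nodes[o].task_type for o in default_net.observables} == set(
            TYPE_OBSERVABLE
        )

    def test_perception_feeds_categorization(self, default_net):
        assert "sound_perception" in default_net.nodes["sound_categorization"].parents

    def test_cycle_rejected(self):
        cfg = {
            "nodes": [
                {"name": "A", "layer": "subcompetency", "parents": ["B"]},
                {"name": "B", "layer": "subcompetency", "parents": ["A"]},
            ]
        }
        with pytest.raises(NetworkValidationError, match="cycle"):
            build_default_network(cfg)

    def test_unknown_parent_named_in_error(self):
        cfg = {"nodes": [{"name": "A", "layer": "root", "parents": ["ghost"]}]}
        with pytest.raises(NetworkValidationError, match="ghost"):
            build_default_network(cfg)


class TestCptRow:
    @pytest.mark.parametrize(
        "parents, expected",
        [
            (["high", "high"], (0.0, 0.0, 1.0)),
            (["low", "high"], (0.0, 1.0, 0.0)),
            (["low", "med"], (0.5, 0.5, 0.0)),
            (["low"], (1.0, 0.0, 0.0)),
        ],
    )
    def test_interpolation_endpoints(self, parents, expected):
        assert cpt_row(parents, 0.0).as_array() == pytest.approx(expected, abs=1e-12)

    def test_smoothing_mixes_uniform(self):
        row = cpt_row(["high"], 0.05).as_array()
        assert row == pytest.approx([0.05, 0.05, 0.90], abs=1e-12)

    def test_roots_have_no_rows(self):
        with pytest.raises(ContractError):
            cpt_row([], 0.05)

    @given(
        states=st.lists(st.sampled_from(["low", "med", "high"]), min_size=1, max_size=5),
        eps=st.floats(0, 0.33, exclude_max=True),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_permutation_symmetry_and_validity(self, states, eps):
        row = cpt_row(states, eps)
        permuted = cpt_row(list(reversed(states)), eps)
        assert row.as_array() == pytest.approx(permuted.as_array(), abs=1e-12)
        assert row.as_array().sum() == pytest.approx(1.0, abs=1e-9)


class TestInference:
    def test_child_of_two_uniform_roots(self):
        net = build_default_network(epsilon=0.0)
        m = infer_marginals(net)["phoneme_understanding"]
        assert m.as_array() == pytest.approx([2 / 9, 5 / 9, 2 / 9], abs=1e-12)

    def test_one_hot_high_roots_propagate(self):
        net = build_default_network(epsilon=0.0)
        for name in net.nodes:
            if not net.nodes[name].parents:
                net.evidence[name] = np.array([0.0, 0.0, 1.0])
        for name, b in infer_marginals(net).items():
            assert b.as_array() == pytest.approx([0, 0, 1], abs=1e-12), name

    def test_marginals_normalized(self, default_net):
        rng = np.random.default_rng(3)
        for name in default_net.nodes:
            default_net.evidence[name] = rng.uniform(0.05, 1.0, 3)
        for b in infer_marginals(default_net).values():
            arr = b.as_array()
            assert arr.sum() == pytest.approx(1.0, abs=1e-9)
            assert (arr >= 0).all()

    def test_matches_enumeration_oracle(self, enumeration_oracle):
        rng = np.random.default_rng(11)
        for _ in range(20):
            net = build_default_network()
            for name in net.nodes:
                net.evidence[name] = rng.uniform(0.01, 1.0, 3)
            expected = enumeration_oracle(net)
            got = infer_marginals(net)
            for name in net.nodes:
                assert got[name].as_array() == pytest.approx(expected[name], abs=1e-9)

    def test_matches_pure_python_oracle_small_net(self):
        from conftest import enumerate_marginals_pure

        cfg = {
            "nodes": [
                {"name": "x", "layer": "observable", "task_type": "SP"},
                {"name": "y", "layer": "observable", "parents": ["x"], "task_type": "SC"},
                {"name": "z", "layer": "root", "parents": ["x", "y"]},
            ],
            "epsilon": 0.07,
        }
        net = build_default_network(cfg)
        net.evidence["x"] = np.array([0.5, 0.3, 0.2])
        net.evidence["z"] = np.array([0.1, 0.1, 0.8])
        expected = enumerate_marginals_pure(net)
        got = infer_marginals(net)
        for name in net.nodes:
            assert got[name].as_array() == pytest.approx(expected[name], abs=1e-12)

    def test_all_zero_evidence_rejected(self, default_net):
        default_net.evidence["hearing"] = np.zeros(3)
        with pytest.raises(DegenerateEvidenceError):
            infer_marginals(default_net)


class TestUpdateObservable:
    def test_correct_mixes_toward_high(self, default_net):
        new = update_observable(default_net, "sound_perception", True, 0.5, delta0=0.1)
        assert new.evidence["sound_perception"] == pytest.approx([0.3, 0.3, 0.4], abs=1e-12)
        # original untouched, other nodes untouched
        assert default_net.evidence["sound_perception"] == pytest.approx([1 / 3] * 3)
        assert new.evidence["hearing"] == pytest.approx([1 / 3] * 3)

    def test_incorrect_mixes_toward_low(self, default_net):
        new = update_observable(default_net, "sound_perception", False, 0.5, delta0=0.1)
        assert new.evidence["sound_perception"] == pytest.approx([0.4, 0.3, 0.3], abs=1e-12)

    def test_difficulty_weighting(self, default_net):
        hard = update_observable(default_net, "sound_perception", True, 1.0, delta0=0.1)
        easy = update_observable(default_net, "sound_perception", True, 0.0, delta0=0.1)
        assert hard.evidence["sound_perception"][2] > easy.evidence["sound_perception"][2]

    def test_non_observable_rejected(self, default_net):
        with pytest.raises(NodeLookupError):
            update_observable(default_net, "hearing", True, 0.5)

    def test_repeated_correct_strictly_increases_p_high(self, default_net):
        """20 correct answers monotonically raise the posterior P(high)."""
        net = default_net
        last = infer_marginals(net)["sound_perception"].p_high
        for _ in range(20):
            net = update_observable(net, "sound_perception", True, 0.5, delta0=0.1)
            now = infer_marginals(net)["sound_perception"].p_high
            assert now > last
            last = now

    def test_correct_on_perception_lifts_categorization(self, default_net):
        """Propagation along the arc: SP evidence raises the SC posterior."""
        before = infer_marginals(default_net)["sound_categorization"].p_high
        net = default_net
        for _ in range(10):
            net = update_observable(net, "sound_perception", True, 0.5)
            after = infer_marginals(net)["sound_categorization"].p_high
            assert after >= before - 1e-12
            before = after

    def test_floor_keeps_components_positive(self, default_net):
        net = default_net
        for _ in range(200):
            net = update_observable(net, "sound_perception", True, 1.0, delta0=0.2)
        ev = net.evidence["sound_perception"]
        assert ev.min() >= 0.01 / (1 + 2 * 0.01)  # floor survives normalization
        assert ev.sum() == pytest.approx(1.0, abs=1e-9)


class TestScalarAndProfiles:
    @pytest.mark.parametrize(
        "belief, expected",
        [((1, 0, 0), 0.0), ((0, 0, 1), 1.0), ((0.2, 0.3, 0.5), 0.65)],
    )
    def test_belief_to_difficulty(self, belief, expected):
        assert belief_to_difficulty(BeliefVector(*belief)) == pytest.approx(expected)

    def test_profile_ladder(self, default_net):
        profiles = default_profiles()
        assert [p.name for p in profiles] == [f"P{i}" for i in range(1, 8)]
        low = apply_profile(default_net, profiles[0])
        for obs in default_net.observables:
            assert low.evidence[obs] == pytest.approx([0.8, 0.15, 0.05])
        scalars = [p.mean_scalar() for p in profiles]
        assert np.diff(scalars) == pytest.approx([0.125] * 6)

    def test_empty_profile_is_identity(self, default_net):
        from citutor.network import CompetenceProfile

        same = apply_profile(default_net, CompetenceProfile("noop", {}))
        for name in default_net.nodes:
            assert (same.evidence[name] == default_net.evidence[name]).all()

    def test_virtual_evidence_allowed_on_latent_nodes(self, default_net):
        from citutor.network import CompetenceProfile

        p = CompetenceProfile("latent", {"hearing": BeliefVector(0.1, 0.2, 0.7)})
        out = apply_profile(default_net, p)
        assert out.evidence["hearing"] == pytest.approx([0.1, 0.2, 0.7])

    def test_unknown_node_rejected(self, default_net):
        from citutor.network import CompetenceProfile

        p = CompetenceProfile("bad", {"ghost": BeliefVector.uniform()})
        with pytest.raises(NodeLookupError):
            apply_profile(default_net, p)


class TestStateSerialization:
    def test_round_trip_marginals(self, default_net):
        restored = load_state(save_state(default_net))
        a = infer_marginals(default_net)
        b = infer_marginals(restored)
        for name in default_net.nodes:
            assert a[name].as_array() == pytest.approx(b[name].as_array(), abs=1e-12)

    def test_round_trip_after_random_updates(self, default_net):
        rng = np.random.default_rng(21)
        net = default_net
        observables = net.observables
        for _ in range(50):
            net = update_observable(
                net,
                observables[rng.integers(len(observables))],
                bool(rng.random() < 0.5),
                float(rng.uniform(0, 1)),
            )
        restored = load_state(save_state(net))
        for name in net.nodes:
            assert (restored.evidence[name] == net.evidence[name]).all()
        assert restored.epsilon == net.epsilon

    def test_truncated_text_rejected(self, default_net):
        text = save_state(default_net)
        with pytest.raises(StateParseError, match="line"):
            load_state(text[: len(text) // 2])
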