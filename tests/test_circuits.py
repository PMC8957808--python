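"""Circuit construction, validation, and architecture-level properties."""

import numpy as np
import pytest

import socialfear as sf
from socialfear import ConnectionSpec, NetworkSpec, UnitSpec, validate_spec
from socialfear.dynamics import NetworkState, SimParams
from socialfear.dynamics import run_timesteps


class TestBasicBuild:
    def test_roster_and_output_afferents(self, basic_spec):
        assert basic_spec.n_units == 16
        aff = [c for c in basic_spec.connections if c.post == "dPag1"]
        assert {c.pre for c in aff} == {"Hyp1", "Pyr2"}
        signs = {c.pre: np.sign(c.weight) for c in aff}
        assert signs["Hyp1"] > 0 and signs["Pyr2"] < 0

    def test_double_inhibition_circuit(self, basic_spec):
        assert basic_spec.connection(("Som1", "Pv")).weight < 0
        assert basic_spec.connection(("Pv", "Pyr1")).weight < 0

    def test_shipped_config_is_valid(self, basic_spec):
        assert validate_spec(basic_spec) == []

    def test_input_channels(self, basic_spec):
        ch = basic_spec.input_channels
        assert set(ch) == {"conspecific", "context1", "context2", "defeat"}
        assert set(ch["defeat"]) == {"lPBN", "Som1"}

    def test_context_symmetry_before_learning(self, basic_spec):
        # both context populations project identically until learning
        for post in ("Hyp1", "Hyp2"):
            w1 = basic_spec.connection(("Hip1", post)).weight
            w2 = basic_spec.connection(("Hip2", post)).weight
            assert w1 == w2


class TestAlternativeBuild:
    def test_adds_exactly_one_inhibitory_hyp1_afferent(self, basic_spec, alt_spec):
        assert alt_spec.n_units == 17
        base_aff = {c.pre for c in basic_spec.connections if c.post == "Hyp1"}
        alt_aff = {c.pre for c in alt_spec.connections if c.post == "Hyp1"}
        assert alt_aff - base_aff == {"LS"}
        assert alt_spec.connection(("LS", "Hyp1")).weight < 0
        assert not alt_spec.connection(("LS", "Hyp1")).plastic

    def test_topology_differs_only_by_ls(self, basic_spec, alt_spec):
        assert set(alt_spec.unit_names) - set(basic_spec.unit_names) == {"LS"}
        extra = set(alt_spec.edges) - set(basic_spec.edges)
        assert extra == {("LS", "Hyp1")}
        assert "LS" in alt_spec.input_channels["conspecific"]


class TestValidateSpec:
    def _minimal(self):
        return NetworkSpec(
            units=[UnitSpec("a", "A", "+"), UnitSpec("g", "A", "-")],
            connections=[ConnectionSpec("a", "g", 0.5)],
            input_channels={"in": {"a": 1.0}},
        )

    def test_sign_violation_names_edge(self):
        spec = self._minimal()
        spec.connections.append(ConnectionSpec("g", "a", +0.5))
        violations = validate_spec(spec)
        assert len(violations) == 1 and "g->a" in violations[0]

    def test_plastic_edge_without_bounds(self):
        spec = self._minimal()
        spec.connections = [ConnectionSpec("a", "g", 0.5, plastic=True)]
        violations = validate_spec(spec)
        assert any("lacks clip bounds" in v for v in violations)

    def test_unknown_unit_reference(self):
        spec = self._minimal()
        spec.connections.append(ConnectionSpec("a", "zz", 0.1))
        assert any("zz" in v for v in validate_spec(spec))

    def test_self_connection_flagged(self):
        spec = self._minimal()
        spec.connections.append(ConnectionSpec("a", "a", 0.1))
        assert any("self-connection" in v for v in validate_spec(spec))

    def test_violations_are_data_not_exceptions(self):
        spec = self._minimal()
        spec.connections.append(ConnectionSpec("g", "a", +0.5))
        assert isinstance(validate_spec(spec), list)


class TestStructuralEdits:
    def test_scaled_weight_scales_bounds_of_plastic_edges(self, basic_spec):
        out = basic_spec.with_scaled_weight(("MeA", "Hyp1"), 2.0)
        c0 = basic_spec.connection(("MeA", "Hyp1"))
        c1 = out.connection(("MeA", "Hyp1"))
        assert c1.weight == pytest.approx(2 * c0.weight)
        assert c1.bounds[1] == pytest.approx(2 * c0.bounds[1])
        # original untouched
        assert basic_spec.connection(("MeA", "Hyp1")).weight == c0.weight

    def test_without_unit_drops_incident_edges(self, basic_spec):
        out = basic_spec.without_unit("HypIN1")
        assert "HypIN1" not in out.unit_names
        assert all("HypIN1" not in e for e in out.edges)
        assert validate_spec(out) == []


def _steady_state(spec, I, steps=2000):
    state = NetworkState.zeros(spec.n_units, spec.weight_matrix())
    final, _ = run_timesteps(state, I, SimParams(), steps)
    return final.F


class TestWinnerTakeAll:
    def test_stronger_drive_wins(self, basic_spec):
        """With frozen weights, the harder-driven hypothalamic unit ends up
        more active, and strengthening the interneurons widens the gap."""
        spec = basic_spec.copy()
        spec.plasticity.enabled = False
        i1, i2 = spec.index("Hyp1"), spec.index("Hyp2")
        I = np.zeros(spec.n_units)
        I[i1], I[i2] = 0.6, 0.5

        def with_inhibition(scale):
            out = spec.copy()
            for e in [("HypIN1", "Hyp1"), ("HypIN2", "Hyp2")]:
                out = out.with_scaled_weight(e, scale)
            out.plasticity.enabled = False
            return out

        # soft competition: both partially active, harder-driven unit ahead
        F = _steady_state(with_inhibition(0.15), I)
        assert F[i1] > F[i2] > 0.0
        gap = F[i1] - F[i2]
        # stronger interneurons widen the winner's lead
        F2 = _steady_state(with_inhibition(0.6), I)
        assert F2[i1] - F2[i2] > gap

    def test_antagonism_across_protocol(self, basic_result):
        """Trial-mean threat and interaction activity move in opposition."""
        h1 = basic_result.trial_means("Hyp1")
        h2 = basic_result.trial_means("Hyp2")
        assert np.corrcoef(h1, h2)[0, 1] < -0.5
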