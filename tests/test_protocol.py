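"""Protocol execution, manipulations, and their windows."""

import numpy as np
import pytest

import socialfear as sf
from socialfear import (
    ConfigurationError,
    Manipulation,
    Phase,
    ProtocolSpec,
    default_protocol,
    mdt_stimulation_block,
    run_protocol,
)
from socialfear.experiments import AVOIDANCE_THRESHOLD, avoidance_index


class TestProtocolStructure:
    def test_default_phases(self):
        proto = default_protocol()
        assert [p.name for p in proto.phases] == [
            "baseline",
            "conditioning",
            "extinction",
        ]
        assert [p.n_trials for p in proto.phases] == [1, 3, 11]
        assert proto.sim.trial_length == 500

    def test_invalid_phase_rejected(self):
        with pytest.raises(ConfigurationError):
            Phase("x", 0, {})
        with pytest.raises(ConfigurationError):
            Phase("x", 1, {"conspecific": -1.0})

    def test_result_bookkeeping(self, basic_result):
        assert len(basic_result.trials) == 15
        assert len(basic_result.weight_snapshots) == 15
        assert basic_result.trials[0].trace.shape == (500, 16)


class TestPhaseBehavior:
    def test_baseline_quiet_conditioning_avoidant(self, basic_result):
        names = basic_result.unit_names
        base = basic_result.phase_trials("baseline")[0]
        assert avoidance_index(base.trace, names) < AVOIDANCE_THRESHOLD
        cond = basic_result.phase_trials("conditioning")[-1]
        assert avoidance_index(cond.trace, names) >= AVOIDANCE_THRESHOLD

    def test_conditioning_recruits_the_defeat_pathway(self, basic_result):
        cond = basic_result.phase_trial_means
        assert cond("Som1", "conditioning").min() > 0.5
        assert cond("Pyr2", "conditioning").max() < 0.05  # fear-OFF shut down
        assert cond("Pyr1", "conditioning").min() > 0.5  # fear-ON recruited
        assert cond("Hyp1", "conditioning").max() > 0.8

    def test_extinction_decays_below_threshold(self, basic_result):
        ext = basic_result.phase_trial_means("dPag1", "extinction")
        assert ext[0] >= AVOIDANCE_THRESHOLD
        assert ext.min() < AVOIDANCE_THRESHOLD
        assert ext[-1] < AVOIDANCE_THRESHOLD


class TestDeterminism:
    def test_repeated_runs_identical(self, basic_spec):
        a = run_protocol(basic_spec)
        b = run_protocol(basic_spec)
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.trace, tb.trace)
        assert np.array_equal(a.weight_snapshots[-1], b.weight_snapshots[-1])


class TestManipulations:
    def test_unknown_targets_fail_before_integration(self, basic_spec):
        for manip in [
            Manipulation("silence_unit", "NoSuchUnit"),
            Manipulation("block_connection", ("MeA", "NoSuchUnit")),
            Manipulation("freeze_plasticity", "NoSuchArea"),
        ]:
            with pytest.raises(ConfigurationError):
                run_protocol(basic_spec, manipulations=[manip])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            Manipulation("teleport_unit", "MeA")

    def test_silence_clamps_rate_to_zero(self, basic_spec):
        res = run_protocol(
            basic_spec,
            manipulations=[Manipulation("silence_unit", "MeA")],
        )
        assert res.trial_means("MeA").max() == 0.0

    def test_block_and_scale_leave_stored_weights_untouched(self, basic_spec):
        base = run_protocol(basic_spec)
        for manip in [
            Manipulation("block_connection", ("Hyp1", "dPag1")),
            Manipulation("scale_connection", ("Hyp1", "dPag1"), magnitude=0.3),
        ]:
            res = run_protocol(basic_spec, manipulations=[manip])
            i, j = res.index("dPag1"), res.index("Hyp1")
            assert res.weight_snapshots[-1][i, j] == base.weight_snapshots[-1][i, j]

    def test_traces_identical_before_window_opens(self, basic_spec):
        """A manipulation has exactly zero effect outside its window."""
        manip = Manipulation(
            "stimulate_unit",
            "Pyr2",
            magnitude=2.0,
            phases=["extinction"],
            trials=[3],
        )
        base = run_protocol(basic_spec)
        pert = run_protocol(basic_spec, manipulations=[manip])
        # everything up to (extinction, trial 3) is bit-identical
        for tb, tp in zip(base.trials[:6], pert.trials[:6]):
            assert np.array_equal(tb.trace, tp.trace)
        i = base.index("Pyr2")
        assert pert.trials[6].trace[:, i].mean() > base.trials[6].trace[:, i].mean()

    def test_step_window_within_trial(self, basic_spec):
        manip = Manipulation(
            "stimulate_unit",
            "dPag1",
            magnitude=3.0,
            phases=["baseline"],
            steps=(250, 500),
        )
        base = run_protocol(basic_spec)
        pert = run_protocol(basic_spec, manipulations=[manip])
        i = base.index("dPag1")
        b, p = base.trials[0].trace[:, i], pert.trials[0].trace[:, i]
        assert np.array_equal(b[:250], p[:250])
        assert p[300:].mean() > b[300:].mean() + 0.3

    def test_removing_manipulation_restores_behavior(self, basic_spec):
        manip = Manipulation("scale_connection", ("MeA", "MDT"), magnitude=0.5)
        base = run_protocol(basic_spec)
        again = run_protocol(basic_spec, manipulations=[])
        run_protocol(basic_spec, manipulations=[manip])  # interleaved perturbed run
        for ta, tb in zip(base.trials, again.trials):
            assert np.array_equal(ta.trace, tb.trace)

    def test_freeze_plasticity_area_target(self, basic_spec):
        res = run_protocol(
            basic_spec,
            manipulations=[Manipulation("freeze_plasticity", "VMHvl")],
        )
        for edge in [("MeA", "Hyp1"), ("MeA", "Hyp2"), ("Hip1", "Hyp1")]:
            w = res.weight_series(edge)
            assert np.all(w == res.initial_weight(edge))
        # the mPFC afferents still learned
        assert res.weight_series(("MDT", "Pyr1"))[3] != res.initial_weight(
            ("MDT", "Pyr1")
        )


class TestPhaseComposability:
    def test_chained_calls_equal_single_protocol(self, basic_spec):
        proto = default_protocol()
        whole = run_protocol(basic_spec, proto)
        first = run_protocol(
            basic_spec, ProtocolSpec(phases=proto.phases[:2], sim=proto.sim)
        )
        second = run_protocol(
            basic_spec,
            ProtocolSpec(phases=proto.phases[2:], sim=proto.sim),
            initial_state=first.final_state,
        )
        merged = first.trials + second.trials
        assert len(merged) == len(whole.trials)
        for tm, tw in zip(merged, whole.trials):
            assert np.array_equal(tm.trace, tw.trace)


class TestStimulationBlock:
    def test_invalid_mode_rejected(self, basic_spec):
        with pytest.raises(ConfigurationError):
            mdt_stimulation_block(basic_spec, "MFS")

    def test_block_freezes_everything_but_mdt_efferents(self, basic_spec):
        phase, manips = mdt_stimulation_block(basic_spec, "HFS")
        freeze = [m for m in manips if m.kind == "freeze_plasticity"]
        assert len(freeze) == 1
        frozen = set(map(tuple, freeze[0].target))
        assert all(e[0] != "MDT" for e in frozen)
        assert frozen | {e for e in basic_spec.plastic_edges if e[0] == "MDT"} == set(
            basic_spec.plastic_edges
        )
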