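"""Scanning probes, repertoire classification, practice and recall."""

from dataclasses import replace

import numpy as np
import pytest

from hkblearn import (
    LearningProtocol,
    PostLearningModel,
    ScanResult,
    ScanningProbe,
    SimulationConfig,
    StabilityRule,
    TrialSummary,
    assign_learning_task,
    bistable_schedule,
    classify_repertoire,
    count_attractors,
    find_fixed_points,
    multistable_schedule,
    relax_post_learning,
    run_learning,
    run_recall,
    run_scanning,
)


@pytest.fixture(scope="module")
def bistable_scan():
    return run_scanning(
        bistable_schedule(0.0), ScanningProbe(), SimulationConfig(seed=3)
    )


@pytest.fixture(scope="module")
def multistable_scan():
    return run_scanning(
        multistable_schedule(0.0), ScanningProbe(), SimulationConfig(seed=3)
    )


class TestScanning:
    def test_noise_free_scan_exact_at_attractors(self, bistable0):
        """Without noise every probe relaxes into its basin's attractor;
        probes placed exactly at attractors score RMSE ~ 0."""
        cfg = SimulationConfig(noise_q=0.0, seed=0)
        scan = run_scanning(bistable0, ScanningProbe(repetitions=1), cfg)
        by_phase = {s.required_deg: s for s in scan.summaries}
        assert by_phase[0.0].rmse_deg == pytest.approx(0.0, abs=1e-6)
        assert by_phase[180.0].rmse_deg == pytest.approx(0.0, abs=1e-6)
        # a probe at 45 deg relaxes to in-phase: AE equals the full distance
        assert by_phase[45.0].ae_deg == pytest.approx(45.0, abs=0.1)

    def test_bistable_rmse_profile(self, bistable_scan):
        """RMSE has local minima at the probe end points 0 and 180 deg."""
        rmse = {s.required_deg: s.rmse_deg for s in bistable_scan.summaries}
        assert rmse[0.0] < rmse[15.0] < rmse[45.0]
        assert rmse[180.0] < rmse[165.0] < rmse[135.0]
        assert rmse[90.0] > 20.0  # mid-range is not in the repertoire

    def test_multistable_rmse_extra_minimum(self, multistable_scan):
        """An additional RMSE dip marks the mid-range attractor near 90."""
        rmse = {s.required_deg: s.rmse_deg for s in multistable_scan.summaries}
        assert rmse[90.0] < rmse[45.0]
        assert rmse[90.0] < rmse[135.0]
        assert rmse[90.0] < 20.0

    def test_scan_has_one_summary_per_probe_phase(self, bistable_scan):
        assert [s.required_deg for s in bistable_scan.summaries] == [
            float(p) for p in range(0, 181, 15)
        ]

    def test_scan_deterministic(self, bistable0):
        cfg = SimulationConfig(seed=9)
        a = run_scanning(bistable0, ScanningProbe(), cfg).to_frame()
        b = run_scanning(bistable0, ScanningProbe(), cfg).to_frame()
        assert a.equals(b)

    def test_probe_validation(self):
        with pytest.raises(ValueError):
            ScanningProbe(required_phases_deg=(0.0, 200.0))
        with pytest.raises(ValueError):
            ScanningProbe(repetitions=0)


class TestClassification:
    def test_bistable_label(self, bistable_scan):
        cls = classify_repertoire(bistable_scan)
        assert cls.label == "bistable"
        assert {0.0, 180.0} <= set(cls.stable_phases_deg)
        assert not any(30.0 < p < 150.0 for p in cls.stable_phases_deg)

    def test_multistable_label(self, multistable_scan):
        cls = classify_repertoire(multistable_scan)
        assert cls.label == "multistable"
        assert any(30.0 < p < 150.0 for p in cls.stable_phases_deg)

    def test_degenerate_everything_stable_is_other(self):
        summaries = [
            TrialSummary.from_ce_sd(float(p), 0.0, 0.0) for p in range(0, 181, 15)
        ]
        cls = classify_repertoire(ScanResult(summaries=summaries))
        assert cls.label == "other"
        assert cls.degenerate

    def test_empty_scan_rejected(self):
        with pytest.raises(ValueError):
            classify_repertoire(ScanResult(summaries=[]))

    def test_task_assignment(self, bistable_scan, multistable_scan):
        assert assign_learning_task(classify_repertoire(bistable_scan)) == 90.0
        assert assign_learning_task(classify_repertoire(multistable_scan)) == 135.0
        from hkblearn import RepertoireClass

        with pytest.raises(ValueError, match="no canonical task"):
            assign_learning_task(RepertoireClass("other", ()))


class TestLearning:
    def test_bistable_route_gains_accuracy_and_stability(self):
        """Practicing 90 deg: both AE and SD drop from early to late trials."""
        summaries, final = run_learning(
            LearningProtocol.canonical("bistable"), SimulationConfig(seed=0)
        )
        ae = [s.ae_deg for s in summaries]
        sd = [s.sd_deg for s in summaries]
        assert np.mean(ae[:5]) > 45.0 > np.mean(ae[-5:])
        assert np.mean(ae[-5:]) < 5.0
        assert np.mean(sd[:5]) > np.mean(sd[-5:])
        assert final.lam == 5.0 and final.profile == "bistable"

    def test_multistable_route_gains_accuracy_without_stabilization(self):
        """Practicing 135 deg: AE drops but SD shows no decrease (shift route
        brings no stability gain)."""
        summaries, final = run_learning(
            LearningProtocol.canonical("multistable"), SimulationConfig(seed=0)
        )
        ae = [s.ae_deg for s in summaries]
        sd = [s.sd_deg for s in summaries]
        assert np.mean(ae[:5]) > np.mean(ae[-5:])
        assert np.mean(ae[-2:]) < 10.0
        assert np.mean(sd[-5:]) >= np.mean(sd[:5])
        assert final.lam == 5.0

    def test_zero_trial_protocol(self):
        protocol = LearningProtocol(profile="bistable", psi_target_deg=90.0, trials=0)
        summaries, params = run_learning(protocol, SimulationConfig(seed=0))
        assert summaries == []
        assert params.lam == 0.0

    def test_linear_ramp(self):
        protocol = LearningProtocol.canonical("bistable", trials=11)
        assert protocol.ramp(0) == 0.0
        assert protocol.ramp(10) == 5.0
        assert protocol.ramp(5) == pytest.approx(2.5)


class TestPostLearning:
    def test_elapsed_zero_is_identity(self):
        final = bistable_schedule(5.0)
        model = PostLearningModel.from_end_of_learning(final)
        params = relax_post_learning(model, 0.0)
        assert params.skeleton.a == final.skeleton.a
        assert params.learning.c == final.learning.c

    def test_bistable_minima_persist_after_decay(self):
        """Long after practice c ~ 0, but the skeleton keeps the new
        mid-range attractor: the learned pattern persists."""
        model = PostLearningModel.from_end_of_learning(bistable_schedule(5.0))
        params = relax_post_learning(model, 1000.0)
        assert params.learning.c == pytest.approx(0.0, abs=1e-12)
        mids = [
            f.location_deg
            for f in find_fixed_points(params)
            if f.is_attractor and 0 < f.location_deg < 180
        ]
        assert len(mids) == 1 and 80.0 < mids[0] < 100.0

    def test_multistable_attractor_shifts_back(self):
        """The shifted attractor migrates back toward 90 once c decays."""
        final = multistable_schedule(5.0)
        model = PostLearningModel.from_end_of_learning(final)
        end_mid = [
            f.location_deg
            for f in find_fixed_points(final)
            if f.is_attractor and 30 < f.location_deg < 170
        ][0]
        relaxed = relax_post_learning(model, 1000.0)
        back_mid = [
            f.location_deg
            for f in find_fixed_points(relaxed)
            if f.is_attractor and 30 < f.location_deg < 170
        ][0]
        assert 120.0 < end_mid < 140.0
        assert 85.0 < back_mid < 105.0
        assert back_mid < end_mid

    def test_persistence_links_the_two_profiles(self):
        """The bistable learner's post-decay skeleton equals the multistable
        learner's pre-practice skeleton: same attractor inventory."""
        post = relax_post_learning(
            PostLearningModel.from_end_of_learning(bistable_schedule(5.0)), 1e9
        )
        pre = multistable_schedule(0.0)
        # a4 frozen at 3 = multistable a4; learning term fully decayed
        assert post.skeleton.a == (1.0, 3.0, 0.0, 3.0)
        post_att = [f.location_deg for f in find_fixed_points(post) if f.is_attractor]
        pre_att = [f.location_deg for f in find_fixed_points(pre) if f.is_attractor]
        assert post_att == pytest.approx(pre_att, abs=1e-6)

    def test_negative_elapsed_rejected(self):
        model = PostLearningModel.from_end_of_learning(bistable_schedule(5.0))
        with pytest.raises(ValueError):
            relax_post_learning(model, -1.0)


class TestRecall:
    @pytest.mark.parametrize("profile, expected", [("bistable", True), ("multistable", False)])
    def test_long_delay_recall_dichotomy(self, profile, expected):
        """Bifurcation-route learners recall the practiced pattern after the
        learning force has decayed; shift-route learners do not."""
        from hkblearn import get_schedule

        model = PostLearningModel.from_end_of_learning(get_schedule(profile)(5.0))
        _, verdict = run_recall(
            model, 50.0, ScanningProbe(), SimulationConfig(seed=7)
        )
        assert verdict is expected

    @pytest.mark.parametrize("profile", ["bistable", "multistable"])
    def test_immediate_recall_always_succeeds(self, profile):
        from hkblearn import get_schedule

        model = PostLearningModel.from_end_of_learning(get_schedule(profile)(5.0))
        _, verdict = run_recall(model, 0.0, ScanningProbe(), SimulationConfig(seed=7))
        assert verdict is True
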