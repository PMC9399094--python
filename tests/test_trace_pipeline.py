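"""Tests for detection, linking, and trajectory classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from oriscope import kymo_sim as ks
from oriscope import trace_pipeline as tp

from conftest import make_trajectory


def _render(events, n_lines=100, photons=2000.0, seed=0):
    tether = ks.TetherModel(n_lines=n_lines)
    nucs = ks.NucleosomeSet(np.array([]), [], np.array([], dtype=bool))
    phot = ks.PhotophysicsModel(photons_per_fluor_per_line=photons,
                                background_per_pixel=10.0,
                                bleach_rate_per_line=0.0)
    return ks.render_kymograph(tether, events, nucs, phot, seed=seed), tether


def _stable_event(bp, channel="red", n_lines=100):
    return ks.BindingEvent("ORC", "bare", "stable", bp, 0, n_lines - 1,
                           np.full(n_lines, bp),
                           dye_states=[(channel, True, None)])


# ---------------------------------------------------------------------------
# detection and linking


def test_detect_on_empty_kymograph_returns_nothing():
    stack, _ = _render([])
    assert tp.detect_and_link(stack, "red") == []


def test_detect_single_stationary_emitter():
    stack, tether = _render([_stable_event(20_000.0)])
    trajs = tp.detect_and_link(stack, "red")
    assert len(trajs) == 1
    traj = trajs[0]
    assert traj.n_lines >= 95
    assert abs(traj.median_position_bp() - 20_000.0) < 0.3 * tether.bp_per_pixel


def test_detect_many_emitters_recall_and_precision():
    truth = np.linspace(3_000, 45_000, 20)
    stack, tether = _render([_stable_event(bp) for bp in truth], seed=3)
    trajs = tp.detect_and_link(stack, "red")
    found = np.array([t.median_position_bp() for t in trajs])
    recall = np.mean([np.min(np.abs(found - bp)) < 500 for bp in truth])
    precision = np.mean([np.min(np.abs(truth - f)) < 500 for f in found])
    assert recall >= 0.95
    assert precision >= 0.95


@settings(max_examples=10, deadline=None, derandomize=True)
@given(snr_lo=hst.floats(min_value=3.0, max_value=6.0),
       snr_hi_extra=hst.floats(min_value=0.5, max_value=6.0))
def test_detection_count_is_monotone_in_snr_threshold(snr_lo, snr_hi_extra):
    truth = np.linspace(5_000, 43_000, 8)
    stack, _ = _render([_stable_event(bp) for bp in truth],
                       photons=300.0, seed=11)
    lo = tp.detect_and_link(stack, "red",
                            tp.DetectionParams(snr_min=snr_lo))
    hi = tp.detect_and_link(stack, "red",
                            tp.DetectionParams(snr_min=snr_lo + snr_hi_extra))
    assert len(hi) <= len(lo)


# ---------------------------------------------------------------------------
# mobility and position


def _noisy_track(anchor_bp, n_lines, loc_sigma_px, rng,
                 D_kb2_per_s=0.0, dt=0.1, bp_per_px=250.0):
    steps = rng.normal(0, np.sqrt(2 * D_kb2_per_s * dt) * 1000, n_lines)
    steps[0] = 0.0
    pos = anchor_bp + np.cumsum(steps)
    pos = pos + rng.normal(0, loc_sigma_px * bp_per_px, n_lines)
    return make_trajectory(pos)


def test_mobility_separates_stable_from_diffusive():
    rng = np.random.default_rng(21)
    thr = tp.calibrate_variance_threshold(localization_sigma_px=0.15)
    stable_ok = sum(
        tp.classify_mobility(_noisy_track(20_000, 50, 0.15, rng),
                             var_threshold_px2=thr).label == "stable"
        for _ in range(200))
    diff_ok = sum(
        tp.classify_mobility(
            _noisy_track(20_000, 50, 0.15, rng, D_kb2_per_s=0.2),
            var_threshold_px2=thr).label == "diffusive"
        for _ in range(200))
    assert stable_ok >= 190
    assert diff_ok >= 190


def test_mobility_short_trajectory_is_unclassified():
    traj = make_trajectory(np.full(5, 10_000.0))
    assert tp.classify_mobility(traj).label == "unclassified"


def test_calibrated_threshold_scales_with_localization_noise():
    lo = tp.calibrate_variance_threshold(localization_sigma_px=0.1)
    hi = tp.calibrate_variance_threshold(localization_sigma_px=0.3)
    assert hi > lo


def test_classify_position_boundary_semantics():
    tether = ks.TetherModel()
    cases = {32_499: "non-ARS", 32_500: "ARS", 33_700: "ARS",
             34_998: "ARS", 35_000: "non-ARS"}
    for bp, expected in cases.items():
        traj = make_trajectory(np.full(50, float(bp)))
        assert tp.classify_position(traj, tether) == expected, bp


# ---------------------------------------------------------------------------
# colocalization


def test_colocalization_trivial_pairs():
    a = [make_trajectory(np.full(50, 10_000.0), channel="green"),
         make_trajectory(np.full(50, 30_000.0), channel="green")]
    b = [make_trajectory(np.full(50, 10_100.0)),
         make_trajectory(np.full(50, 41_000.0))]
    calls = tp.call_colocalization(a, b)
    by_a = {c.traj_ref_a: c for c in calls}
    assert by_a[0].colocalized and by_a[0].traj_ref_b == 0
    assert not by_a[1].colocalized
    assert by_a[0].mean_separation_bp == pytest.approx(100.0)


def test_colocalization_assigns_qualifying_pairs_first():
    # b0 is 300 bp from a0 (qualifying) but 200 bp from a1's partner slot:
    # a1 has no partner within the cutoff. Greedy assignment on raw distance
    # alone would let the non-qualifying (a1, b0) pair block (a0, b0).
    a = [make_trajectory(np.full(50, 10_000.0), channel="green"),
         make_trajectory(np.full(50, 10_200.0), channel="green")]
    b = [make_trajectory(np.full(50, 10_300.0))]
    calls = tp.call_colocalization(a, b, cutoff_bp=350.0)
    coloc = {c.traj_ref_a for c in calls if c.colocalized}
    assert 1 in coloc  # the 100-bp pair wins the single partner
    assert 0 not in coloc


def test_colocalization_shared_partner_without_one_to_one():
    # two fragments of the same site both qualify against a single partner
    a = [make_trajectory(np.full(50, 10_000.0), channel="green"),
         make_trajectory(np.full(50, 10_050.0), channel="green")]
    b = [make_trajectory(np.full(50, 10_100.0))]
    exclusive = tp.call_colocalization(a, b)
    assert sum(c.colocalized for c in exclusive) == 1
    shared = tp.call_colocalization(a, b, one_to_one=False)
    assert sum(c.colocalized for c in shared) == 2


def test_colocalization_requires_temporal_overlap():
    a = [make_trajectory(np.full(20, 10_000.0), channel="green",
                         start_line=0)]
    b = [make_trajectory(np.full(20, 10_000.0), start_line=40)]
    calls = tp.call_colocalization(a, b)
    assert not any(c.colocalized for c in calls)


# ---------------------------------------------------------------------------
# salt response and arrival


def test_salt_response_labels_constructed_cases():
    rng = np.random.default_rng(5)
    wash = 50
    stay = make_trajectory(10_000 + rng.normal(0, 30, 150))
    assert tp.classify_salt_response(stay, wash).label == "stable"
    gone = make_trajectory(np.full(52, 10_000.0))
    assert tp.classify_salt_response(gone, wash).label == "dissociate"
    pos = np.full(150, 10_000.0)
    pos[wash:] = 10_000 + np.linspace(0, 6_000, 100)
    slide = make_trajectory(pos)
    assert tp.classify_salt_response(slide, wash).label == "slide"
    later = make_trajectory(np.full(20, 10_000.0), start_line=60)
    assert tp.classify_salt_response(later, wash) is None


def test_salt_response_fractions_recovered_from_simulation():
    tether = ks.TetherModel(n_lines=200)
    plan = ks.SaltWashPlan(wash_line_index=100,
                           behavior_probs=(0.3, 0.3, 0.4))
    rng = np.random.default_rng(7)
    events = []
    for _ in range(1000):
        anchor = float(rng.uniform(5_000, 42_000))
        events.append(ks.BindingEvent(
            "MCM", "bare", "stable", anchor, 0, 199,
            np.full(200, anchor), dye_states=[("far_red", True, None)]))
    washed = ks.apply_salt_wash(events, plan, tether, seed=3)
    truth = {lbl: sum(e.salt_response == lbl for e in washed) / len(washed)
             for lbl in ("slide", "stay", "dissociate")}
    labels = []
    for ev in washed:
        traj = make_trajectory(ev.positions_bp, start_line=ev.start_line)
        labels.append(tp.classify_salt_response(traj, 100).label)
    n = len(labels)
    called = {"slide": labels.count("slide") / n,
              "stay": labels.count("stable") / n,
              "dissociate": labels.count("dissociate") / n}
    for lbl in truth:
        assert abs(called[lbl] - truth[lbl]) <= 0.05, lbl


def test_arrival_mode_fractions_recovered():
    rng = np.random.default_rng(9)
    n_each = 200
    correct = {"direct_3D": 0, "sliding_1D": 0}
    for _ in range(n_each):
        target = float(rng.uniform(10_000, 40_000))
        direct = make_trajectory(target + rng.normal(0, 40, 50))
        if tp.classify_arrival(direct, np.array([target])) == "direct_3D":
            correct["direct_3D"] += 1
        start = target + rng.choice([-1, 1]) * rng.uniform(3_000, 8_000)
        approach = np.linspace(start, target, 10)
        pos = np.concatenate([approach, target + rng.normal(0, 40, 40)])
        slid = make_trajectory(pos)
        if tp.classify_arrival(slid, np.array([target])) == "sliding_1D":
            correct["sliding_1D"] += 1
    # recovered fraction of each true mode within +/- 0.05
    assert correct["direct_3D"] / n_each >= 0.95
    assert correct["sliding_1D"] / n_each >= 0.95


# ---------------------------------------------------------------------------
# summaries


def test_summarize_matches_hand_computation():
    labels = ["stable"] * 6 + ["diffusive"] * 2 + ["stable"] * 2 + \
        ["diffusive"] * 2
    reps = [1] * 8 + [2] * 4
    s = tp.summarize(labels, reps, compare=("stable", "diffusive"))
    assert s.counts == {"stable": 8, "diffusive": 4}
    assert s.fractions["stable"] == pytest.approx(8 / 12)
    np.testing.assert_allclose(
        sorted(s.replicate_fractions["stable"]), [0.5, 0.75])
    assert s.mean["stable"] == pytest.approx(0.625)
    assert s.sd["stable"] == pytest.approx(np.std([0.75, 0.5], ddof=1))
    t_exp, p_exp = stats.ttest_ind([0.75, 0.5], [0.25, 0.5])
    assert s.t_statistic == pytest.approx(t_exp)
    assert s.p_value == pytest.approx(p_exp)


def test_summarize_single_replicate_has_no_test():
    s = tp.summarize(["a", "b", "a"], [1, 1, 1], compare=("a", "b"))
    assert s.t_statistic is None or np.isnan(s.t_statistic)
    assert s.warnings
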