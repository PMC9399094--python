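"""Tests for the kymograph/tether simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from oriscope import kymo_sim as ks


# ---------------------------------------------------------------------------
# tether and nucleosome deposition


def test_simulate_tether_is_deterministic():
    t1, n1 = ks.simulate_tether(seed=7)
    t2, n2 = ks.simulate_tether(seed=7)
    assert t1 == t2
    np.testing.assert_array_equal(n1.positions_bp, n2.positions_bp)
    np.testing.assert_array_equal(n1.labeled, n2.labeled)


def test_nucleosome_count_and_spacing():
    for seed in range(40):
        tether, nucs = ks.simulate_tether(seed=seed)
        assert 1 <= len(nucs) <= 7
        pos = np.sort(nucs.positions_bp)
        assert pos.min() >= 1 and pos.max() <= tether.length_bp
        if len(pos) > 1:
            assert np.diff(pos).min() >= 2000


def test_nucleosome_label_fraction_matches_efficiency():
    labeled = total = 0
    for seed in range(300):
        _, nucs = ks.simulate_tether(label_efficiency=0.7, seed=seed)
        labeled += int(nucs.labeled.sum())
        total += len(nucs)
    frac = labeled / total
    # binomial SE at total ~ 1200 draws is ~0.013
    assert abs(frac - 0.7) < 0.05


def test_tether_pixel_mapping_round_trip():
    t = ks.TetherModel()
    assert t.px_to_bp(t.bp_to_px(12345.0)) == pytest.approx(12345.0)


# ---------------------------------------------------------------------------
# binding events


def test_events_stay_on_tether_and_respect_confinement():
    for seed in range(10):
        tether, nucs = ks.simulate_tether(seed=seed)
        events = ks.simulate_events(tether, nucs, ks.ProteinConfig(),
                                    duration_s=20.0, seed=seed)
        for ev in events:
            assert ev.positions_bp.min() >= 0.0
            assert ev.positions_bp.max() <= tether.length_bp
            if ev.mode == "stable":
                assert np.ptp(ev.positions_bp) == 0.0


def test_stable_orc_attaches_to_nucleosomes_with_given_probability():
    hit = total = 0
    cfg = ks.ProteinConfig(p_orc_nuc_bind=0.95)
    for seed in range(150):
        tether, nucs = ks.simulate_tether(seed=seed)
        events = ks.simulate_events(tether, nucs, cfg, duration_s=20.0,
                                    seed=seed)
        occupied = {ev.nucleosome_index for ev in events
                    if ev.species == "ORC" and ev.mode == "stable"
                    and ev.nucleosome_index is not None}
        total += len(nucs)
        hit += len(occupied)
    frac = hit / total
    assert abs(frac - 0.95) < 0.03


# ---------------------------------------------------------------------------
# photobleaching traces


def test_bleach_trace_visible_fraction_matches_closed_form():
    model = ks.StoichModel(f_dh=0.79, p_label=0.6)
    _, truth = ks.simulate_bleach_traces(
        model, ks.PhotophysicsModel(bleach_rate_per_line=0.01), 20_000, 50,
        seed=3)
    f, p = 0.79, 0.6
    expected = f * (2 * p - p * p) + (1 - f) * p
    assert abs(truth.visible.mean() - expected) < 0.01


def test_bleach_trace_label_counts_follow_binomial_mixture():
    from scipy.stats import chisquare

    model = ks.StoichModel(f_dh=0.5, p_label=0.6)
    _, truth = ks.simulate_bleach_traces(
        model, ks.PhotophysicsModel(bleach_rate_per_line=0.01), 10_000, 50,
        seed=4)
    dh = truth[truth.is_dh]
    counts = dh.n_labeled.value_counts().reindex([0, 1, 2], fill_value=0)
    probs = np.array([0.4 ** 2, 2 * 0.6 * 0.4, 0.6 ** 2])
    stat, pval = chisquare(counts.to_numpy(), probs * len(dh))
    assert pval > 1e-4
    single = truth[~truth.is_dh]
    assert set(single.n_labeled.unique()) <= {0, 1}


def test_bleach_traces_are_deterministic_per_seed():
    model = ks.StoichModel()
    phot = ks.PhotophysicsModel(bleach_rate_per_line=0.01)
    a, _ = ks.simulate_bleach_traces(model, phot, 20, 50, seed=9)
    b, _ = ks.simulate_bleach_traces(model, phot, 20, 50, seed=9)
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# salt wash


def _mcm_events(n, n_lines=200, seed=0):
    rng = np.random.default_rng(seed)
    events = []
    for _ in range(n):
        anchor = float(rng.uniform(5000, 42_000))
        events.append(ks.BindingEvent(
            "MCM", "bare", "stable", anchor, 0, n_lines - 1,
            np.full(n_lines, anchor), n_hexamers=1,
            dye_states=[("far_red", True, None)]))
    return events


def test_salt_wash_outcome_fractions_match_plan():
    tether = ks.TetherModel(n_lines=200)
    plan = ks.SaltWashPlan(wash_line_index=100,
                           behavior_probs=(0.3, 0.3, 0.4))
    events = _mcm_events(3000, seed=5)
    washed = ks.apply_salt_wash(events, plan, tether, seed=6)
    n = len(washed)
    for label, expected in zip(("slide", "stay", "dissociate"),
                               (0.3, 0.3, 0.4)):
        frac = sum(e.salt_response == label for e in washed) / n
        assert abs(frac - expected) < 0.03


def test_salt_wash_rewrites_trajectories_consistently():
    tether = ks.TetherModel(n_lines=200)
    plan = ks.SaltWashPlan(wash_line_index=100)
    events = _mcm_events(200, seed=1)
    washed = ks.apply_salt_wash(events, plan, tether, seed=2)
    for old, new in zip(events, washed):
        # pre-wash positions are never altered
        np.testing.assert_array_equal(new.positions_bp[:101],
                                      old.positions_bp[:101])
        if new.salt_response == "dissociate":
            assert new.end_line == 100
            assert new.positions_bp.size == 101
        elif new.salt_response == "stay":
            np.testing.assert_array_equal(new.positions_bp,
                                          old.positions_bp)
        else:
            assert new.mode == "diffusive"
            assert new.positions_bp.size == old.positions_bp.size
    # inputs not mutated
    assert all(e.salt_response is None for e in events)


def test_salt_wash_leaves_orc_and_prewash_events_alone():
    tether = ks.TetherModel(n_lines=200)
    plan = ks.SaltWashPlan(wash_line_index=100)
    orc = ks.BindingEvent("ORC", "nucleosome", "stable", 10_000.0, 0, 199,
                          np.full(200, 10_000.0),
                          dye_states=[("red", True, None)])
    gone = ks.BindingEvent("MCM", "bare", "stable", 20_000.0, 0, 50,
                           np.full(51, 20_000.0),
                           dye_states=[("far_red", True, None)])
    washed = ks.apply_salt_wash([orc, gone], plan, tether, seed=0)
    assert washed[0] is orc and washed[1] is gone


# ---------------------------------------------------------------------------
# rendering


def test_render_background_only_without_emitters():
    tether = ks.TetherModel(n_lines=100)
    nucs = ks.NucleosomeSet(np.array([]), [], np.array([], dtype=bool))
    phot = ks.PhotophysicsModel(background_per_pixel=20.0)
    stack = ks.render_kymograph(tether, [], nucs, phot, seed=0)
    for img in stack.channels.values():
        assert abs(img.mean() - 20.0) < 0.5


def test_render_centroid_matches_truth_position():
    tether = ks.TetherModel(n_lines=100)
    nucs = ks.NucleosomeSet(np.array([]), [], np.array([], dtype=bool))
    truth_bp = 20_000.0
    ev = ks.BindingEvent("ORC", "bare", "stable", truth_bp, 0, 99,
                         np.full(100, truth_bp),
                         dye_states=[("red", True, None)])
    phot = ks.PhotophysicsModel(photons_per_fluor_per_line=100_000.0,
                                background_per_pixel=5.0,
                                bleach_rate_per_line=0.0)
    stack = ks.render_kymograph(tether, [ev], nucs, phot, seed=1)
    img = stack.channels["red"] - 5.0
    cols = np.arange(img.shape[1])
    truth_px = tether.bp_to_px(truth_bp)
    for line in range(0, 100, 10):
        w = np.clip(img[line], 0, None)
        centroid = (w * cols).sum() / w.sum()
        assert abs(centroid - truth_px) < 0.1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=hst.integers(min_value=0, max_value=10_000))
def test_licensing_experiment_shapes_are_consistent(seed):
    stack, events, nucs = ks.simulate_licensing_experiment(seed=seed)
    width = int(np.ceil(stack.tether.length_bp / stack.tether.bp_per_pixel))
    for img in stack.channels.values():
        assert img.shape == (stack.tether.n_lines, width)
        assert np.all(img >= 0)
    assert 1 <= len(nucs) <= 7
    for ev in events:
        assert ev.positions_bp.size == ev.end_line - ev.start_line + 1
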