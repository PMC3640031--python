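"""Response scores, Stage-1/Stage-2 calling rules, spike rescaling."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import percentile_linear, trimmed_mean_by_sort
from brulechip.calling import (
    ArchaeaThresholds,
    BacteriaThresholds,
    CallingThresholds,
    adjusted_q3,
    call_otus,
    response_scores,
    spike_scale,
    spike_scale_factors,
    stage1_call,
    stage1_metrics,
    trimmed_mean,
)
from brulechip.model import ArrayExperiment, Stage1Metrics
from brulechip.simulate import SimulationConfig, simulate_array
from conftest import noise_free_config


# ---------------------------------------------------------------------------
# Response scores
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pm,mm,expected",
    [
        (50.0, 50.0, 0.0),  # PM = MM -> 0
        (99.0, 1.0, 0.98),  # closed form
        (10.0, 90.0, 0.0),  # MM > PM clipped to 0
    ],
)
def test_response_score_values(pm, mm, expected):
    scores, usable, scored = response_scores([pm], [mm], background=0.0)
    assert scores[0] == pytest.approx(expected)
    assert usable[0] and scored[0]


def test_zero_total_pair_is_unscorable():
    scores, usable, scored = response_scores([0.0], [0.0], background=-1.0)
    assert np.isnan(scores[0]) and usable[0] and not scored[0]


def test_background_and_saturation_gate_usability():
    scores, usable, _ = response_scores([5.0, 50.0, 500.0], [1.0, 1.0, 1.0],
                                        background=10.0, saturation=400.0)
    assert list(usable) == [False, True, False]


# ---------------------------------------------------------------------------
# Stage-1 metrics and calls
# ---------------------------------------------------------------------------


def test_constant_scores_give_unit_quantiles():
    m = stage1_metrics(np.ones(10), np.ones(10, dtype=bool))
    assert (m.q1, m.q2, m.q3) == (1.0, 1.0, 1.0)
    assert m.pairs_counted == m.pairs_scored == 10


def test_six_usable_pairs_fail_the_count_rule():
    m = stage1_metrics(np.ones(6), np.ones(6, dtype=bool))
    assert m.pairs_counted == 6
    assert not stage1_call(m, "bacteria", CallingThresholds())


def test_zero_usable_pairs_never_raise():
    m = stage1_metrics(np.array([0.5, 0.5]), np.zeros(2, dtype=bool))
    assert m.pairs_counted == 0 and np.isnan(m.q2)
    assert not stage1_call(m, "bacteria", CallingThresholds())
    assert not stage1_call(m, "archaea", CallingThresholds())


def test_quantiles_match_brute_force_oracle():
    rng = np.random.default_rng(12)
    for _ in range(100):
        n = int(rng.integers(1, 20))
        vals = rng.uniform(0, 1, n)
        m = stage1_metrics(vals, np.ones(n, dtype=bool))
        for q, frac in ((m.q1, 0.25), (m.q2, 0.5), (m.q3, 0.75)):
            assert q == pytest.approx(percentile_linear(vals, frac))


def test_bacterial_boundaries_are_inclusive():
    thr = CallingThresholds()
    at_boundary = Stage1Metrics(7, 7, 0.5, 0.93, 0.98)
    assert stage1_call(at_boundary, "bacteria", thr)
    below = Stage1Metrics(7, 7, 0.5, 0.93, 0.979)
    assert not stage1_call(below, "bacteria", thr)


def test_archaeal_rule_uses_intensity_gate():
    thr = CallingThresholds()
    m = Stage1Metrics(7, 7, 0.6, 0.85, 0.95)
    # q cutoffs pass, but no sample reached the trimmed-mean floor
    assert not stage1_call(m, "archaea", thr, archaea_eligible=False)
    assert stage1_call(m, "archaea", thr, archaea_eligible=True)
    # the loosened cutoffs are still cutoffs
    assert not stage1_call(Stage1Metrics(7, 7, 0.6, 0.79, 0.95), "archaea", thr)


def test_unknown_domain_rejected():
    with pytest.raises(ValueError):
        stage1_call(Stage1Metrics(7, 7, 1, 1, 1), "eukaryote", CallingThresholds())


# ---------------------------------------------------------------------------
# Trimmed mean
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "values,expected",
    [([1000, 2000, 3000], 2000.0), ([7, 7, 7, 7], 7.0), ([5, 1, 9, 7, 3], 5.0), ([4, 8], 6.0)],
)
def test_trimmed_mean_examples(values, expected):
    assert trimmed_mean(np.array(values, dtype=float)) == pytest.approx(expected)


def test_trimmed_mean_empty_rejected():
    with pytest.raises(ValueError):
        trimmed_mean(np.array([]))


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=3, max_size=30))
def test_trimmed_mean_matches_sort_oracle(values):
    assert trimmed_mean(np.array(values)) == pytest.approx(trimmed_mean_by_sort(values))


# ---------------------------------------------------------------------------
# Cross-hyb adjustment
# ---------------------------------------------------------------------------


def test_adjusted_q3_identity_without_flags():
    rng = np.random.default_rng(1)
    scores = rng.uniform(0, 1, 12)
    usable = np.ones(12, dtype=bool)
    assert adjusted_q3(scores, usable, np.zeros(12, dtype=bool)) == pytest.approx(
        np.percentile(scores, 75)
    )


def test_adjusted_q3_zero_when_all_flagged():
    assert adjusted_q3(np.ones(5), np.ones(5, dtype=bool), np.ones(5, dtype=bool)) == 0.0


def test_adjusted_q3_matches_subset_percentile_oracle():
    rng = np.random.default_rng(2)
    for _ in range(100):
        n = int(rng.integers(4, 16))
        scores = rng.uniform(0, 1, n)
        usable = rng.random(n) < 0.8
        flagged = rng.random(n) < 0.5
        keep = usable & ~flagged
        expected = percentile_linear(scores[keep], 0.75) if keep.any() else 0.0
        assert adjusted_q3(scores, usable, flagged) == pytest.approx(expected)


def test_stage2_removes_crosshyb_only_support(small_noisy_sim):
    library, _, exp, _ = small_noisy_sim
    calls = call_otus(exp, library)
    df = calls.calls
    # Stage 2 never adds calls
    assert not (df["present"] & ~df["stage1_present"]).any()
    # with the crosshyb map emptied, Stage 2 is the identity on Stage 1
    bare = dataclasses.replace(library, crosshyb={})
    calls_bare = call_otus(exp, bare).calls
    assert (calls_bare["present"] == calls_bare["stage1_present"]).all()
    assert np.allclose(calls_bare["q3_adjusted"], calls_bare["q3"], equal_nan=True)


# ---------------------------------------------------------------------------
# Spike scaling
# ---------------------------------------------------------------------------


def _experiment(matrix, design):
    return ArrayExperiment(matrix, design)


def test_spike_scale_identity_when_already_equal(toy_library, design_3v3):
    probes = toy_library.all_probe_ids()
    rng = np.random.default_rng(3)
    mat = pd.DataFrame(rng.uniform(10, 100, (len(probes), 6)),
                       index=pd.Index(probes, name="probe_id"), columns=list(design_3v3.index))
    mat.loc[toy_library.spike_probes] = 50.0
    exp = _experiment(mat, design_3v3)
    factors = spike_scale_factors(exp, toy_library)
    assert np.allclose(factors, 1.0)
    pd.testing.assert_frame_equal(spike_scale(exp, toy_library).intensities, mat)


def test_spike_scale_restores_doubled_sample(toy_library, design_3v3):
    probes = toy_library.all_probe_ids()
    mat = pd.DataFrame(30.0, index=pd.Index(probes, name="probe_id"), columns=list(design_3v3.index))
    mat["In_2"] = 60.0  # whole array doubled, spikes included
    exp = _experiment(mat, design_3v3)
    scaled = spike_scale(exp, toy_library)
    means = scaled.intensities.loc[toy_library.spike_probes].mean()
    assert means.std() / means.mean() < 1e-9
    # grand-mean ratio: spike means (30x5, 60) -> grand mean 35
    assert spike_scale_factors(exp, toy_library)["In_2"] == pytest.approx(35.0 / 60.0)


def test_spike_scale_postcondition_on_random_jitter():
    cfg = SimulationConfig(seed=8, n_phyla=2, otus_per_phylum=5, array_scale_jitter=0.5)
    library, _, exp, _ = simulate_array(cfg)
    scaled = spike_scale(exp, library)
    means = scaled.intensities.loc[library.spike_probes].mean()
    assert means.std() / means.mean() < 1e-9
    twice = spike_scale(scaled, library)
    assert np.allclose(twice.intensities, scaled.intensities, rtol=1e-9)


def test_spike_scale_requires_positive_spikes(toy_library, design_3v3):
    probes = toy_library.all_probe_ids()
    mat = pd.DataFrame(30.0, index=pd.Index(probes, name="probe_id"), columns=list(design_3v3.index))
    mat.loc[toy_library.spike_probes, "Out_3"] = 0.0
    with pytest.raises(ValueError):
        spike_scale(_experiment(mat, design_3v3), toy_library)


# ---------------------------------------------------------------------------
# Whole-pipeline properties
# ---------------------------------------------------------------------------


def test_raising_thresholds_never_adds_calls(small_noisy_sim):
    library, _, exp, _ = small_noisy_sim
    base = call_otus(exp, library)
    n_base = int(base.calls["present"].sum())
    for field, value in (("q1_min", 0.9), ("q2_min", 0.99), ("q3_min", 0.999),
                         ("min_pairs_counted", 13)):
        thr = CallingThresholds(bacteria=BacteriaThresholds(**{field: value}))
        stricter = call_otus(exp, library, thr)
        assert int(stricter.calls["present"].sum()) <= n_base


def test_noise_free_recovery_small_sweep():
    rng = np.random.default_rng(20)
    for _ in range(10):
        cfg = noise_free_config(int(rng.integers(2**31)), rng)
        library, _, exp, truth = simulate_array(cfg)
        calls = call_otus(exp, library)
        pres = calls.presence().loc[truth.presence.index, truth.presence.columns]
        assert (pres == truth.presence).all().all()
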