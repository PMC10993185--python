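"""Synthetic session generator: sampling model, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

from gazenet import (
    MarkovAttentionModel,
    SessionConfig,
    build_network,
    clean_samples,
    classroom_model,
    classroom_scene,
    extract_transitions,
    raycast_samples,
    sample_attention_sequence,
    separated_scene,
    synthesize_session,
    uniform_model,
)


class TestMarkovModel:
    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            MarkovAttentionModel(["A", "B"], [[0.5, 0.5], [1.0, 0.0]])

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MarkovAttentionModel(["A", "B"], [[0.0, 0.9], [1.0, 0.0]])

    def test_forced_chain_alternates_strictly(self):
        model = MarkovAttentionModel(["A", "B"], [[0, 1], [1, 0]], dwell_mean_ms=100, dwell_sd_ms=10)
        seq = sample_attention_sequence(model, 5000, seed=3)
        names = [s for s, _ in seq]
        assert all(a != b for a, b in zip(names, names[1:]))
        assert set(names) == {"A", "B"}

    def test_sequence_deterministic_under_seed(self):
        model = uniform_model(["A", "B", "C"])
        assert sample_attention_sequence(model, 60000, seed=5) == sample_attention_sequence(
            model, 60000, seed=5
        )

    def test_dwell_truncation_and_total_duration(self):
        model = uniform_model(["A", "B"], dwell_mean_ms=50, dwell_sd_ms=200)
        seq = sample_attention_sequence(model, 10000, seed=1)
        dwells = np.array([d for _, d in seq])
        assert (dwells >= 0).all() and (dwells[:-1] >= model.min_dwell_ms).all()
        assert dwells.sum() == pytest.approx(10000)


class TestSynthesizeSession:
    def test_fixed_rate_row_count_law(self):
        """duration_s * fps rows exactly: 60 s at 40 fps -> 2400."""
        cfg = SessionConfig(
            scene=separated_scene(3), model=uniform_model(["ooi_0", "ooi_1", "ooi_2"]),
            duration_s=60, seed=0,
        )
        raw, _ = synthesize_session(cfg)
        assert len(raw) == 2400
        assert np.allclose(np.diff(raw["time_ms"]), 25.0)

    def test_deterministic_under_seed(self):
        cfg = dict(scene=separated_scene(3), model=uniform_model(["ooi_0", "ooi_1", "ooi_2"]),
                   duration_s=10, seed=9)
        raw1, _ = synthesize_session(SessionConfig(**cfg))
        raw2, _ = synthesize_session(SessionConfig(**cfg))
        pd.testing.assert_frame_equal(raw1, raw2)

    def test_invalid_rate_marks_pupils_only(self):
        cfg = SessionConfig(
            scene=separated_scene(3), model=uniform_model(["ooi_0", "ooi_1", "ooi_2"]),
            duration_s=30, seed=2, invalid_rate=0.3,
        )
        raw, _ = synthesize_session(cfg)
        invalid = raw["pupil_left_mm"] == -1
        assert 0.2 < invalid.mean() < 0.4
        assert (raw.loc[invalid, "pupil_right_mm"] == -1).all()
        # gaze geometry is still present on invalid frames
        assert np.isfinite(raw.loc[invalid, ["gaze_x", "gaze_y", "gaze_z"]]).all().all()

    def test_zero_invalid_rate_cleans_nothing(self):
        cfg = SessionConfig(
            scene=separated_scene(3), model=uniform_model(["ooi_0", "ooi_1", "ooi_2"]),
            duration_s=10, seed=4, invalid_rate=0.0,
        )
        raw, _ = synthesize_session(cfg)
        _, dropped = clean_samples(raw)
        assert dropped == 0

    def test_noiseless_raycast_recovers_true_target_every_frame(self):
        """With zero gaze noise and well-separated OOIs the ray caster
        reproduces the ground-truth attended object frame by frame."""
        scene = separated_scene(3)
        cfg = SessionConfig(
            scene=scene, model=uniform_model(scene.names), duration_s=30,
            seed=6, gaze_noise_deg=0.0, invalid_rate=0.0,
        )
        raw, truth = synthesize_session(cfg)
        labelled = raycast_samples(raw, scene)
        starts = truth.segments["t_start_ms"].to_numpy()
        idx = np.minimum(
            np.searchsorted(starts, raw["time_ms"].to_numpy(), side="right") - 1,
            len(starts) - 1,
        )
        expected = truth.segments["ooi"].to_numpy()[idx]
        assert (labelled["gaze_target"].to_numpy() == expected).all()

    def test_ground_truth_counts_match_segments(self):
        cfg = SessionConfig(
            scene=separated_scene(3), model=uniform_model(["ooi_0", "ooi_1", "ooi_2"]),
            duration_s=60, seed=8,
        )
        _, truth = synthesize_session(cfg)
        assert truth.transition_counts["count"].sum() == len(truth.segments) - 1

    def test_jittered_mode_keeps_mean_rate(self):
        cfg = SessionConfig(
            scene=separated_scene(3), model=uniform_model(["ooi_0", "ooi_1", "ooi_2"]),
            duration_s=120, seed=1, fixed_rate=False,
        )
        raw, _ = synthesize_session(cfg)
        dt = np.diff(raw["time_ms"])
        assert (dt > 0).all()
        assert dt.mean() == pytest.approx(25.0, rel=0.1)

    def test_config_validation(self):
        scene = separated_scene(3)
        model = uniform_model(["ooi_0", "ooi_9"])  # ooi_9 not in scene
        with pytest.raises(ValueError, match="not in scene"):
            SessionConfig(scene=scene, model=model)
        with pytest.raises(ValueError):
            SessionConfig(scene=scene, model=uniform_model(scene.names), invalid_rate=1.5)


def test_markov_parameter_recovery_through_full_pipeline():
    """A seeded half-hour 3-OOI session pushed through raycast -> clean ->
    transitions -> network recovers the row-normalized transition matrix
    within total-variation distance 0.05 per source state."""
    scene = separated_scene(3)
    probs = np.array([[0.0, 0.7, 0.3], [0.2, 0.0, 0.8], [0.5, 0.5, 0.0]])
    model = MarkovAttentionModel(scene.names, probs, dwell_mean_ms=800, dwell_sd_ms=400)
    cfg = SessionConfig(scene=scene, model=model, duration_s=1800, seed=123)
    raw, _ = synthesize_session(cfg)
    labelled = raycast_samples(raw, scene)
    clean, _ = clean_samples(labelled)
    table = extract_transitions(clean, scene.names, max_duration_ms=1000)
    net = build_network(table, nodes=scene.names)
    for i, src in enumerate(scene.names):
        out = {t: d["weight"] for _, t, d in net.graph.out_edges(src, data=True)}
        total = sum(out.values())
        assert total > 0
        tv = 0.5 * sum(
            abs(out.get(t, 0) / total - probs[i, j])
            for j, t in enumerate(scene.names)
            if t != src
        )
        assert tv < 0.05, f"TV distance {tv:.3f} for source {src}"


def test_classroom_defaults_consistent():
    scene = classroom_scene()
    model = classroom_model()
    assert set(model.states) == set(scene.names)
    assert np.allclose(model.transition_probs.sum(axis=1), 1.0)
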