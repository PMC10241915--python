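"""Generator: determinism, convergence monotonicity, raw-trace round trip."""

import json

import numpy as np
import pytest

from emglfm import (
    EmgTrace,
    GeneratorConfig,
    PhaseAnnotation,
    compute_envelope,
    generate_behavior,
    generate_study,
    lfm_r_squared,
    make_model_template,
    segment_phases,
    simulate_study,
    synthesize_raw_trace,
    synthesize_trainee_envelope,
    time_normalize,
)
from emglfm.emg_processing import PHASES
from emglfm.synthetic_data import _r2, subject_mixing


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_sessions": 1},
            {"mixing_schedule_aot": (0.2, 1.3, 0.4, 0.5, 0.6, 0.7)},
            {"envelope_noise_sd": -0.1},
            {"phase_duration_means": (1.0, 0.0, 1.0)},
            {"convergence_cells": (("ADM", "flying"),)},
            {"sampling_rate": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)

    def test_scalar_schedule_broadcasts(self):
        cfg = GeneratorConfig(mixing_schedule_ctrl=(0.4,))
        assert cfg.mixing_schedule_ctrl == (0.4,) * 6

    def test_unknown_group_rejected(self):
        cfg = GeneratorConfig()
        with pytest.raises(ValueError):
            cfg.mixing_schedule("PLACEBO")


class TestModelTemplate:
    def test_deterministic_per_seed(self):
        cfg = GeneratorConfig(seed=4)
        a, b = make_model_template(cfg), make_model_template(cfg)
        for key in a.curves:
            assert np.array_equal(a.curves[key], b.curves[key])

    def test_construction_invariants(self, templates):
        for curve in templates.curves.values():
            assert curve.shape == (100,)
            assert curve.min() >= 0
            assert curve.std() / curve.mean() > 0.1

    def test_templates_mutually_distinct(self, templates):
        keys = list(templates.curves)
        for i, ki in enumerate(keys):
            for kj in keys[i + 1 :]:
                assert _r2(templates.curves[ki], templates.curves[kj]) < 0.9


class TestTraineeEnvelope:
    def test_pure_model_weight_reproduces_template(self, templates, rng):
        t = templates.curve("OP", "reaching")
        y = synthesize_trainee_envelope(t, 1.0, 0.0, np.zeros_like(t) + 0.1, rng)
        assert lfm_r_squared(y, t) == pytest.approx(1.0)

    def test_orthogonalized_idiosyncratic_scores_zero(self, templates, rng):
        t = templates.curve("OP", "reaching")
        i = templates.curve("FDI", "transport").copy()
        tc = t - t.mean()
        i_perp = i - np.dot(i - i.mean(), tc) / np.dot(tc, tc) * tc
        i_perp = i_perp - i_perp.min() + 0.01  # restore positivity
        y = synthesize_trainee_envelope(t, 0.0, 0.0, i_perp, rng)
        assert lfm_r_squared(y, t) < 1e-10

    def test_expected_similarity_monotone_in_w(self, templates):
        """Monte-Carlo: mean R² non-decreasing over w = 0, .25, .5, .75, 1."""
        t = templates.curve("FDI", "holding")
        rng = np.random.default_rng(77)
        from emglfm.synthetic_data import _bump_curve

        means = []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            r2s = []
            for _ in range(500):
                idio = _bump_curve(rng)
                y = synthesize_trainee_envelope(t, w, 0.05, idio, rng)
                r2s.append(lfm_r_squared(y, t))
            means.append(np.mean(r2s))
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_higher_weight_beats_lower_weight(self, templates):
        t = templates.curve("ADM", "reaching")
        rng = np.random.default_rng(5)
        from emglfm.synthetic_data import _bump_curve

        r_hi, r_lo = [], []
        for _ in range(200):
            idio = _bump_curve(rng)
            r_hi.append(lfm_r_squared(synthesize_trainee_envelope(t, 0.8, 0.05, idio, rng), t))
            r_lo.append(lfm_r_squared(synthesize_trainee_envelope(t, 0.4, 0.05, idio, rng), t))
        assert np.mean(r_hi) > np.mean(r_lo)

    def test_invalid_inputs_rejected(self, templates, rng):
        t = templates.curve("OP", "holding")
        with pytest.raises(ValueError):
            synthesize_trainee_envelope(t, 1.2, 0.0, t, rng)
        with pytest.raises(ValueError):
            synthesize_trainee_envelope(t, 0.5, -0.01, t, rng)


class TestRawTrace:
    def test_sample_count_arithmetic(self, templates, rng):
        envs = {p: templates.curve("OP", p) for p in PHASES}
        samples, events = synthesize_raw_trace(envs, (1.0, 0.5, 1.0), 2000.0, rng)
        assert samples.size == 5000
        assert events.place == pytest.approx(2.5)

    def test_deterministic_for_fixed_seed(self, templates):
        envs = {p: templates.curve("FDI", p) for p in PHASES}
        a, _ = synthesize_raw_trace(envs, (1.0, 0.6, 1.2), 2000.0, np.random.default_rng(3))
        b, _ = synthesize_raw_trace(envs, (1.0, 0.6, 1.2), 2000.0, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_constant_envelope_gives_flat_processed_envelope(self, rng):
        envs = {p: np.full(100, 0.5) for p in PHASES}
        samples, _ = synthesize_raw_trace(envs, (2.0, 2.0, 2.0), 2000.0, rng)
        env = compute_envelope(EmgTrace("s", 1, "OP", samples))
        interior = env[2000:-2000]
        assert interior.std() / interior.mean() < 0.2

    @pytest.mark.parametrize("muscle", ["OP", "FDI", "ADM"])
    def test_processing_chain_round_trip(self, templates, rng, muscle):
        """Noise-free modulated trace -> envelope chain -> R² ≥ 0.9 per phase.

        Phase durations of 1.5–2 s keep the curve features within the reach
        of the 2 Hz envelope low-pass; much shorter phases are smoothed by
        the chain itself.
        """
        envs = {p: templates.curve(muscle, p) for p in PHASES}
        samples, events = synthesize_raw_trace(envs, (2.0, 1.5, 2.0), 2000.0, rng)
        env = compute_envelope(EmgTrace("s", 1, muscle, samples))
        segs = segment_phases(env, 2000.0, PhaseAnnotation([events]))[0]
        for phase in PHASES:
            r2 = lfm_r_squared(time_normalize(segs[phase]), envs[phase])
            assert r2 >= 0.9

    def test_invalid_rate_rejected(self, templates, rng):
        envs = {p: templates.curve("OP", p) for p in PHASES}
        with pytest.raises(ValueError):
            synthesize_raw_trace(envs, (1.0, 1.0, 1.0), 0.0, rng)


class TestBehaviorGeneration:
    def test_zero_extra_rate_hits_floor(self):
        cfg = GeneratorConfig(ga_extra_start=0.0, fl_rate=0.0, seed=0)
        log = generate_behavior("AOT", 1, cfg, np.random.default_rng(0))
        assert sum(len(m.attempt_contacts) for m in log.marbles) == cfg.n_marbles

    def test_zero_decay_keeps_expected_ga_flat(self):
        cfg = GeneratorConfig(ga_decay_aot=0.0, seed=0)
        rng = np.random.default_rng(1)
        ga = {s: np.mean([
            sum(len(m.attempt_contacts) for m in generate_behavior("AOT", s, cfg, rng).marbles)
            for _ in range(200)]) for s in (1, 6)}
        assert ga[6] == pytest.approx(ga[1], rel=0.1)

    def test_aot_outperforms_ctrl_at_final_session(self):
        """Steeper AOT decay -> fewer S6 grasping attempts on average."""
        cfg = GeneratorConfig(seed=0)
        rng = np.random.default_rng(2)
        means = {}
        for group in ("AOT", "CTRL"):
            means[group] = np.mean([
                sum(len(m.attempt_contacts) for m in generate_behavior(group, 6, cfg, rng).marbles)
                for _ in range(100)])
        assert means["AOT"] < means["CTRL"]

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            generate_behavior("X", 1, GeneratorConfig(), np.random.default_rng(0))


class TestSimulatedStudy:
    def test_shapes_and_determinism(self):
        cfg = GeneratorConfig(n_per_group=3, seed=13)
        a, b = simulate_study(cfg), simulate_study(cfg)
        assert a.phase_curves.shape == (6, 6, 3, 3, 100)
        assert np.array_equal(a.phase_curves, b.phase_curves)
        assert a.behavior.equals(b.behavior)
        assert a.manifest.equals(b.manifest)

    def test_subject_gain_scales_mixing_rise(self):
        cfg = GeneratorConfig(seed=0)
        prof = simulate_study(GeneratorConfig(n_per_group=1, seed=0))
        from emglfm.synthetic_data import SubjectProfile

        strong = SubjectProfile("x", "AOT", 2.0, 1, 1, 1, 1)
        weak = SubjectProfile("y", "AOT", 0.5, 1, 1, 1, 1)
        ws, ww = subject_mixing(cfg, strong), subject_mixing(cfg, weak)
        assert ws[0] == ww[0] == cfg.mixing_schedule_aot[0]
        assert ws[-1] > ww[-1]
        assert ws.max() <= 1.0

    def test_flat_ctrl_schedule_gives_flat_group_similarity(self):
        """CTRL mean R² gain S6−S1 within ±2 SE of 0 across replicate studies."""
        from emglfm.pipeline import similarity_table

        gains = []
        for seed in range(30):
            study = simulate_study(GeneratorConfig(n_per_group=6, seed=seed))
            st = similarity_table(study)
            full = st[(st.scope == "full_trial") & (st.group == "CTRL")]
            m = full.groupby("session").r_squared.mean()
            gains.append(m[6] - m[1])
        se = np.std(gains, ddof=1) / np.sqrt(len(gains))
        assert abs(np.mean(gains)) < 2 * se + 1e-4


class TestBundle:
    def test_file_counts(self, tiny_bundle, tiny_config):
        n_subj = 2 * tiny_config.n_per_group
        traces = list((tiny_bundle / "traces").glob("*/S*/*.csv"))
        assert len(traces) == n_subj * tiny_config.n_sessions * 3
        assert len(list((tiny_bundle / "mvc").glob("*/*.csv"))) == n_subj * 3
        assert len(list((tiny_bundle / "events").glob("*/S*.json"))) == n_subj * tiny_config.n_sessions

    def test_manifest_deterministic(self, tiny_bundle, tiny_config, tmp_path):
        other = tmp_path / "again"
        generate_study(tiny_config, other)
        assert (other / "manifest.json").read_bytes() == (tiny_bundle / "manifest.json").read_bytes()

    def test_manifest_contents(self, tiny_bundle):
        with open(tiny_bundle / "manifest.json") as fh:
            man = json.load(fh)
        assert {s["group"] for s in man["subjects"]} == {"AOT", "CTRL"}
        assert all("age" in s for s in man["subjects"])
        assert set(man["mvc_truth"]) == {s["id"] for s in man["subjects"]}
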