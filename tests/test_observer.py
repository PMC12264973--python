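"""Virtual observers, confusion/bias analysis, and motion-energy drift."""

import itertools

import numpy as np
import pytest

import spvsim
from spvsim.pipeline import TrialRecord, _make_stimulus

from conftest import fast_config


def _records(task, pairs):
    labels = spvsim.OPTOTYPE_LETTERS if task == "letter" else tuple(spvsim.BAR_DIRECTIONS)
    out = []
    for t, (stim, choice) in enumerate(pairs):
        out.append(
            TrialRecord(
                trial=t, block=t // 8, task=task, condition="x",
                stimulus=stim, choice=choice, correct=stim == choice, seed=0,
            )
        )
    return out


class TestTemplateObserver:
    def test_template_matches_itself(self):
        # letters sized to the implant field so all 8 templates are distinct
        cfg = fast_config(
            raster_pattern="none", temporal_enabled=False, letter_size_deg=18.0
        )
        sim = spvsim.Simulator(cfg)
        bank = spvsim.render_template_bank(sim, "letter")
        for label, tpl in bank.items():
            clip = spvsim.PerceptClip(
                frames=tpl[None], render_rate_hz=90.0,
                extent_deg=cfg.percept_grid_extent_deg, n_groups=1,
                frames_per_group=1, cycle_index=np.zeros(1, int),
                raster_frame=np.zeros(1, int),
            )
            assert spvsim.template_observer(clip, bank) == label

    def test_near_veridical_limit_all_letters_correct(self):
        """Tight phosphenes (ρ=100 µm, λ→0), no raster, no temporal decay,
        letters sized to the array's field of view: the template observer
        identifies all 8 letters."""
        cfg = fast_config(
            raster_pattern="none", temporal_enabled=False,
            rho_um=100.0, lam_um=1.0, letter_size_deg=18.0,
            stimulus_duration_s=0.1,
        )
        sim = spvsim.Simulator(cfg)
        bank = spvsim.render_template_bank(sim, "letter")
        for L in spvsim.OPTOTYPE_LETTERS:
            clip = sim.run(_make_stimulus("letter", L, cfg), None, temporal_enabled=False)
            assert spvsim.template_observer(clip, bank) == L

    def test_zero_percept_falls_to_first_alternative(self):
        cfg = fast_config(raster_pattern="none", temporal_enabled=False)
        sim = spvsim.Simulator(cfg)
        bank = spvsim.render_template_bank(sim, "letter")
        clip = spvsim.PerceptClip(
            frames=np.zeros((3, 49, 49), np.float32), render_rate_hz=90.0,
            extent_deg=12.0, n_groups=1, frames_per_group=1,
            cycle_index=np.zeros(3, int), raster_frame=np.zeros(3, int),
        )
        assert spvsim.template_observer(clip, bank) == "C"

    def test_empty_clip_rejected(self):
        clip = spvsim.PerceptClip(
            frames=np.zeros((0, 4, 4), np.float32), render_rate_hz=90.0,
            extent_deg=12.0, n_groups=1, frames_per_group=1,
            cycle_index=np.zeros(0, int), raster_frame=np.zeros(0, int),
        )
        with pytest.raises(ValueError):
            spvsim.template_observer(clip, {"C": np.zeros((4, 4))})


class TestRandomObserver:
    def test_chance_level_within_3_sigma(self):
        """Analytic chance is 1/8; 10⁵ seeded draws stay in the binomial band."""
        stream = spvsim.random_observer(8, seed=123)
        n = 100_000
        hits = sum(next(stream) == 0 for _ in range(n))
        p = 1 / 8
        assert abs(hits / n - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_same_seed_same_stream(self):
        a = spvsim.random_observer(8, seed=5)
        b = spvsim.random_observer(8, seed=5)
        assert [next(a) for _ in range(50)] == [next(b) for _ in range(50)]


class TestMotionEnergy:
    @staticmethod
    def _clip(frames, cycles=None):
        frames = np.asarray(frames, np.float32)
        T = len(frames)
        return spvsim.PerceptClip(
            frames=frames, render_rate_hz=90.0, extent_deg=12.0, n_groups=1,
            frames_per_group=1,
            cycle_index=np.zeros(T, int) if cycles is None else cycles,
            raster_frame=np.zeros(T, int),
        )

    def test_static_uniform_clip_zero_drift(self):
        clip = self._clip(np.full((10, 33, 33), 0.5))
        assert np.allclose(spvsim.motion_energy(clip), 0.0)

    def test_rightward_bar_positive_x_drift(self):
        cfg = fast_config(raster_pattern="none", stimulus_duration_s=1.0)
        sim = spvsim.Simulator(cfg)
        clip = sim.run(_make_stimulus("motion", "right", cfg), None)
        v = spvsim.motion_energy(clip)
        assert v[0] > 0 and abs(v[1]) < abs(v[0])

    @pytest.mark.parametrize("direction", list(spvsim.BAR_DIRECTIONS))
    def test_all_8_directions_within_45_degrees(self, direction):
        cfg = fast_config(raster_pattern="none", stimulus_duration_s=1.0)
        sim = spvsim.Simulator(cfg)
        clip = sim.run(_make_stimulus("motion", direction, cfg), None)
        v = spvsim.motion_energy(clip)
        u = np.array(spvsim.BAR_DIRECTIONS[direction])
        cos = v @ u / np.linalg.norm(v)
        assert cos > np.cos(np.deg2rad(45))
        assert spvsim.motion_observer(clip) == direction

    def test_static_letter_linear_rasters_drift_more_than_checkerboard(self):
        """Simulator-level apparent-motion bias: scanning rasters drag a
        static percept along the scan axis; the checkerboard does not."""
        drifts = {}
        for pattern in ("horizontal", "vertical", "checkerboard"):
            cfg = fast_config(raster_pattern=pattern, stimulus_duration_s=1.0)
            sim = spvsim.Simulator(cfg)
            clip = sim.run(_make_stimulus("letter", "E", cfg), None)
            drifts[pattern] = np.linalg.norm(spvsim.motion_energy(clip))
        assert drifts["horizontal"] > drifts["checkerboard"]
        assert drifts["vertical"] > drifts["checkerboard"]

    def test_cycle_wrap_pairs_excluded(self):
        # two "cycles": constant within each, a jump across the boundary
        frames = np.zeros((4, 9, 9), np.float32)
        frames[:2, 2, 2] = 1.0
        frames[2:, 6, 6] = 1.0
        cycles = np.array([0, 0, 1, 1])
        assert np.allclose(spvsim.motion_energy(self._clip(frames, cycles)), 0.0)

    def test_phase_method_agrees_on_translating_blob(self):
        x = np.arange(64)
        frames = []
        for t in range(8):
            xx, yy = np.meshgrid(x, x)
            frames.append(np.exp(-((xx - 20 - 2 * t) ** 2 + (yy - 32) ** 2) / 40.0))
        clip = self._clip(np.array(frames))
        vc = spvsim.motion_energy(clip, method="centroid")
        vp = spvsim.motion_energy(clip, method="phase")
        assert vc[0] > 0 and vp[0] > 0
        assert np.allclose(vc, vp, rtol=0.2, atol=1.0)


class TestConfusionAndBias:
    def test_perfect_observer_identity_matrix(self):
        pairs = [(L, L) for L in spvsim.OPTOTYPE_LETTERS] * 6
        mat, bias = spvsim.confusion_and_bias(_records("letter", pairs))
        assert np.array_equal(np.diag(mat.values), [6] * 8)
        assert mat.values.sum() == 48
        assert np.all(bias.values == 0.0)

    def test_row_sums_equal_trials_per_stimulus(self):
        plan = [(lab, "C") for _, lab in spvsim.make_trial_plan("letter", 6, 1)]
        mat, _ = spvsim.confusion_and_bias(_records("letter", plan))
        assert np.all(mat.sum(axis=1).values == 6)

    def test_uniform_random_responder_bias_near_one_eighth(self):
        rng = np.random.default_rng(17)
        letters = spvsim.OPTOTYPE_LETTERS
        pairs = [
            (letters[rng.integers(8)], letters[rng.integers(8)]) for _ in range(20000)
        ]
        _, bias = spvsim.confusion_and_bias(_records("letter", pairs))
        assert np.all(np.abs(bias.values - 1 / 8) < 0.012)  # ~3σ at n≈17500 errors

    def test_mixed_tasks_rejected(self):
        recs = _records("letter", [("C", "C")]) + _records("motion", [("up", "up")])
        with pytest.raises(ValueError):
            spvsim.confusion_and_bias(recs)

    def test_count_conservation(self):
        cfg = fast_config(stimulus_duration_s=0.2, seed=6)
        recs = spvsim.run_experiment("letter", cfg, n_blocks=2, observer="random")
        mat, _ = spvsim.confusion_and_bias(recs)
        assert mat.values.sum() == len(recs) == 16
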