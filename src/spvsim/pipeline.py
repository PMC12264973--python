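"""End-to-end simulation: stimulus → percept, and full virtual experiments.

Per render frame (90 Hz by default): preprocess the stimulus frame → apply
the gaze-contingent shift → select the active raster group from the frame
clock → sample electrode activations → axon-map spatial percept → one Euler
step of the temporal model → record the brightness field.  Experiments
reproduce the trial structure of the behavioural tasks: per condition,
6 blocks × 8 stimuli = 48 trials, each block a seeded permutation of the
eight alternatives, scored by a virtual observer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import observer as obs
from .config import SimConfig, save_config
from .engine import SpatialModel, TemporalParams, electrode_activation
from .errors import ConfigurationError
from .raster import RasterClock, make_schedule
from .retina import (
    AxonMapParams,
    RetinaSpec,
    build_axon_map,
    build_electrode_array,
    check_field_coverage,
)
from .stimulus import (
    BAR_DIRECTIONS,
    OPTOTYPE_LETTERS,
    GazeTrace,
    StimulusClip,
    apply_gaze_shift,
    preprocess_frame,
    render_moving_bar,
    render_optotype,
    simulate_gaze,
)

__all__ = [
    "PerceptClip",
    "TrialRecord",
    "Simulator",
    "run_simulation",
    "make_trial_plan",
    "run_experiment",
    "write_outputs",
    "read_records",
]

TASK_LABELS = {"letter": OPTOTYPE_LETTERS, "motion": tuple(BAR_DIRECTIONS)}


@dataclass(frozen=True)
class PerceptClip:
    """Rendered brightness frames at the render rate, with clock metadata.

    ``cycle_index``/``raster_frame`` attribute every render frame to its
    raster cycle and raster frame (all zeros when rastering is off), letting
    metrics exclude cycle-wrap artifacts.
    """

    frames: np.ndarray  # (T, ny, nx) float32 brightness (pre-display gain)
    render_rate_hz: float
    extent_deg: float
    n_groups: int
    frames_per_group: int
    cycle_index: np.ndarray
    raster_frame: np.ndarray
    label: str = ""

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.render_rate_hz


@dataclass(frozen=True)
class TrialRecord:
    """One 8AFC trial of a virtual experiment."""

    trial: int
    block: int
    task: str
    condition: str
    stimulus: str
    choice: str
    correct: bool
    seed: int


class Simulator:
    """Holds the expensive per-configuration state (axon map, Gaussian bases,
    schedule) so many clips can be rendered against one configuration."""

    def __init__(self, cfg: SimConfig) -> None:
        cfg.validate()
        self.cfg = cfg
        self.spec = RetinaSpec(
            um_per_degree=cfg.um_per_degree,
            percept_grid_extent_deg=cfg.percept_grid_extent_deg,
            percept_grid_step_deg=cfg.percept_grid_step_deg,
        )
        self.array = build_electrode_array(cfg.rows, cfg.cols, cfg.pitch_um, cfg.center_um)
        check_field_coverage(self.spec, self.array, cfg.rho_um)
        self.axon_map = build_axon_map(self.spec, cfg.n_axons, cfg.axon_step_um)
        self.spatial = SpatialModel(
            self.array, self.axon_map, AxonMapParams(cfg.rho_um, cfg.lam_um)
        )
        self.clock = RasterClock(cfg.render_rate_hz, cfg.group_interval_ms)
        self.schedule = make_schedule(
            cfg.raster_pattern, self.array, cfg.n_groups, cfg.reshuffle_every, cfg.seed
        )
        self.temporal = TemporalParams.preset(cfg.temporal_preset)

    def active_for_frame(self, t: int) -> np.ndarray | None:
        """Electrode indices active on render frame ``t`` (None = all)."""
        if self.schedule is None:
            return None
        raster_frame = t // self.clock.frames_per_group
        return self.schedule.active_electrodes(raster_frame)

    def run(
        self,
        stimulus: StimulusClip,
        gaze: GazeTrace | None = None,
        temporal_enabled: bool | None = None,
    ) -> PerceptClip:
        cfg = self.cfg
        if temporal_enabled is None:
            temporal_enabled = cfg.temporal_enabled
        rate = cfg.render_rate_hz
        n_frames = max(int(round(stimulus.duration_s * rate)), 1)
        dt = 1.0 / rate
        fpg = self.clock.frames_per_group
        n_groups = self.schedule.n_groups if self.schedule is not None else 1
        ny, nx = self.spec.grid_shape
        out = np.empty((n_frames, ny, nx), dtype=np.float32)
        cyc = np.zeros(n_frames, dtype=int)
        rfr = np.zeros(n_frames, dtype=int)
        n_state = np.zeros(ny * nx)
        b_state = np.zeros(ny * nx)
        p = self.temporal
        last_stim_idx, pre = -1, None
        for t in range(n_frames):
            # nearest stimulus frame; preprocessing cached per source frame
            s_idx = min(int(round(t * stimulus.fps / rate)), len(stimulus.frames) - 1)
            if s_idx != last_stim_idx:
                pre = preprocess_frame(stimulus.frames[s_idx])
                last_stim_idx = s_idx
            frame = pre
            if gaze is not None:
                frame = apply_gaze_shift(frame, gaze.at_time(t * dt), cfg.frame_fov_deg)
            active = self.active_for_frame(t)
            if self.schedule is not None:
                rfr[t] = t // fpg
                cyc[t] = rfr[t] // n_groups
            amps = electrode_activation(
                frame, self.array, active, self.spec, cfg.frame_fov_deg
            )
            b_I = self.spatial.evaluate(amps).ravel()
            if temporal_enabled:
                n_state = n_state + dt * (-p.tau_n * n_state + b_I)
                b_state = np.maximum(
                    b_state + dt * (-p.tau_b * b_state - p.alpha * n_state + b_I), 0.0
                )
            else:
                b_state = b_I
            out[t] = b_state.reshape(ny, nx).astype(np.float32)
        return PerceptClip(
            frames=out,
            render_rate_hz=rate,
            extent_deg=cfg.percept_grid_extent_deg,
            n_groups=n_groups,
            frames_per_group=fpg,
            cycle_index=cyc,
            raster_frame=rfr,
            label=stimulus.label,
        )


def run_simulation(
    stimulus: StimulusClip, gaze: GazeTrace | None, cfg: SimConfig
) -> PerceptClip:
    """Convenience wrapper: build a :class:`Simulator` for ``cfg`` and render
    one stimulus clip."""
    return Simulator(cfg).run(stimulus, gaze)


def make_trial_plan(task: str, n_blocks: int = 6, seed: int = 0) -> list:
    """Blocked stimulus order: each block is a seeded random permutation of
    the eight alternatives.  Returns a list of (block, label) pairs."""
    if task not in TASK_LABELS:
        raise ConfigurationError(f"unknown task {task!r}; choose from {tuple(TASK_LABELS)}")
    labels = TASK_LABELS[task]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB10C)))
    plan = []
    for b in range(n_blocks):
        for lab in rng.permutation(labels):
            plan.append((b, str(lab)))
    return plan


def _make_stimulus(task: str, label: str, cfg: SimConfig) -> StimulusClip:
    if task == "letter":
        return render_optotype(
            label,
            size_deg=cfg.letter_size_deg,
            field_deg=cfg.frame_fov_deg,
            duration_s=cfg.stimulus_duration_s,
            fps=cfg.render_rate_hz,
        )
    return render_moving_bar(
        label,
        duration_s=cfg.stimulus_duration_s,
        fps=cfg.render_rate_hz,
        field_deg=cfg.frame_fov_deg,
        bar_width_frac=cfg.bar_width_frac,
    )


def run_experiment(
    task: str,
    cfg: SimConfig,
    n_blocks: int = 6,
    observer: str = "template",
    seed: int | None = None,
    simulator: Simulator | None = None,
) -> list:
    """Run one condition of the 8AFC experiment with a virtual observer.

    The default 6 blocks × 8 stimuli give 48 trials.  The template observer's
    bank is rendered under the no-raster, temporal-off reference at the same
    ρ/λ, so the observer shares the signal's spatial distortions and only the
    raster manipulation differentiates conditions.
    """
    if task not in TASK_LABELS:
        raise ConfigurationError(f"unknown task {task!r}; choose from {tuple(TASK_LABELS)}")
    if observer not in ("template", "random"):
        raise ConfigurationError("observer must be 'template' or 'random'")
    if seed is None:
        seed = cfg.seed
    sim = simulator if simulator is not None else Simulator(cfg)
    plan = make_trial_plan(task, n_blocks, seed)
    bank = None
    if observer == "template" and task == "letter":
        bank = obs.render_template_bank(sim, task)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x0B5)))
    records = []
    for trial, (block, label) in enumerate(plan):
        stim = _make_stimulus(task, label, cfg)
        trial_seed = int(np.random.SeedSequence((seed, trial)).generate_state(1)[0] % (2**31))
        gaze = simulate_gaze(
            stim.duration_s,
            rate_hz=cfg.render_rate_hz,
            mode=cfg.gaze_mode,
            noise_deg=cfg.gaze_noise_deg,
            seed=trial_seed,
        )
        clip = sim.run(stim, gaze)
        if observer == "random":
            choice = str(TASK_LABELS[task][rng.integers(len(TASK_LABELS[task]))])
        elif task == "letter":
            choice = obs.template_observer(clip, bank)
        else:
            choice = obs.motion_observer(clip)
        records.append(
            TrialRecord(
                trial=trial,
                block=block,
                task=task,
                condition=cfg.condition_name or cfg.raster_pattern,
                stimulus=label,
                choice=choice,
                correct=(choice == label),
                seed=trial_seed,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------

def records_to_frame(records: list) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def write_outputs(
    clip: PerceptClip | None,
    records: list | None,
    out_dir,
    cfg: SimConfig | None = None,
) -> None:
    """Write percept frames as 8-bit PNGs (fixed display gain), trial records
    as CSV, and echo the configuration alongside."""
    import os

    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    gain = cfg.display_gain if cfg is not None else 1.0
    if clip is not None:
        for t, frame in enumerate(clip.frames):
            img = (np.clip(frame * gain, 0.0, 1.0) * 255).astype(np.uint8)
            iio.imwrite(os.path.join(out_dir, f"frame_{t:04d}.png"), img)
    if records is not None:
        records_to_frame(records).to_csv(os.path.join(out_dir, "records.csv"), index=False)
    if cfg is not None:
        save_config(cfg, os.path.join(out_dir, "config.yaml"))


def read_records(path) -> list:
    df = pd.read_csv(path)
    return [
        TrialRecord(
            trial=int(r.trial),
            block=int(r.block),
            task=str(r.task),
            condition=str(r.condition),
            stimulus=str(r.stimulus),
            choice=str(r.choice),
            correct=bool(r.correct),
            seed=int(r.seed),
        )
        for r in df.itertuples()
    ]
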