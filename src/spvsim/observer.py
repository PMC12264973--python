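"""Virtual observers and raster-quality metrics.

A software stand-in for the human participants of the two 8AFC tasks:

- the template observer matches the time-averaged percept against a bank of
  the eight alternatives rendered under a stated reference condition
  (normalized cross-correlation, fixed tie-break order);
- the motion observer reads the percept's drift vector (brightness-centroid
  motion energy, cycle-wrap transitions excluded) and picks the nearest of
  the eight compass directions;
- the random observer draws uniformly — the 1/8 chance baseline.

Confusion matrices and per-response bias indices quantify the systematic
errors that raster patterns induce (grouping confusions among similar
letters; apparent-motion biases along the scan axis of linear rasters).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stimulus import BAR_DIRECTIONS, OPTOTYPE_LETTERS

__all__ = [
    "render_template_bank",
    "template_observer",
    "random_observer",
    "motion_energy",
    "motion_observer",
    "confusion_and_bias",
]


def render_template_bank(simulator, task: str = "letter") -> dict:
    """Render the 8 alternatives under the no-raster, temporal-off reference
    at the simulator's ρ/λ, as single-frame percepts on the percept grid."""
    from .pipeline import TASK_LABELS, _make_stimulus
    from .raster import make_schedule

    cfg = simulator.cfg
    ref_cfg = cfg.replace(raster_pattern="none", temporal_enabled=False)
    # reuse the expensive spatial state; only schedule/temporal flags differ
    ref = object.__new__(type(simulator))
    ref.__dict__.update(simulator.__dict__)
    ref.cfg = ref_cfg
    ref.schedule = make_schedule("none", simulator.array)
    bank = {}
    for label in TASK_LABELS[task]:
        stim = _make_stimulus(task, label, ref_cfg.replace(stimulus_duration_s=1.0 / cfg.render_rate_hz))
        clip = ref.run(stim, gaze=None, temporal_enabled=False)
        bank[label] = clip.frames.mean(axis=0)
    return bank


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation; -2 when either image is constant (below
    any attainable correlation, so constant percepts fall to the tie-break)."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return -2.0
    return float(a @ b / (na * nb))


def template_observer(clip, bank: dict) -> str:
    """Choice = argmax NCC between the time-averaged percept and each
    template; ties resolved by the bank's (alphabetical/clockwise) order."""
    if len(clip.frames) == 0:
        raise ValueError("empty percept clip")
    avg = clip.frames.mean(axis=0)
    labels = list(bank)
    scores = np.array([_ncc(avg, bank[lab]) for lab in labels])
    return labels[int(np.argmax(scores))]  # argmax keeps the first of ties


def random_observer(n_alternatives: int, seed: int, labels=None):
    """Seeded stream of uniform choices; yields labels if given, else ints."""
    rng = np.random.default_rng(seed)
    while True:
        k = int(rng.integers(n_alternatives))
        yield labels[k] if labels is not None else k


def motion_energy(clip, method: str = "centroid") -> np.ndarray:
    """Mean drift of the percept, in degrees of visual angle per second.

    Consecutive-frame displacements are estimated by brightness-centroid
    differencing (suited to the near-binary bar/letter percepts) or by phase
    correlation, then averaged.  Frame pairs that straddle a raster-cycle
    boundary are excluded: the wrap from the last group back to the first is
    an artifact of the cycle index, not perceived motion.  Returns (vx, vy)
    with y positive upward; a constant or empty-brightness clip gives (0, 0).
    """
    frames = np.asarray(clip.frames, dtype=float)
    if len(frames) < 2:
        raise ValueError("motion energy needs at least 2 frames")
    dt = 1.0 / clip.render_rate_hz
    ny, nx = frames.shape[1:]
    step = 2.0 * clip.extent_deg / max(nx - 1, 1)
    same_cycle = clip.cycle_index[:-1] == clip.cycle_index[1:]
    disps = []
    if method == "centroid":
        ax = np.linspace(-clip.extent_deg, clip.extent_deg, nx)
        ay = np.linspace(clip.extent_deg, -clip.extent_deg, ny)
        mass = frames.sum(axis=(1, 2))
        cx = np.where(mass > 1e-9, (frames * ax[None, None, :]).sum(axis=(1, 2)) / np.maximum(mass, 1e-30), np.nan)
        cy = np.where(mass > 1e-9, (frames * ay[None, :, None]).sum(axis=(1, 2)) / np.maximum(mass, 1e-30), np.nan)
        for t in np.nonzero(same_cycle)[0]:
            if np.isfinite(cx[t]) and np.isfinite(cx[t + 1]):
                disps.append((cx[t + 1] - cx[t], cy[t + 1] - cy[t]))
    elif method == "phase":
        from skimage.registration import phase_cross_correlation

        for t in np.nonzero(same_cycle)[0]:
            if frames[t].std() < 1e-12 or frames[t + 1].std() < 1e-12:
                continue
            shift, _, _ = phase_cross_correlation(
                frames[t], frames[t + 1], upsample_factor=8, normalization=None
            )
            # shift = displacement of frame t+1 relative to t in (row, col)
            disps.append((-shift[1] * step, shift[0] * step))
    else:
        raise ValueError("method must be 'centroid' or 'phase'")
    if not disps:
        return np.zeros(2)
    return np.mean(disps, axis=0) / dt


def motion_observer(clip, method: str = "centroid") -> str:
    """Nearest compass direction to the drift vector; zero drift falls back
    to the first direction of the fixed clockwise order."""
    v = motion_energy(clip, method=method)
    labels = list(BAR_DIRECTIONS)
    if np.linalg.norm(v) < 1e-12:
        return labels[0]
    units = np.array([BAR_DIRECTIONS[d] for d in labels])
    return labels[int(np.argmax(units @ (v / np.linalg.norm(v))))]


def confusion_and_bias(records: list):
    """8×8 confusion matrix (rows = presented, cols = chosen) and the
    per-response bias index: the fraction of all error trials drawn to each
    response alternative.

    Records must come from a single task; mixing letter and motion trials is
    an error.
    """
    if not records:
        raise ValueError("no trial records")
    tasks = {r.task for r in records}
    if len(tasks) > 1:
        raise ValueError(f"records mix tasks {sorted(tasks)}; analyse one task at a time")
    task = tasks.pop()
    labels = list(OPTOTYPE_LETTERS if task == "letter" else BAR_DIRECTIONS)
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for r in records:
        mat.loc[r.stimulus, r.choice] += 1
    errors = [r for r in records if not r.correct]
    bias = pd.Series(0.0, index=labels)
    if errors:
        for r in errors:
            bias[r.choice] += 1.0
        bias /= len(errors)
    return mat, bias
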