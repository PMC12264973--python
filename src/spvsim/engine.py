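"""Phosphene generation: electrode activation, axon-map spatial model, and
leaky-integrator temporal dynamics.

Spatial model.  The instantaneous brightness at percept-grid sample (r, θ) is

    b_I(r, θ) = max_{p ∈ R(θ)}  Σ_e  a_e · exp(−d_e²/2ρ²  −  d_soma²/2λ²)

where R(θ) is the axon path terminating at (r, θ), d_e the distance from the
path point p to electrode e, d_soma the arc length from p back to the soma,
and a_e ∈ [0, 1] the electrode amplitude (gray level interpreted as current).
The maximum over the path — not a linear sum — captures the nonlinear spatial
interactions of simultaneous epiretinal stimulation (merging, elongation,
asymmetric brightness).

Temporal model.  Two coupled leaky integrators per pixel track neural
desensitization n(t) and perceived brightness b(t):

    dn/dt = −τ_n n + b_I        db/dt = −τ_b b − α n + b_I

integrated by forward Euler at the render period with a non-negativity clamp
on b.  τ_n, τ_b are rate coefficients as the equations are written, so b is
the fast variable (1/τ_b = 0.2 s) and n the slow one (1/τ_n = 5 s) —
sustained input therefore fades: the preset "5Hz" (τ_n=0.2, τ_b=5, α=0.2)
fades exactly to zero, and "20Hz" (α=0.25) is clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError
from .retina import AxonMap, AxonMapParams, ElectrodeArray, RetinaSpec

__all__ = [
    "TemporalParams",
    "TEMPORAL_PRESETS",
    "SpatialModel",
    "electrode_activation",
    "spatial_percept",
    "integrate_temporal",
]


@dataclass(frozen=True)
class TemporalParams:
    """Rate coefficients of the coupled leaky integrators (1/s) and the
    desensitization coupling α (dimensionless)."""

    tau_n: float = 0.2
    tau_b: float = 5.0
    alpha: float = 0.2

    def __post_init__(self) -> None:
        if self.tau_n < 0 or self.tau_b < 0 or self.alpha < 0:
            raise ValueError("temporal parameters must be non-negative")

    @classmethod
    def preset(cls, name: str) -> "TemporalParams":
        try:
            return cls(*TEMPORAL_PRESETS[name])
        except KeyError:
            raise ValueError(
                f"unknown temporal preset {name!r}; choose from {tuple(TEMPORAL_PRESETS)}"
            ) from None


# fitted to reproduce reported fading/persistence at two stimulation rates
TEMPORAL_PRESETS = {"5Hz": (0.2, 5.0, 0.2), "20Hz": (0.2, 5.0, 0.25)}


# ---------------------------------------------------------------------------
# Electrode activation (pixel → amplitude)
# ---------------------------------------------------------------------------

def electrode_pixel_indices(
    array: ElectrodeArray, spec: RetinaSpec, frame_shape, field_deg: float
) -> np.ndarray:
    """Nearest-pixel (row, col) of each electrode's visual-field position;
    (-1, -1) for electrodes mapping outside the frame."""
    h, w = frame_shape
    deg = spec.um_to_deg(array.positions)
    col = np.floor((deg[:, 0] / field_deg + 0.5) * w).astype(int)
    row = np.floor((0.5 - deg[:, 1] / field_deg) * h).astype(int)
    ok = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    out = np.stack([np.where(ok, row, -1), np.where(ok, col, -1)], axis=1)
    return out


def electrode_activation(
    frame: np.ndarray,
    array: ElectrodeArray,
    active: np.ndarray | None,
    spec: RetinaSpec,
    field_deg: float = 60.0,
) -> np.ndarray:
    """Per-electrode amplitude: the preprocessed-frame intensity at the pixel
    nearest each active electrode; inactive (out-of-group) electrodes are
    exactly zero, as are electrodes mapping outside the frame.

    ``active`` is an array of electrode indices, or None for all electrodes.
    """
    rc = electrode_pixel_indices(array, spec, frame.shape, field_deg)
    amps = np.zeros(array.n_electrodes)
    idx = np.arange(array.n_electrodes) if active is None else np.asarray(active)
    for e in idx:
        r, c = rc[e]
        if r >= 0:
            amps[e] = frame[r, c]
    return amps


# ---------------------------------------------------------------------------
# Spatial model
# ---------------------------------------------------------------------------

class SpatialModel:
    """Precomputed axon-map evaluator for one (array, axon map, ρ, λ).

    Two precomputed Gaussian bases are combined per frame:

    - ``_soma``: sample-to-electrode radial terms (the p = soma path point,
      where d_soma = 0);
    - ``_bundle``: bundle-point-to-electrode radial terms, combined with each
      sample's path weights exp(−d_soma²/2λ²) in a CSR layout and reduced by
      a segment maximum.

    Single-electrode percepts are never summed across electrodes after the
    max — amplitudes weight the radial terms *inside* the path maximum, which
    is what makes multi-electrode interactions nonlinear.
    """

    #: path weights below this are dropped from the precomputed basis
    weight_floor = 1e-4

    def __init__(
        self,
        array: ElectrodeArray,
        axon_map: AxonMap,
        params: AxonMapParams | None = None,
    ) -> None:
        params = params or AxonMapParams()
        spec = axon_map.spec
        self.array, self.axon_map, self.params = array, axon_map, params
        self.grid_shape = spec.grid_shape
        grid_um = spec.grid_points_um()
        rho2 = 2.0 * params.rho_um**2
        lam2 = 2.0 * params.lam_um**2

        # soma term: the sample itself is the soma (d_soma = 0)
        self._soma = np.exp(-cdist(grid_um, array.positions) ** 2 / rho2)

        # bundle terms: for each sample, walk its nearest bundle from the
        # attachment point back toward the disc, accumulating arc length
        pts, arc = axon_map.bundle_points, axon_map.bundle_arc
        offs = axon_map.bundle_offsets
        max_dsoma = params.lam_um * np.sqrt(-2.0 * np.log(self.weight_floor))
        idx_list, w_list, counts = [], [], []
        for pix in range(len(grid_um)):
            b = axon_map.pixel_bundle[pix]
            k = axon_map.pixel_point[pix]
            gap = axon_map.pixel_gap_um[pix]
            start = offs[b]
            # d_soma(i) = gap + arc[k] − arc[i] for i ∈ [start, k]
            d = gap + arc[k] - arc[start : k + 1]
            keep = np.nonzero(d <= max_dsoma)[0]
            idx = start + keep
            w = np.exp(-d[keep] ** 2 / lam2)
            idx_list.append(idx)
            w_list.append(w)
            counts.append(len(idx))
        self._indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self._point_idx = (
            np.concatenate(idx_list) if idx_list else np.empty(0, dtype=np.int64)
        )
        self._w = np.concatenate(w_list) if w_list else np.empty(0)
        used = np.unique(self._point_idx)
        # compact the bundle basis to the points some sample actually visits
        remap = np.full(len(pts), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        self._point_idx = remap[self._point_idx]
        self._bundle = np.exp(-cdist(pts[used], array.positions) ** 2 / rho2)

    def evaluate(self, amplitudes: np.ndarray) -> np.ndarray:
        """Brightness field for one activation vector; shape = percept grid."""
        a = np.asarray(amplitudes, dtype=float)
        if a.shape != (self.array.n_electrodes,):
            raise ConfigurationError(
                f"activation vector has {a.shape} amplitudes; the array has "
                f"{self.array.n_electrodes} electrodes"
            )
        soma_term = self._soma @ a
        if self._w.size:
            s = self._bundle @ a
            vals = self._w * s[self._point_idx]
            vals = np.append(vals, 0.0)  # sentinel for trailing empty segments
            starts = np.minimum(self._indptr[:-1], len(vals) - 1)
            seg_max = np.maximum.reduceat(vals, starts)
            empty = self._indptr[:-1] == self._indptr[1:]
            seg_max[empty] = 0.0
            field = np.maximum(soma_term, seg_max)
        else:
            field = soma_term
        return field.reshape(self.grid_shape)


def spatial_percept(
    amplitudes: np.ndarray,
    axon_map: AxonMap,
    params: AxonMapParams,
    array: ElectrodeArray,
) -> np.ndarray:
    """One-shot axon-map evaluation (builds the basis; for repeated frames
    construct a :class:`SpatialModel` once and call ``evaluate``)."""
    return SpatialModel(array, axon_map, params).evaluate(amplitudes)


# ---------------------------------------------------------------------------
# Temporal model
# ---------------------------------------------------------------------------

def integrate_temporal(
    b_I_series: np.ndarray,
    params: TemporalParams,
    dt: float = 1.0 / 90.0,
    state: tuple | None = None,
    clamp: bool = True,
    return_state: bool = False,
):
    """Forward-Euler integration of the desensitization/brightness system.

    ``b_I_series`` has shape (T, ...); the two state variables share the
    trailing shape and start at zero unless ``state=(n0, b0)`` is given.
    Returns the brightness sequence (and the final state if requested).
    The clamp keeps b non-negative after every step; disable it only to
    compare against the exact linear-system solution.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    b_I_series = np.asarray(b_I_series, dtype=float)
    shape = b_I_series.shape[1:]
    n = np.zeros(shape) if state is None else np.array(state[0], dtype=float)
    b = np.zeros(shape) if state is None else np.array(state[1], dtype=float)
    out = np.empty_like(b_I_series)
    for t, b_I in enumerate(b_I_series):
        n = n + dt * (-params.tau_n * n + b_I)
        b = b + dt * (-params.tau_b * b - params.alpha * n + b_I)
        if clamp:
            b = np.maximum(b, 0.0)
        out[t] = b
    if return_state:
        return out, (n, b)
    return out
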