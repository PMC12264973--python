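"""Retinal coordinate system, electrode-array geometry, and axon-path map.

Coordinate convention (used everywhere in the package)
------------------------------------------------------
Right eye, single planar frame shared by the visual field and the retinal
surface: ``x`` positive nasal (toward the optic disc), ``y`` positive
superior, fovea at the origin.  Retinal positions are in micrometres (µm);
visual-field positions in degrees of visual angle, related by a linear
constant ``um_per_degree`` (default 280 µm/deg).  The temporal horizontal
raphe — the divide that retinal ganglion-cell axons never cross — is the ray
``y = 0, x < 0``.  The optic-disc centre sits at (15°, 2°) nasal-superior.

The axon map discretizes ganglion-cell axon trajectories as "bundles"
(polylines growing from the optic disc outward).  Each percept-grid sample is
treated as a soma; its axon runs from the sample to the nearest bundle point
and then along that bundle back toward the disc.  Trajectories follow a
Jansonius-style spiral family generated in a raphe-aligned frame and sheared
nasally so that the disc lands at (15°, 2°) while the temporal raphe stays
exactly on ``y = 0`` (parameterization version ``traj-v1``).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError

__all__ = [
    "RetinaSpec",
    "ElectrodeArray",
    "AxonMap",
    "AxonMapParams",
    "build_electrode_array",
    "build_axon_map",
    "check_field_coverage",
]

OPTIC_DISC_DEG = (15.0, 2.0)  # nasal-superior, right eye
_DISC_RADIUS_DEG = 4.0  # bundles start this far from the disc centre
TRAJECTORY_VERSION = "traj-v1"


@dataclass(frozen=True)
class RetinaSpec:
    """Retina/visual-field geometry: unit conversion and the percept grid."""

    um_per_degree: float = 280.0
    percept_grid_extent_deg: float = 12.0  # grid spans ±extent per axis
    percept_grid_step_deg: float = 0.25
    eye: str = "right"

    def __post_init__(self) -> None:
        if self.um_per_degree <= 0:
            raise ValueError("um_per_degree must be positive")
        if self.percept_grid_step_deg <= 0:
            raise ValueError("percept_grid_step_deg must be positive")
        if self.percept_grid_extent_deg <= 0:
            raise ValueError("percept_grid_extent_deg must be positive")
        if self.eye != "right":
            raise ValueError("only the right-eye convention is implemented")

    def deg_to_um(self, v):
        """Visual angle (deg) to retinal distance (µm); linear."""
        return np.asarray(v, dtype=float) * self.um_per_degree

    def um_to_deg(self, v):
        """Retinal distance (µm) to visual angle (deg); exact inverse."""
        return np.asarray(v, dtype=float) / self.um_per_degree

    @property
    def grid_axis_deg(self) -> np.ndarray:
        """Sample positions along one percept-grid axis, in degrees."""
        e, s = self.percept_grid_extent_deg, self.percept_grid_step_deg
        n = int(round(2 * e / s)) + 1
        return np.linspace(-e, e, n)

    @property
    def grid_shape(self) -> tuple:
        n = self.grid_axis_deg.size
        return (n, n)

    def grid_points_um(self) -> np.ndarray:
        """All percept-grid sample positions, shape (n_samples, 2), µm.

        Row-major over (y descending, x ascending) so that reshaping to
        ``grid_shape`` yields an image with superior visual field at the top.
        """
        ax = self.grid_axis_deg
        xx, yy = np.meshgrid(ax, ax[::-1])
        pts_deg = np.column_stack([xx.ravel(), yy.ravel()])
        return self.deg_to_um(pts_deg)


@dataclass(frozen=True)
class ElectrodeArray:
    """Electrode positions on the retina (µm) with grid indices and labels."""

    ids: tuple
    grid_index: np.ndarray  # (n, 2) ints: (row i, col j); row 0 = superior
    positions: np.ndarray  # (n, 2) floats, µm
    rows: int
    cols: int
    pitch_um: float
    center_um: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if len({tuple(p) for p in np.round(self.positions, 6)}) != len(self.ids):
            raise ValueError("electrode positions must be distinct")

    @property
    def n_electrodes(self) -> int:
        return len(self.ids)

    def index_of(self, electrode_id: str) -> int:
        return self.ids.index(electrode_id)


def build_electrode_array(
    rows: int, cols: int, pitch_um: float, center_um=(0.0, 0.0)
) -> ElectrodeArray:
    """Build a regular ``rows × cols`` grid of electrodes at ``pitch_um`` spacing.

    Labels follow the Argus-style convention: row letter (A = top/superior)
    plus 1-based column number, e.g. ``"A1"`` .. ``"J10"`` for a 10×10 array.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if pitch_um <= 0:
        raise ValueError("pitch_um must be positive")
    cx, cy = center_um
    ids, gidx, pos = [], [], []
    for i in range(rows):
        for j in range(cols):
            ids.append(f"{chr(ord('A') + i)}{j + 1}")
            gidx.append((i, j))
            x = cx + (j - (cols - 1) / 2.0) * pitch_um
            y = cy + ((rows - 1) / 2.0 - i) * pitch_um  # row 0 is superior
            pos.append((x, y))
    return ElectrodeArray(
        ids=tuple(ids),
        grid_index=np.array(gidx, dtype=int),
        positions=np.array(pos, dtype=float),
        rows=rows,
        cols=cols,
        pitch_um=float(pitch_um),
        center_um=(float(cx), float(cy)),
    )


@dataclass(frozen=True)
class AxonMapParams:
    """Gaussian falloff scales of the axon-map phosphene model.

    ``rho_um`` controls radial current spread around an electrode; ``lam_um``
    controls elongation along the stimulated axon bundle.  Defaults are the
    realistic epiretinal values ρ = 300 µm, λ = 1000 µm.
    """

    rho_um: float = 300.0
    lam_um: float = 1000.0

    def __post_init__(self) -> None:
        if self.rho_um <= 0 or self.lam_um <= 0:
            raise ValueError("rho_um and lam_um must be positive")


def check_field_coverage(spec: RetinaSpec, array: ElectrodeArray, rho_um: float) -> None:
    """Require the percept grid to cover the array footprint plus a 3ρ margin."""
    half_extent_um = spec.deg_to_um(spec.percept_grid_extent_deg)
    need = np.abs(array.positions).max() + array.pitch_um / 2.0 + 3.0 * rho_um
    if half_extent_um < need:
        raise ConfigurationError(
            f"percept grid half-extent {half_extent_um:.0f} µm does not cover the "
            f"array footprint plus 3ρ margin ({need:.0f} µm); enlarge "
            "percept_grid_extent_deg or reduce rho"
        )


# ---------------------------------------------------------------------------
# Axon trajectories (traj-v1)
# ---------------------------------------------------------------------------

def _spiral_phi(phi0: float, r: np.ndarray) -> np.ndarray:
    """Spiral emission model: angle along a bundle as a function of the
    distance ``r`` (deg) from the disc centre, for emission angle ``phi0``.

    Angles are measured at the disc from the nasal direction (away from the
    fovea), so ``|phi0| -> 180`` is the papillomacular bundle and
    ``|phi0| ~ 60-120`` the arcuate bundles.  Superior bundles (phi0 > 0)
    arch over the macula toward the temporal raphe (phi increasing), inferior
    bundles mirror this from below; coefficients taper the curvature across
    the arcuate/papillomacular transition in the style of published
    ganglion-axon trajectory fits.
    """
    if phi0 > 0:
        b = np.exp(-1.9 + 3.9 * np.tanh(-(phi0 - 121.0) / 14.0))
        c = 1.9 + 1.4 * np.tanh((phi0 - 121.0) / 14.0)
    else:
        b = -np.exp(0.5 + 1.5 * np.tanh(-(-phi0 - 90.0) / 25.0))
        c = 1.0 + 0.5 * np.tanh((-phi0 - 90.0) / 25.0)
    return phi0 + b * np.maximum(r - _DISC_RADIUS_DEG, 0.0) ** c


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _grow_bundles(spec: RetinaSpec, n_axons: int, step_um: float):
    """Grow axon bundles from the optic disc outward; return list of (k,2) µm
    polylines resampled to ≤ ``step_um`` chord spacing."""
    disc_x, disc_y = OPTIC_DISC_DEG
    extent = spec.percept_grid_extent_deg
    # radius that covers the farthest grid corner from the disc, plus margin
    r_max = float(np.hypot(disc_x + extent, extent)) + 2.0
    step_deg = spec.um_to_deg(step_um)
    r = np.arange(_DISC_RADIUS_DEG, r_max, min(step_deg, 0.25))
    phi0s = -180.0 + 360.0 * (np.arange(n_axons) + 0.5) / n_axons
    bundles = []
    for phi0 in phi0s:
        phi_deg = _spiral_phi(float(phi0), r)
        # Bundles terminate on the horizontal meridian through the disc; for
        # r beyond the fovea that line is the temporal raphe, which axons
        # never cross.
        over = np.nonzero(np.abs(phi_deg) >= 180.0)[0]
        ri, phii = (r, phi_deg) if not over.size else (r[: over[0]], phi_deg[: over[0]])
        if ri.size < 2:
            continue
        phi = np.deg2rad(phii)
        # raphe-aligned generation frame: disc at (disc_x, 0), fovea at the
        # origin, phi = 0 pointing nasally.
        x = disc_x + ri * np.cos(phi)
        y = ri * np.sin(phi)
        # nasal-only shear lifts the disc to (15, 2); identity for x <= 0
        y = y + disc_y * _smoothstep(x / disc_x)
        pts = spec.deg_to_um(np.column_stack([x, y]))
        pts = _truncate_at_raphe(pts)
        if len(pts) >= 2:
            bundles.append(_resample_polyline(pts, step_um))
    return bundles


def _truncate_at_raphe(pts: np.ndarray) -> np.ndarray:
    """Cut a polyline before any segment that crosses y=0 on the temporal
    (x<0) side.  A safety net: traj-v1 avoids such crossings by construction."""
    x, y = pts[:, 0], pts[:, 1]
    sign_change = np.signbit(y[:-1]) != np.signbit(y[1:])
    temporal = (x[:-1] < 0) | (x[1:] < 0)
    bad = np.nonzero(sign_change & temporal & (y[:-1] != 0))[0]
    if bad.size:
        return pts[: bad[0] + 1]
    return pts


def _resample_polyline(pts: np.ndarray, step_um: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing ``step_um``."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(np.ceil(total / step_um)) + 1, 2)
    s = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(s, arc, pts[:, 0]), np.interp(s, arc, pts[:, 1])])
    return out


@dataclass(frozen=True)
class AxonMap:
    """Discretized axon bundles plus the percept-grid soma assignment.

    ``bundle_points`` concatenates all bundle polylines (µm); ``bundle_offsets``
    delimits them CSR-style; ``bundle_arc`` is the cumulative arc length from
    the disc end of each bundle (strictly increasing within a bundle).  For
    each percept-grid sample, ``pixel_bundle``/``pixel_point`` give the nearest
    bundle and on-bundle point, and ``pixel_gap_um`` the distance from the
    sample (its soma) to that point.
    """

    spec: RetinaSpec
    n_axons: int
    step_um: float
    bundle_points: np.ndarray  # (P, 2) µm
    bundle_offsets: np.ndarray  # (n_bundles + 1,) int
    bundle_arc: np.ndarray  # (P,) µm
    pixel_bundle: np.ndarray  # (n_pix,) int
    pixel_point: np.ndarray  # (n_pix,) int, global index into bundle_points
    pixel_gap_um: np.ndarray  # (n_pix,) float
    version: str = TRAJECTORY_VERSION

    @property
    def n_bundles(self) -> int:
        return len(self.bundle_offsets) - 1

    def bundle(self, i: int) -> np.ndarray:
        return self.bundle_points[self.bundle_offsets[i] : self.bundle_offsets[i + 1]]

    def content_hash(self) -> str:
        """Hash of the build parameters; keys on-disk caches."""
        key = (
            self.version,
            self.spec.um_per_degree,
            self.spec.percept_grid_extent_deg,
            self.spec.percept_grid_step_deg,
            self.n_axons,
            self.step_um,
        )
        return hashlib.sha256(repr(key).encode()).hexdigest()[:16]

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            bundle_points=self.bundle_points,
            bundle_offsets=self.bundle_offsets,
            bundle_arc=self.bundle_arc,
            pixel_bundle=self.pixel_bundle,
            pixel_point=self.pixel_point,
            pixel_gap_um=self.pixel_gap_um,
            meta=np.array(
                [
                    self.spec.um_per_degree,
                    self.spec.percept_grid_extent_deg,
                    self.spec.percept_grid_step_deg,
                    self.n_axons,
                    self.step_um,
                ]
            ),
        )

    @classmethod
    def load_npz(cls, path) -> "AxonMap":
        d = np.load(path)
        meta = d["meta"]
        spec = RetinaSpec(
            um_per_degree=float(meta[0]),
            percept_grid_extent_deg=float(meta[1]),
            percept_grid_step_deg=float(meta[2]),
        )
        return cls(
            spec=spec,
            n_axons=int(meta[3]),
            step_um=float(meta[4]),
            bundle_points=d["bundle_points"],
            bundle_offsets=d["bundle_offsets"],
            bundle_arc=d["bundle_arc"],
            pixel_bundle=d["pixel_bundle"],
            pixel_point=d["pixel_point"],
            pixel_gap_um=d["pixel_gap_um"],
        )


def build_axon_map(
    spec: RetinaSpec, n_axons: int = 500, step_um: float = 50.0
) -> AxonMap:
    """Grow the bundle family and assign every percept-grid sample to its
    nearest bundle point.  Deterministic: identical inputs give bit-identical
    maps."""
    if n_axons < 2:
        raise ValueError("n_axons must be >= 2")
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    bundles = _grow_bundles(spec, n_axons, step_um)
    if not bundles:
        raise ConfigurationError("no axon bundles intersect the percept grid")
    offsets = np.concatenate([[0], np.cumsum([len(b) for b in bundles])]).astype(int)
    points = np.vstack(bundles)
    arcs = np.concatenate(
        [
            np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(b, axis=0), axis=1))])
            for b in bundles
        ]
    )
    grid = spec.grid_points_um()
    # Attachment respects the raphe: a temporal (x < 0) sample may only
    # attach to a bundle point in its own hemifield — the percept is
    # discontinuous across the temporal raphe, as the axon model requires.
    gap = np.empty(len(grid))
    gidx = np.empty(len(grid), dtype=np.int64)
    tree_all = cKDTree(points)
    sup = np.nonzero(points[:, 1] >= 0)[0]
    inf = np.nonzero(points[:, 1] < 0)[0]
    tree_sup = cKDTree(points[sup])
    tree_inf = cKDTree(points[inf])
    nasal = grid[:, 0] >= 0
    if nasal.any():
        gap[nasal], gidx[nasal] = tree_all.query(grid[nasal], k=1)
    for side_mask, tree, subset in (
        ((~nasal) & (grid[:, 1] >= 0), tree_sup, sup),
        ((~nasal) & (grid[:, 1] < 0), tree_inf, inf),
    ):
        if side_mask.any():
            g, i = tree.query(grid[side_mask], k=1)
            gap[side_mask], gidx[side_mask] = g, subset[i]
    bundle_of_point = np.repeat(np.arange(len(bundles)), np.diff(offsets))
    return AxonMap(
        spec=spec,
        n_axons=n_axons,
        step_um=float(step_um),
        bundle_points=points,
        bundle_offsets=offsets,
        bundle_arc=arcs,
        pixel_bundle=bundle_of_point[gidx],
        pixel_point=gidx.astype(int),
        pixel_gap_um=gap,
    )
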