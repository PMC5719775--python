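"""Synthetic grid-sheet phantom and MR/CT acquisition simulator.

The physical phantom being emulated is a box of parallel styrene grid sheets
immersed in mineral oil: 17 sheets, each carrying a 17x17 lattice of grid-bar
crossings ("control points") at 1.5 cm in-plane pitch; sheets are 0.76 cm
thick and separated by 0.9 cm oil gaps inside a 30 cm cube.  The simulator
rasterizes this phantom into CT and MR volumes, warps the MR volumes with a
known smooth 3D displacement field (the stand-in for the unknown scanner
gradient-nonlinearity field), adds a polarity-signed B0 read-axis shift,
a smooth multiplicative intensity bias, Gaussian noise and air-bubble
artifacts.  Because the applied field is analytic, every downstream stage of
the mapping pipeline can be validated against exact ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume

log = logging.getLogger(__name__)

# two-level rendering intensities
MR_OIL, MR_GRID, MR_AIR = 1000.0, 100.0, 0.0
CT_OIL, CT_GRID, CT_AIR = 100.0, 1000.0, 0.0

#: grid-sheet normal axis for each acquisition orientation (array axis index)
ORIENTATION_NORMAL = {"transverse": 2, "sagittal": 0, "coronal": 1}
#: in-plane array axes for each orientation, in (u, v) order
ORIENTATION_INPLANE = {"transverse": (0, 1), "sagittal": (1, 2), "coronal": (0, 2)}


@dataclass
class PhantomGeometry:
    """Physical dimensions of the grid-sheet phantom (mm)."""

    n_sheets: int = 17
    points_per_row: int = 17
    point_pitch_mm: float = 15.0
    sheet_thickness_mm: float = 7.6
    gap_mm: float = 9.0
    grid_bar_width_mm: float = 2.0
    box_inner_mm: tuple[float, float, float] = (300.0, 300.0, 300.0)

    def __post_init__(self):
        if self.n_sheets < 1 or self.points_per_row < 2:
            raise ValueError("need n_sheets >= 1 and points_per_row >= 2")
        for name in ("point_pitch_mm", "sheet_thickness_mm", "gap_mm", "grid_bar_width_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def sheet_pitch_mm(self) -> float:
        """Center-to-center sheet spacing along the sheet normal."""
        return self.sheet_thickness_mm + self.gap_mm

    @property
    def n_points(self) -> int:
        return self.n_sheets * self.points_per_row**2

    def line_positions(self) -> np.ndarray:
        """In-plane grid-bar center positions, centered on the phantom."""
        m = self.points_per_row
        return (np.arange(m) - (m - 1) / 2.0) * self.point_pitch_mm

    def sheet_positions(self) -> np.ndarray:
        """Sheet center positions along the normal, centered on the phantom."""
        n = self.n_sheets
        return (np.arange(n) - (n - 1) / 2.0) * self.sheet_pitch_mm

    def nominal_lattice(self, orientation: str = "transverse") -> np.ndarray:
        """(N, 3) world coordinates of the nominal control points."""
        normal = ORIENTATION_NORMAL[orientation]
        axes_coords = [None, None, None]
        a, b = ORIENTATION_INPLANE[orientation]
        axes_coords[a] = self.line_positions()
        axes_coords[b] = self.line_positions()
        axes_coords[normal] = self.sheet_positions()
        gx, gy, gz = np.meshgrid(*axes_coords, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


# ---------------------------------------------------------------------------
# ground-truth distortion model
# ---------------------------------------------------------------------------

def _power_table(v: np.ndarray, max_pow: int) -> list:
    tab = [None, v]
    for p in range(2, max_pow + 1):
        tab.append(tab[-1] * v)
    return tab


def _eval_poly(coeffs: dict, x, y, z, powers=None):
    """Evaluate a sparse trivariate monomial sum ``sum c * x^i y^j z^k``."""
    out = np.zeros(np.broadcast(x, y, z).shape)
    if not coeffs:
        return out
    if powers is None:
        pmax = max(max(k) for k in coeffs)
        powers = (_power_table(x, pmax), _power_table(y, pmax), _power_table(z, pmax))
    px, py, pz = powers
    for (i, j, k), c in coeffs.items():
        if i:
            term = c * px[i]
            if j:
                term = term * py[j]
            if k:
                term = term * pz[k]
        elif j:
            term = c * py[j]
            if k:
                term = term * pz[k]
        elif k:
            term = c * pz[k]
        else:
            term = np.full_like(out, c)
        out += term
    return out


@dataclass
class DistortionModel:
    """Analytic ground-truth displacement field delta(x) in mm.

    Each component is a sparse trivariate polynomial (degree <= 3) over
    physical mm coordinates, optionally plus a radial harmonic term.  A
    separate polynomial models the B0-inhomogeneity displacement, applied
    along ``read_axis`` with a sign that follows the read-gradient polarity.
    """

    coeffs_x: dict = field(default_factory=dict)
    coeffs_y: dict = field(default_factory=dict)
    coeffs_z: dict = field(default_factory=dict)
    #: optional (axis_out, amplitude_mm, gain_axis, osc_axis, wavelength_mm)
    harmonics: tuple = ()
    b0_coeffs: dict = field(default_factory=dict)
    read_axis: int = 0
    #: half-extent of the declared validity box (mm)
    validity_mm: tuple[float, float, float] = (165.0, 165.0, 165.0)

    def system_displacement(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        powers = (_power_table(x, 3), _power_table(y, 3), _power_table(z, 3))
        d = np.column_stack(
            [
                _eval_poly(self.coeffs_x, x, y, z, powers),
                _eval_poly(self.coeffs_y, x, y, z, powers),
                _eval_poly(self.coeffs_z, x, y, z, powers),
            ]
        )
        for axis_out, amp, gain_axis, osc_axis, wavelength in self.harmonics:
            gain = p[:, gain_axis] / self.validity_mm[gain_axis]
            d[:, axis_out] += amp * gain * np.sin(2 * np.pi * p[:, osc_axis] / wavelength)
        return d

    def b0_displacement(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        return _eval_poly(self.b0_coeffs, p[:, 0], p[:, 1], p[:, 2])

    def displacement(self, points: np.ndarray, polarity: str = "forward") -> np.ndarray:
        """System displacement plus polarity-signed B0 displacement (mm)."""
        if polarity not in ("forward", "reverse"):
            raise ValueError("polarity must be 'forward' or 'reverse'")
        d = self.system_displacement(points)
        if self.b0_coeffs:
            sign = 1.0 if polarity == "forward" else -1.0
            d[:, self.read_axis] += sign * self.b0_displacement(points)
        return d

    def max_over_voi(self, half_extent_mm=(130.0, 130.0, 125.0), n: int = 21) -> float:
        """Maximum displacement magnitude sampled over the VOI."""
        axes = [np.linspace(-h, h, n) for h in half_extent_mm]
        g = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([a.ravel() for a in g])
        return float(np.linalg.norm(self.system_displacement(pts), axis=1).max())

    # -- stock models -----------------------------------------------------
    @classmethod
    def zero(cls) -> "DistortionModel":
        return cls()

    @classmethod
    def default_study(
        cls,
        scale: float = 1.0,
        with_b0: bool = True,
        half_extents: tuple[float, float, float] = (120.0, 120.0, 132.8),
        max_mm: float = 5.5,
    ) -> "DistortionModel":
        """Degree-3 field with ``max_mm * scale`` maximum over the
        control-point VOI.

        Each component combines an odd radial term ``a * u * (r/R)^2`` (the
        classic leading behaviour of gradient nonlinearity) with a Chebyshev
        T3 term in one *through-plane* axis, which steepens the field toward
        the volume edges so that through-plane coupling is non-negligible.
        The field vanishes at the isocenter.  ``half_extents`` is the
        control-point lattice half extent per axis; polynomial arguments are
        normalized over a slightly larger box so the field stays tame over
        the grid-bar tails outside the lattice.
        """
        half_extents = tuple(float(h) for h in half_extents)
        rx, ry, rz = (1.125 * h for h in half_extents)
        rr = 1.736 * float(np.mean((rx, ry, rz)))

        def radial(axis_r, amp):
            # amp * (u/ru) * (x^2+y^2+z^2)/rr^2
            u_pow = [0, 0, 0]
            u_pow[axis_r] = 1
            c = {}
            for ax in range(3):
                p = list(u_pow)
                p[ax] += 2
                c[tuple(p)] = amp / ([rx, ry, rz][axis_r] * rr**2)
            return c

        def cheb(axis_gain, axis_osc, amp):
            # amp * (u/ru) * T3(w/rw),  T3(t) = 4 t^3 - 3 t
            rg = [rx, ry, rz][axis_gain]
            ro = [rx, ry, rz][axis_osc]
            base = [0, 0, 0]
            base[axis_gain] = 1
            p3 = list(base)
            p3[axis_osc] += 3
            p1 = list(base)
            p1[axis_osc] += 1
            return {tuple(p3): 4 * amp / (rg * ro**3), tuple(p1): -3 * amp / (rg * ro)}

        def merge(*dicts):
            out = {}
            for d in dicts:
                for k, v in d.items():
                    out[k] = out.get(k, 0.0) + v
            return out

        # harmonic wavelength: ~half the stack height, but never below
        # ~3.7 lattice pitches so the sampled lattice still resolves it
        lam = max(0.46 * half_extents[2], 55.0)
        model = cls(
            coeffs_x=merge(radial(0, 0.9), cheb(0, 2, 2.4)),
            coeffs_y=merge(radial(1, 0.8), cheb(1, 0, 1.9)),
            coeffs_z=merge(radial(2, 2.4), cheb(2, 1, 0.8)),
            harmonics=(
                (0, 1.5, 0, 2, lam),  # dx: gain x, oscillating along z
                (1, 1.3, 1, 2, lam),  # dy: gain y, oscillating along z
            ),
            validity_mm=(1.25 * half_extents[0], 1.25 * half_extents[1], 1.25 * half_extents[2]),
        )
        # rescale so the maximum magnitude over the analyzed VOI (the
        # outermost sheet plane on each side is excluded from analysis)
        # is max_mm*scale
        voi = (half_extents[0], half_extents[1], 0.875 * half_extents[2])
        s = max_mm * scale / model.max_over_voi(voi)
        for c in (model.coeffs_x, model.coeffs_y, model.coeffs_z):
            for k in c:
                c[k] *= s
        model.harmonics = tuple(
            (ax, amp * s, g, o, w) for (ax, amp, g, o, w) in model.harmonics
        )
        if with_b0:
            model.b0_coeffs = {
                (2, 0, 0): 0.6 * scale / rx**2,
                (0, 0, 2): 0.6 * scale / rz**2,
            }
        return model

    @classmethod
    def pure_b0(cls, amplitude_mm: float = 1.0, read_axis: int = 0) -> "DistortionModel":
        return cls(
            b0_coeffs={(2, 0, 0): amplitude_mm / 130.0**2, (0, 0, 2): amplitude_mm / 120.0**2},
            read_axis=read_axis,
        )

    @classmethod
    def separable_linear(cls, slopes=(0.02, 0.015, 0.01)) -> "DistortionModel":
        """Field whose in-plane values do not depend on the through-plane
        coordinate (first-order estimation is exact for it)."""
        return cls(
            coeffs_x={(1, 0, 0): slopes[0]},
            coeffs_y={(0, 1, 0): slopes[1]},
            coeffs_z={(0, 0, 1): slopes[2]},
        )

    def to_json(self, path: str) -> None:
        payload = {
            "coeffs_x": [[list(k), v] for k, v in self.coeffs_x.items()],
            "coeffs_y": [[list(k), v] for k, v in self.coeffs_y.items()],
            "coeffs_z": [[list(k), v] for k, v in self.coeffs_z.items()],
            "harmonics": [list(h) for h in self.harmonics],
            "b0_coeffs": [[list(k), v] for k, v in self.b0_coeffs.items()],
            "read_axis": self.read_axis,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def true_displacement(
    model: DistortionModel, points: np.ndarray, polarity: str = "forward"
) -> np.ndarray:
    """Ground-truth displacement (mm) at the given world points."""
    p = np.atleast_2d(np.asarray(points, float))
    box = np.asarray(model.validity_mm)
    if np.any(np.abs(p) > box * 1.5):
        raise ValueError("points outside the simulator's declared validity box")
    return model.displacement(p, polarity)


@dataclass
class AcquisitionConfig:
    """One simulated scan: orientation, polarity, sampling grid and artifacts."""

    grid_orientation: str = "transverse"
    read_polarity: str = "forward"
    voxel_mm: tuple[float, float, float] = (0.9, 0.9, 1.0)
    matrix: tuple[int, int, int] | None = None
    fov_mm: tuple[float, float] | None = None
    bias_amplitude: float = 0.0
    noise_sigma: float = 0.0
    bubble_count: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.grid_orientation not in ORIENTATION_NORMAL:
            raise ValueError(f"unknown orientation {self.grid_orientation!r}")
        if self.read_polarity not in ("forward", "reverse"):
            raise ValueError("read_polarity must be 'forward' or 'reverse'")


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _interval_coverage(centers: np.ndarray, starts: np.ndarray, width: float) -> np.ndarray:
    """Fraction of each voxel interval covered by a union of equal slabs.

    ``centers``: voxel center coordinates; ``starts``: slab start positions
    (disjoint, equal ``width``).  Exact 1D partial-volume integration.
    """
    h = centers[1] - centers[0] if len(centers) > 1 else width
    lo = centers - h / 2.0
    hi = centers + h / 2.0
    cov = np.zeros_like(centers)
    for s in starts:
        cov += np.clip(np.minimum(hi, s + width) - np.maximum(lo, s), 0.0, None)
    return cov / h


def rasterize_phantom(
    geometry: PhantomGeometry,
    voxel_mm=(1.0, 1.0, 1.0),
    modality: str = "MR",
    orientation: str = "transverse",
    matrix: tuple[int, int, int] | None = None,
    margin_mm: float = 10.0,
) -> Volume:
    """Render the ideal (undistorted) phantom volume, centered on the isocenter.

    The voxel value is the exact partial-volume fraction of grid material
    (1D coverage along each axis, in-plane union ``a + b - a*b``) mapped to a
    two-level modality intensity: MR shows bright oil / dark grid, CT the
    opposite.  Grid bars span the control-point lattice plus half a pitch.
    """
    if modality not in ("MR", "CT"):
        raise ValueError("modality must be 'MR' or 'CT'")
    voxel_mm = tuple(float(v) for v in voxel_mm)
    if any(v <= 0 for v in voxel_mm):
        raise ValueError("voxel_mm must be positive")
    box = np.asarray(geometry.box_inner_mm, float)
    if matrix is None:
        matrix = tuple(int(np.ceil((box[a] + 2 * margin_mm) / voxel_mm[a])) for a in range(3))
    shape = np.asarray(matrix, int)
    extent = (shape - 1) * np.asarray(voxel_mm)
    origin = -extent / 2.0
    if np.any(extent < box - 1e-6):
        raise ValueError("phantom larger than the requested matrix extent")

    coords = [origin[a] + np.arange(shape[a]) * voxel_mm[a] for a in range(3)]
    normal = ORIENTATION_NORMAL[orientation]
    a_ax, b_ax = ORIENTATION_INPLANE[orientation]

    lines = geometry.line_positions()
    bar_w = geometry.grid_bar_width_mm
    bar_cov_a = _interval_coverage(coords[a_ax], lines - bar_w / 2.0, bar_w)
    bar_cov_b = _interval_coverage(coords[b_ax], lines - bar_w / 2.0, bar_w)
    # bars run one full pitch past the outer lattice lines (toward the sheet
    # edge), so the along-bar response is symmetric at the outermost crossings
    half_len = (geometry.points_per_row - 1) / 2.0 * geometry.point_pitch_mm + (
        geometry.point_pitch_mm
    )
    in_len_a = np.clip((half_len - np.abs(coords[a_ax])) / voxel_mm[a_ax] + 0.5, 0.0, 1.0)
    in_len_b = np.clip((half_len - np.abs(coords[b_ax])) / voxel_mm[b_ax] + 0.5, 0.0, 1.0)
    sheets = geometry.sheet_positions()
    slab_cov = _interval_coverage(
        coords[normal], sheets - geometry.sheet_thickness_mm / 2.0, geometry.sheet_thickness_mm
    )
    box_cov = [
        np.clip((box[a] / 2.0 - np.abs(coords[a])) / voxel_mm[a] + 0.5, 0.0, 1.0)
        for a in range(3)
    ]

    # grid fraction: in-plane union of the two bar families (a + b - a*b),
    # modulated by the slab profile along the sheet-normal axis
    idx_shape_a = [1, 1, 1]
    idx_shape_a[a_ax] = -1
    idx_shape_b = [1, 1, 1]
    idx_shape_b[b_ax] = -1
    idx_shape_n = [1, 1, 1]
    idx_shape_n[normal] = -1
    # a bar centered on an a-axis line runs along the b axis (and vice versa):
    # clip its length with the extent factor of the *other* axis
    sa3 = bar_cov_a.reshape(idx_shape_a) * in_len_b.reshape(idx_shape_b)
    sb3 = bar_cov_b.reshape(idx_shape_b) * in_len_a.reshape(idx_shape_a)
    grid = (sa3 + sb3 - sa3 * sb3) * slab_cov.reshape(idx_shape_n)

    inside = (
        box_cov[0].reshape(-1, 1, 1) * box_cov[1].reshape(1, -1, 1) * box_cov[2].reshape(1, 1, -1)
    )
    grid = grid * inside
    oil = inside - grid
    if modality == "MR":
        data = MR_AIR * (1 - inside) + MR_OIL * oil + MR_GRID * grid
    else:
        data = CT_AIR * (1 - inside) + CT_OIL * oil + CT_GRID * grid
    return Volume(
        data=data.astype(np.float32),
        voxel_mm=voxel_mm,
        origin_mm=tuple(origin),
        modality=modality,
        meta={"grid_orientation": orientation},
    )


# ---------------------------------------------------------------------------
# forward imaging model
# ---------------------------------------------------------------------------

def warp_volume(
    ideal: Volume,
    model: DistortionModel,
    config: AcquisitionConfig | None = None,
    interp_order: int = 3,
    tol_mm: float = 0.01,
    max_iter: int = 12,
) -> Volume:
    """Apply the forward imaging model: a structure truly at ``x`` appears at
    ``x + delta(x)``.

    The output voxel at world coordinate ``r`` holds the ideal intensity at
    the pre-image ``x`` of ``r`` under ``T(x) = x + delta(x)``, found by
    fixed-point iteration ``x <- r - delta(x)``.  Pre-images falling outside
    the ideal volume are filled with the background (air) value.
    """
    polarity = config.read_polarity if config is not None else "forward"
    shape = ideal.shape
    coords = [ideal.axis_coords(a) for a in range(3)]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    r = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    x = r.copy()
    # clamp the pre-image search to a plausible displacement range so the
    # fixed point cannot run away where the polynomial grows outside the
    # phantom (those voxels are background anyway); iterate only the
    # not-yet-converged points
    dmax = 4.0 * max(1.0, model.max_over_voi())
    active = np.arange(len(r))
    for _ in range(max_iter):
        ra = r[active]
        d = np.clip(model.displacement(x[active], polarity), -dmax, dmax)
        x_new = np.clip(ra - d, ra - dmax, ra + dmax)
        step = np.abs(x_new - x[active]).max(axis=1)
        x[active] = x_new
        active = active[step >= tol_mm]
        if len(active) == 0:
            break
    idx = (x - np.asarray(ideal.origin_mm)) / np.asarray(ideal.voxel_mm)
    outside = np.any((idx < 0) | (idx > np.asarray(shape) - 1), axis=1)
    n_out = int(outside.sum())
    if n_out:
        log.info("warp_volume: %d pre-image samples outside the ideal volume", n_out)
    warped = ndimage.map_coordinates(
        np.asarray(ideal.data, np.float64),
        idx.T,
        order=interp_order,
        mode="constant",
        cval=float(MR_AIR if ideal.modality == "MR" else CT_AIR),
    ).reshape(shape)
    out = ideal.copy_with(warped.astype(np.float32))
    out.meta["read_polarity"] = polarity
    return out


# ---------------------------------------------------------------------------
# intensity artifacts
# ---------------------------------------------------------------------------

def apply_bias_field(
    volume: Volume, amplitude: float, scale_mm: float = 150.0, seed: int = 0
) -> Volume:
    """Multiply by a smooth positive field in ``[1-amplitude, 1+amplitude]``.

    The field is a seeded mixture of broad Gaussian blobs, normalized to unit
    mean so that the volume's mean intensity is preserved.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must be in [0, 1)")
    if amplitude == 0:
        return volume.copy_with(volume.data.copy())
    rng = np.random.default_rng(seed)
    lo, hi = volume.world_bounds()
    coords = [volume.axis_coords(a) for a in range(3)]
    g = np.zeros(volume.shape)
    for _ in range(4):
        center = rng.uniform(lo, hi)
        w = rng.uniform(-1.0, 1.0)
        parts = [
            np.exp(-0.5 * ((coords[a] - center[a]) / scale_mm) ** 2) for a in range(3)
        ]
        g += w * parts[0][:, None, None] * parts[1][None, :, None] * parts[2][None, None, :]
    # normalize to the requested amplitude over the interior (the imaged
    # object), not over volume corners the phantom never reaches
    sl = tuple(slice(int(0.15 * n), int(0.85 * n) or None) for n in volume.shape)
    m = np.abs(g[sl]).max()
    if m > 0:
        g = np.clip(g / m, -1.0, 1.0)
    bias = 1.0 + amplitude * g
    bias /= bias.mean()
    out = volume.copy_with((volume.data * bias).astype(np.float32))
    out.meta["bias_amplitude"] = amplitude
    return out


def add_noise_and_bubbles(
    volume: Volume,
    noise_sigma: float,
    bubble_count: int = 0,
    seed: int = 0,
    geometry: PhantomGeometry | None = None,
    orientation: str = "transverse",
    guard_mm: float = 5.0,
    bubble_radius_mm: float = 2.5,
) -> Volume:
    """Add Gaussian noise and dark air-bubble ellipsoids at oil locations.

    Bubbles are kept at least ``guard_mm`` (in-plane) away from every nominal
    grid intersection so the ground-truth control-point count is unaffected.
    Deterministic under a fixed seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    data = np.asarray(volume.data, np.float64).copy()
    rng = np.random.default_rng(seed)
    if bubble_count:
        geometry = geometry or PhantomGeometry()
        a_ax, b_ax = ORIENTATION_INPLANE[orientation]
        lines = geometry.line_positions()
        half = (geometry.points_per_row - 1) / 2.0 * geometry.point_pitch_mm
        coords = [volume.axis_coords(a) for a in range(3)]
        air = MR_AIR if volume.modality == "MR" else CT_AIR
        placed = 0
        while placed < bubble_count:
            c = rng.uniform(-half, half, size=3)
            da = np.abs(lines - c[a_ax]).min()
            db = np.abs(lines - c[b_ax]).min()
            if np.hypot(da, db) < guard_mm:
                continue
            # soft ellipsoid: radius bubble_radius_mm, slightly squashed
            radii = bubble_radius_mm * np.array([1.0, 1.0, 0.8])
            sl = []
            ok = True
            for a in range(3):
                i0 = np.searchsorted(coords[a], c[a] - radii[a] - 2)
                i1 = np.searchsorted(coords[a], c[a] + radii[a] + 2)
                if i1 <= i0:
                    ok = False
                    break
                sl.append((i0, i1))
            if not ok:
                continue
            loc = [coords[a][sl[a][0] : sl[a][1]] - c[a] for a in range(3)]
            dist = np.sqrt(
                (loc[0][:, None, None] / radii[0]) ** 2
                + (loc[1][None, :, None] / radii[1]) ** 2
                + (loc[2][None, None, :] / radii[2]) ** 2
            )
            w = np.clip((1.2 - dist) / 0.4, 0.0, 1.0)  # soft edge
            region = data[sl[0][0] : sl[0][1], sl[1][0] : sl[1][1], sl[2][0] : sl[2][1]]
            region[:] = region * (1 - w) + air * w
            placed += 1
    if noise_sigma > 0:
        data += rng.normal(0.0, noise_sigma, size=data.shape)
    out = volume.copy_with(data.astype(np.float32))
    out.meta["noise_sigma"] = noise_sigma
    out.meta["bubble_count"] = bubble_count
    return out


def ideal_orientation_samples(
    model: DistortionModel,
    geometry: PhantomGeometry | None = None,
    orientation: str = "transverse",
    polarity: str = "forward",
    noise_mm: float = 0.0,
    seed: int = 0,
):
    """Noise-free (or Gaussian-perturbed) measurement samples for one
    orientation, bypassing the imaging chain.

    Emulates what a perfect detector would measure: displacement vectors at
    the nominal CT lattice sites.  The in-plane components are exact; the
    through-plane component doubles as the housing offset of the apparent
    sheet position, exactly as the image-based pipeline produces them.
    """
    from .field import DisplacementSamples

    geometry = geometry or PhantomGeometry()
    sites = geometry.nominal_lattice(orientation)
    d = model.displacement(sites, polarity)
    if noise_mm > 0:
        rng = np.random.default_rng(seed)
        d = d + rng.normal(0.0, noise_mm, size=d.shape)
    return DisplacementSamples(
        sites=sites, d=d, provenance="measured", grid_orientation=orientation
    )


# ---------------------------------------------------------------------------
# study-level generation
# ---------------------------------------------------------------------------

def simulate_acquisition(
    geometry: PhantomGeometry,
    model: DistortionModel,
    config: AcquisitionConfig,
    modality: str = "MR",
) -> Volume:
    """Rasterize, warp (MR only; CT is taken distortion-free) and degrade."""
    ideal = rasterize_phantom(
        geometry, config.voxel_mm, modality=modality, orientation=config.grid_orientation,
        matrix=config.matrix,
    )
    vol = ideal
    if modality == "MR":
        vol = warp_volume(ideal, model, config)
        if config.bias_amplitude:
            vol = apply_bias_field(vol, config.bias_amplitude, seed=config.seed + 11)
        if config.noise_sigma or config.bubble_count:
            vol = add_noise_and_bubbles(
                vol,
                config.noise_sigma,
                config.bubble_count,
                seed=config.seed + 13,
                geometry=geometry,
                orientation=config.grid_orientation,
            )
    vol.meta["grid_orientation"] = config.grid_orientation
    vol.meta["read_polarity"] = config.read_polarity
    return vol


def simulate_study(
    geometry: PhantomGeometry | None = None,
    model: DistortionModel | None = None,
    voxel_mm=(0.9, 0.9, 1.0),
    orientations=("transverse", "sagittal", "coronal"),
    polarities=("forward", "reverse"),
    bias_amplitude: float = 0.3,
    noise_sigma: float = 0.05 * (MR_OIL - MR_GRID),
    bubble_count: int = 10,
    seed: int = 0,
) -> dict:
    """Generate a full phantom study: one CT volume plus MR volumes for each
    orientation x polarity.  Returns ``{"ct": Volume, ("transverse",
    "forward"): Volume, ...}``."""
    geometry = geometry or PhantomGeometry()
    model = model if model is not None else DistortionModel.default_study()
    out = {}
    ct_cfg = AcquisitionConfig(grid_orientation="transverse", voxel_mm=voxel_mm)
    out["ct"] = simulate_acquisition(geometry, model, ct_cfg, modality="CT")
    for i, orient in enumerate(orientations):
        for j, pol in enumerate(polarities):
            cfg = AcquisitionConfig(
                grid_orientation=orient,
                read_polarity=pol,
                voxel_mm=voxel_mm,
                bias_amplitude=bias_amplitude,
                noise_sigma=noise_sigma,
                bubble_count=bubble_count,
                seed=seed + 101 * i + 7 * j,
            )
            out[(orient, pol)] = simulate_acquisition(geometry, model, cfg, modality="MR")
    return out


def write_study(study: dict, model: DistortionModel, out_dir: str,
                geometry: PhantomGeometry | None = None) -> None:
    """Write a simulated study: NIfTI volumes, truth CSV and model JSON."""
    import os

    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    short = {"transverse": "tra", "sagittal": "sag", "coronal": "cor"}
    for key, vol in study.items():
        if key == "ct":
            vol.to_nifti(os.path.join(out_dir, "ct.nii.gz"))
        else:
            orient, pol = key
            vol.to_nifti(os.path.join(out_dir, f"mr_{short[orient]}_{pol[:3]}.nii.gz"))
    geometry = geometry or PhantomGeometry()
    pts = geometry.nominal_lattice("transverse")
    d = model.system_displacement(pts)
    pd.DataFrame(
        {
            "x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2],
            "dx_mm": d[:, 0], "dy_mm": d[:, 1], "dz_mm": d[:, 2],
        }
    ).to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    model.to_json(os.path.join(out_dir, "truth.json"))
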