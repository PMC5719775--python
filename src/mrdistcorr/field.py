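"""3D distortion-field estimation from three orthogonal phantom acquisitions.

Each acquisition measures, per control point, the two *in-plane* components
of the displacement field (the through-plane coordinate of a grid sheet is
known only as its apparent — distorted — position).  Combining the
transverse (x,y), sagittal (y,z) and coronal (x,z) data therefore gives a
double estimate of every component:

    dx0 = (dx_tra + dx_cor) / 2
    dy0 = (dy_tra + dy_sag) / 2          (first-order estimate)
    dz0 = (dz_sag + dz_cor) / 2

This first-order estimate is biased wherever the field has through-plane
gradients: an in-plane value measured on a sheet is housed at the sheet's
*apparent* through-plane position.  The iterative refinement re-evaluates
each component at lookup coordinates displaced by the current estimate of
the other components (each orientation's map displaced only along its own
through-plane axis), repeating until the largest per-point change of every
component falls below the cutoff ``phi`` — in practice a handful of passes.
If the iteration gap grows instead of shrinking, the first-order values are
kept and flagged.

The converged per-point samples sit on the regular CT lattice and are
interpolated into a continuous :class:`DistortionMap` (tensor cubic
B-spline) used for image correction and residual analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline

from .detect import ControlPointSet
from .phantom import ORIENTATION_INPLANE, ORIENTATION_NORMAL
from .register import CorrespondenceSet, match_correspondences

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# displacement samples
# ---------------------------------------------------------------------------

@dataclass
class DisplacementSamples:
    """Per-control-point displacement vectors housed at CT coordinates.

    ``sites``: (N, 3) CT world coordinates; ``d``: (N, 3) displacement
    vectors (MR - CT, mm).  ``dr`` always equals the Euclidean norm of the
    vector — asserted on construction.
    """

    sites: np.ndarray
    d: np.ndarray
    provenance: str = "first_order"
    grid_orientation: str | None = None
    sheet: np.ndarray | None = None

    def __post_init__(self):
        self.sites = np.atleast_2d(np.asarray(self.sites, float))
        self.d = np.atleast_2d(np.asarray(self.d, float))
        if self.sites.shape != self.d.shape or self.sites.shape[1] != 3:
            raise ValueError("sites and d must both be (N, 3)")
        if not (np.all(np.isfinite(self.sites)) and np.all(np.isfinite(self.d))):
            raise ValueError("displacement samples must be finite")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def dr(self) -> np.ndarray:
        """Total per-point distortion sqrt(dx^2 + dy^2 + dz^2)."""
        return np.linalg.norm(self.d, axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_mm": self.sites[:, 0], "y_mm": self.sites[:, 1], "z_mm": self.sites[:, 2],
                "dx_mm": self.d[:, 0], "dy_mm": self.d[:, 1], "dz_mm": self.d[:, 2],
                "dr_mm": self.dr,
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def per_axis_displacement(pairs: CorrespondenceSet) -> DisplacementSamples:
    """Per-point displacement vectors MR - CT, housed at the CT sites."""
    if len(pairs) == 0:
        raise ValueError("empty correspondence set")
    sheet = pairs.pairs["sheet"].to_numpy(int) if "sheet" in pairs.pairs else None
    return DisplacementSamples(
        sites=pairs.ct,
        d=pairs.mr - pairs.ct,
        provenance="measured",
        grid_orientation=pairs.grid_orientation,
        sheet=sheet,
    )


def average_forward_reverse(
    fwd: ControlPointSet, rev: ControlPointSet, match_radius_mm: float = 7.5
) -> ControlPointSet:
    """Remove the B0-inhomogeneity shift by averaging forward- and
    reverse-read-gradient point positions, coordinate by coordinate.

    Points without a counterpart within ``match_radius_mm`` are dropped
    with a warning.
    """
    corr = match_correspondences(
        _as_ct_like(fwd), rev, match_radius_mm=match_radius_mm
    )
    dropped = len(fwd) - len(corr)
    if dropped:
        log.warning("average_forward_reverse: dropped %d unmatched point(s)", dropped)
    mean = 0.5 * (corr.ct + corr.mr)
    df = corr.pairs.copy()
    out = pd.DataFrame(
        {
            "x_mm": mean[:, 0], "y_mm": mean[:, 1], "z_mm": mean[:, 2],
            "slice": 0, "sheet": df["sheet"].to_numpy(int),
            "area_px": 0, "intensity": 0.0,
        }
    )
    return ControlPointSet(out, fwd.modality, fwd.grid_orientation, "averaged")


def _as_ct_like(cps: ControlPointSet) -> ControlPointSet:
    # match_correspondences treats its first argument as the reference set
    return cps


# ---------------------------------------------------------------------------
# per-orientation field maps
# ---------------------------------------------------------------------------

def _cluster_1d(values: np.ndarray, gap: float) -> tuple[np.ndarray, np.ndarray]:
    """Cluster scalars into groups separated by more than ``gap``.

    Returns (sorted cluster centers, per-value cluster index).
    """
    order = np.argsort(values)
    sv = values[order]
    breaks = np.flatnonzero(np.diff(sv) > gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(sv)]])
    centers = np.array([sv[s:e].mean() for s, e in zip(starts, ends)])
    labels = np.empty(len(values), int)
    for ci, (s, e) in enumerate(zip(starts, ends)):
        labels[order[s:e]] = ci
    return centers, labels


def _fill_nan_grid(a: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Fill NaN grid nodes with the mean of their non-NaN neighbours."""
    a = a.copy()
    finite = a[np.isfinite(a)]
    if finite.size == 0:
        return np.zeros_like(a)
    for _ in range(max_iter):
        nan = np.isnan(a)
        if not nan.any():
            break
        s = np.where(nan, 0.0, a)
        w = (~nan).astype(float)
        ks = np.ones((3,) * a.ndim)
        num = ndimage.convolve(s, ks, mode="constant")
        den = ndimage.convolve(w, ks, mode="constant")
        fill = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        a[nan] = fill[nan]
    np.nan_to_num(a, copy=False, nan=float(finite.mean()))
    return a


def _major_clusters(values: np.ndarray, gap: float, min_frac: float = 0.25):
    """Cluster and keep only clusters holding at least ``min_frac`` of the
    median cluster population (sparse clusters are stray artifact lines).

    Returns (centers, labels, keep_mask) with labels re-indexed over the
    kept clusters; dropped values get label -1.
    """
    centers, labels = _cluster_1d(values, gap)
    counts = np.bincount(labels, minlength=len(centers))
    good = counts >= max(1, min_frac * np.median(counts))
    if good.all():
        return centers, labels, np.ones(len(values), bool)
    keep = good[labels]
    remap = -np.ones(len(centers), int)
    remap[good] = np.arange(good.sum())
    new_labels = np.where(keep, remap[labels], -1)
    return centers[good], new_labels, keep


class OrientationFieldMap:
    """Continuous in-plane displacement map measured by one orientation.

    The samples of one acquisition form, per grid sheet, a regular in-plane
    lattice of (component_a, component_b) values; the sheet itself sits at
    its apparent (displaced) through-plane position, which varies across the
    sheet.  The map interpolates with a bivariate cubic spline in-plane and
    a non-uniform Catmull-Rom cubic across the warped stack of sheets.
    Queries beyond the sampled volume are extended linearly up to one pitch
    and clamped beyond.
    """

    def __init__(self, samples: DisplacementSamples, pitch_mm: float = 15.0):
        if samples.grid_orientation is None:
            raise ValueError("samples must carry their grid orientation")
        self.orientation = samples.grid_orientation
        self.a_ax, self.b_ax = ORIENTATION_INPLANE[self.orientation]
        self.n_ax = ORIENTATION_NORMAL[self.orientation]
        self.pitch_mm = pitch_mm
        s, d = samples.sites, samples.d
        ua, la, ka = _major_clusters(s[:, self.a_ax], pitch_mm / 2.0)
        ub, lb, kb = _major_clusters(s[:, self.b_ax], pitch_mm / 2.0)
        un, ln, kn = _major_clusters(s[:, self.n_ax], pitch_mm / 2.0)
        keep = ka & kb & kn
        if not keep.all():
            log.info(
                "OrientationFieldMap(%s): ignoring %d sample(s) on stray lines",
                samples.grid_orientation, int((~keep).sum()),
            )
            s, d = s[keep], d[keep]
            la, lb, ln = la[keep], lb[keep], ln[keep]
        na, nb, nk = len(ua), len(ub), len(un)
        if na < 2 or nb < 2:
            raise ValueError("degenerate in-plane lattice; cannot interpolate")
        val_a = np.full((nk, na, nb), np.nan)
        val_b = np.full((nk, na, nb), np.nan)
        wapp = np.full((nk, na, nb), np.nan)
        val_a[ln, la, lb] = d[:, self.a_ax]
        val_b[ln, la, lb] = d[:, self.b_ax]
        wapp[ln, la, lb] = s[:, self.n_ax] + d[:, self.n_ax]
        n_nan = int(np.isnan(val_a).sum())
        if n_nan:
            log.info(
                "OrientationFieldMap(%s): filling %d/%d missing lattice nodes",
                self.orientation, n_nan, val_a.size,
            )
        # extend the in-plane grids by one ghost line per side (linear trend
        # from the edge lines) so queries up to one pitch outside the lattice
        # follow the local gradient; a curvature-based extrapolation would
        # amplify detection noise at the boundary instead
        uae = np.concatenate([[2 * ua[0] - ua[1]], ua, [2 * ua[-1] - ua[-2]]])
        ube = np.concatenate([[2 * ub[0] - ub[1]], ub, [2 * ub[-1] - ub[-2]]])
        kx = min(3, len(uae) - 1)
        ky = min(3, len(ube) - 1)
        self._ua, self._ub, self._un = uae, ube, un
        self._spl_a, self._spl_b, self._spl_w = [], [], []
        for k in range(nk):
            for grid, dest in (
                (val_a[k], self._spl_a), (val_b[k], self._spl_b), (wapp[k], self._spl_w),
            ):
                g = _extend_ghost(_fill_nan_grid(grid))
                dest.append(RectBivariateSpline(uae, ube, g, kx=kx, ky=ky))

    def query(self, points: np.ndarray, axis: int) -> np.ndarray:
        """In-plane displacement component ``axis`` at the given 3D points.

        ``axis`` must be one of the two in-plane axes of this orientation.
        The through-plane coordinate of ``points`` is interpreted in
        apparent (image) space, matching how the samples are housed.
        """
        if axis == self.a_ax:
            spls = self._spl_a
        elif axis == self.b_ax:
            spls = self._spl_b
        else:
            raise ValueError(f"axis {axis} is not in-plane for {self.orientation}")
        p = np.atleast_2d(np.asarray(points, float))
        pa = np.clip(p[:, self.a_ax], self._ua[0] - self.pitch_mm, self._ua[-1] + self.pitch_mm)
        pb = np.clip(p[:, self.b_ax], self._ub[0] - self.pitch_mm, self._ub[-1] + self.pitch_mm)
        w = p[:, self.n_ax]
        nk = len(self._un)
        vals = np.empty((nk, len(p)))
        wk = np.empty((nk, len(p)))
        for k in range(nk):
            vals[k] = spls[k].ev(pa, pb)
            wk[k] = self._spl_w[k].ev(pa, pb)
        if nk == 1:
            return vals[0]
        return _catmull_rom_columns(wk, vals, w, self.pitch_mm)


def _extend_ghost(g: np.ndarray) -> np.ndarray:
    """Pad a 2D value grid with one linearly extrapolated line per side.

    The ghost value ``1.5 * edge - 0.5 * third`` follows the local linear
    trend with modest noise amplification (a two-line slope estimate).
    """
    out = np.pad(g, 1, mode="edge")
    if g.shape[0] >= 3:
        out[0, 1:-1] = 1.5 * g[0] - 0.5 * g[2]
        out[-1, 1:-1] = 1.5 * g[-1] - 0.5 * g[-3]
    elif g.shape[0] == 2:
        out[0, 1:-1] = 2 * g[0] - g[1]
        out[-1, 1:-1] = 2 * g[-1] - g[-2]
    if g.shape[1] >= 3:
        out[1:-1, 0] = 1.5 * g[:, 0] - 0.5 * g[:, 2]
        out[1:-1, -1] = 1.5 * g[:, -1] - 0.5 * g[:, -3]
    elif g.shape[1] == 2:
        out[1:-1, 0] = 2 * g[:, 0] - g[:, 1]
        out[1:-1, -1] = 2 * g[:, -1] - g[:, -2]
    # corners: average of the two adjacent ghost lines' extrapolations
    out[0, 0] = 0.5 * (out[0, 1] + out[1, 0])
    out[0, -1] = 0.5 * (out[0, -2] + out[1, -1])
    out[-1, 0] = 0.5 * (out[-1, 1] + out[-2, 0])
    out[-1, -1] = 0.5 * (out[-1, -2] + out[-2, -1])
    return out


def _catmull_rom_columns(zk: np.ndarray, vk: np.ndarray, w: np.ndarray, pitch: float) -> np.ndarray:
    """Non-uniform Catmull-Rom interpolation along axis 0, per column.

    ``zk``: (K, N) strictly increasing knot positions per column; ``vk``:
    (K, N) values; ``w``: (N,) query positions.  Outside the knot range the
    end segment is extended linearly, clamped one ``pitch`` beyond.
    """
    kmax = zk.shape[0]
    w = np.clip(w, zk[0] - pitch, zk[-1] + pitch)
    j = np.clip(np.sum(zk <= w[None, :], axis=0) - 1, 0, kmax - 2)
    cols = np.arange(zk.shape[1])

    def at(idx):
        idx = np.clip(idx, 0, kmax - 1)
        return zk[idx, cols], vk[idx, cols]

    z0, v0 = at(j - 1)
    z1, v1 = at(j)
    z2, v2 = at(j + 1)
    z3, v3 = at(j + 2)
    h = z2 - z1
    t = np.clip((w - z1) / h, -1.0, 2.0)  # linear-ish extension outside
    m1 = np.where(j > 0, (v2 - v0) / np.maximum(z2 - z0, 1e-9), (v2 - v1) / h)
    m2 = np.where(j < kmax - 2, (v3 - v1) / np.maximum(z3 - z1, 1e-9), (v2 - v1) / h)
    inside = (t >= 0) & (t <= 1)
    t2, t3 = t * t, t * t * t
    herm = (
        (2 * t3 - 3 * t2 + 1) * v1
        + (t3 - 2 * t2 + t) * h * m1
        + (-2 * t3 + 3 * t2) * v2
        + (t3 - t2) * h * m2
    )
    below = v1 + m1 * (w - z1)
    above = v2 + m2 * (w - z2)
    return np.where(inside, herm, np.where(t < 0, below, above))


# ---------------------------------------------------------------------------
# first-order estimate and iterative refinement
# ---------------------------------------------------------------------------

@dataclass
class IterationConfig:
    """Controls of the iterative field refinement."""

    phi_mm: float = 0.2
    max_iter: int = 10
    axis_order: tuple[str, str, str] = ("x", "y", "z")
    interpolator: str = "spline"

    def __post_init__(self):
        if self.phi_mm <= 0 or self.max_iter < 1:
            raise ValueError("need phi_mm > 0 and max_iter >= 1")
        if sorted(self.axis_order) != ["x", "y", "z"]:
            raise ValueError("axis_order must be a permutation of x, y, z")


def build_orientation_maps(
    tra: DisplacementSamples, sag: DisplacementSamples, cor: DisplacementSamples,
    pitch_mm: float = 15.0,
) -> dict:
    return {
        "transverse": OrientationFieldMap(tra, pitch_mm),
        "sagittal": OrientationFieldMap(sag, pitch_mm),
        "coronal": OrientationFieldMap(cor, pitch_mm),
    }


#: which two orientations measure each axis (the double-estimate pairing)
_AXIS_SOURCES = {0: ("transverse", "coronal"), 1: ("transverse", "sagittal"),
                 2: ("sagittal", "coronal")}


def _axis_estimate(maps: dict, sites: np.ndarray, axis: int, d_cur: np.ndarray) -> np.ndarray:
    """Average of the two orientation estimates for one axis, each looked up
    at the site displaced along that orientation's through-plane axis by the
    current estimate of that component."""
    vals = []
    for name in _AXIS_SOURCES[axis]:
        m = maps[name]
        q = sites.copy()
        q[:, m.n_ax] = q[:, m.n_ax] + d_cur[:, m.n_ax]
        vals.append(m.query(q, axis))
    return 0.5 * (vals[0] + vals[1])


def first_order_estimate(
    tra: DisplacementSamples,
    sag: DisplacementSamples,
    cor: DisplacementSamples,
    sites: np.ndarray | None = None,
    maps: dict | None = None,
    pitch_mm: float = 15.0,
) -> DisplacementSamples:
    """Double estimate of the field at the common CT sites (no through-plane
    correction): each axis is the average of its two orientation
    measurements looked up at the undisplaced site."""
    maps = maps or build_orientation_maps(tra, sag, cor, pitch_mm)
    if sites is None:
        sites = tra.sites
    zero = np.zeros_like(sites)
    d = np.column_stack([_axis_estimate(maps, sites, ax, zero) for ax in range(3)])
    return DisplacementSamples(sites=sites, d=d, provenance="first_order")


_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def iterate_field(
    tra: DisplacementSamples,
    sag: DisplacementSamples,
    cor: DisplacementSamples,
    init: DisplacementSamples | None = None,
    config: IterationConfig | None = None,
    maps: dict | None = None,
    pitch_mm: float = 15.0,
) -> tuple[DisplacementSamples, int, bool, dict]:
    """Iteratively refine the field at the common sites.

    Per iteration, each axis in ``config.axis_order`` is re-estimated with
    the lookup coordinates displaced by the latest estimates of the other
    components; the pass repeats until the largest per-site change of all
    three components is below ``config.phi_mm`` simultaneously, or
    ``max_iter`` is reached.  If the final gap exceeds the first gap the
    iteration is deemed divergent and the initial estimate is returned with
    ``converged=False``.

    Returns ``(samples, n_iterations, converged, info)`` where ``info``
    holds the per-iteration gap history.
    """
    config = config or IterationConfig()
    maps = maps or build_orientation_maps(tra, sag, cor, pitch_mm)
    if init is None:
        init = first_order_estimate(tra, sag, cor, maps=maps, pitch_mm=pitch_mm)
    sites = init.sites
    d = init.d.copy()
    gaps: list[float] = []
    converged = False
    n_done = 0
    for n in range(1, config.max_iter + 1):
        d_prev = d.copy()
        for axis_name in config.axis_order:
            ax = _AXIS_INDEX[axis_name]
            d[:, ax] = _axis_estimate(maps, sites, ax, d)
        gap = float(np.abs(d - d_prev).max())
        gaps.append(gap)
        n_done = n
        if gap < config.phi_mm:
            converged = True
            break
    info = {"gaps": gaps, "axis_order": config.axis_order}
    if not converged and len(gaps) >= 2 and gaps[-1] > gaps[0]:
        log.warning(
            "iterate_field: divergent (gap %.3f > initial %.3f); "
            "falling back to the first-order estimate", gaps[-1], gaps[0],
        )
        return (
            DisplacementSamples(sites=sites, d=init.d.copy(), provenance="first_order"),
            n_done, False, info,
        )
    out = DisplacementSamples(sites=sites, d=d, provenance=f"iteration_{n_done}")
    return out, n_done, converged, info


# ---------------------------------------------------------------------------
# continuous map
# ---------------------------------------------------------------------------

class DistortionMap:
    """Continuous 3D displacement field built from lattice samples.

    On a (possibly non-uniform) rectilinear lattice the map is a tensor
    cubic B-spline, exact at the sample sites; one lattice pitch beyond the
    sampled volume the field is extended via linearly extrapolated ghost
    planes, and clamped farther out.  Sites that do not form a lattice fall
    back to scattered linear interpolation (nearest-neighbour outside the
    convex hull) with a warning.
    """

    def __init__(self, samples: DisplacementSamples, method: str = "spline",
                 tol_mm: float = 5.0):
        self.samples = samples
        s = samples.sites
        self.voi = np.stack([s.min(axis=0), s.max(axis=0)])
        self._scattered = None
        if method not in ("spline", "linear"):
            raise ValueError("method must be 'spline' or 'linear'")
        if method == "spline":
            axes, labels = [], []
            keep = np.ones(len(s), bool)
            ok = True
            for ax in range(3):
                c, l, k = _major_clusters(s[:, ax], tol_mm)
                axes.append(c)
                labels.append(l)
                keep &= k
                if len(c) < 2:
                    ok = False
            nx, ny, nz = (len(a) for a in axes)
            if ok and nx * ny * nz <= 2 * len(s):
                d_keep = samples.d[keep]
                lk = [l[keep] for l in labels]
                grid = np.full((nx, ny, nz, 3), np.nan)
                cnt = np.zeros((nx, ny, nz))
                np.add.at(cnt, (lk[0], lk[1], lk[2]), 1.0)
                for c in range(3):
                    acc = np.zeros((nx, ny, nz))
                    np.add.at(acc, (lk[0], lk[1], lk[2]), d_keep[:, c])
                    with np.errstate(invalid="ignore"):
                        grid[..., c] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
                miss = int(np.isnan(grid[..., 0]).sum())
                if miss:
                    log.info("DistortionMap: filling %d missing lattice cells", miss)
                    for c in range(3):
                        grid[..., c] = _fill_nan_grid(grid[..., c])
                self._build_grid(axes, grid)
                return
            log.warning("DistortionMap: sites not griddable; falling back to scattered linear")
        self._build_scattered()

    # -- grid spline path --------------------------------------------------
    def _build_grid(self, axes, grid):
        # ghost planes: linear extrapolation one pitch out
        gaxes = []
        for ax in range(3):
            c = axes[ax]
            step_lo = c[1] - c[0]
            step_hi = c[-1] - c[-2]
            gaxes.append(np.concatenate([[c[0] - step_lo], c, [c[-1] + step_hi]]))
        g = np.pad(grid, ((1, 1), (1, 1), (1, 1), (0, 0)), mode="edge")
        for ax in range(3):
            sl_lo = [slice(None)] * 4
            sl_a = [slice(None)] * 4
            sl_b = [slice(None)] * 4
            sl_lo[ax], sl_a[ax], sl_b[ax] = 0, 1, 2
            g[tuple(sl_lo)] = 2 * g[tuple(sl_a)] - g[tuple(sl_b)]
            sl_lo[ax], sl_a[ax], sl_b[ax] = -1, -2, -3
            g[tuple(sl_lo)] = 2 * g[tuple(sl_a)] - g[tuple(sl_b)]
        self._axes = gaxes
        self._coeff = [
            ndimage.spline_filter(g[..., c], order=3, mode="nearest") for c in range(3)
        ]
        self._grid_mode = True

    def _build_scattered(self):
        from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

        s = self.samples.sites
        self._lin = LinearNDInterpolator(s, self.samples.d)
        self._near = NearestNDInterpolator(s, self.samples.d)
        self._grid_mode = False

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.evaluate(points)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Displacement vectors (N, 3) at arbitrary world points (mm)."""
        p = np.atleast_2d(np.asarray(points, float))
        if not self._grid_mode:
            v = self._lin(p)
            nan = np.isnan(v[:, 0])
            if nan.any():
                v[nan] = self._near(p[nan])
            return v
        idx = np.empty((3, len(p)))
        for ax in range(3):
            c = self._axes[ax]
            idx[ax] = np.interp(p[:, ax], c, np.arange(len(c)))
        out = np.empty((len(p), 3))
        for comp in range(3):
            out[:, comp] = ndimage.map_coordinates(
                self._coeff[comp], idx, order=3, prefilter=False, mode="nearest"
            )
        return out


def build_map(samples: DisplacementSamples, method: str = "spline") -> DistortionMap:
    """Continuous distortion map from lattice samples (see DistortionMap)."""
    return DistortionMap(samples, method=method)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class DistortionStats:
    """Mean / standard deviation / maximum of |dx|, |dy|, |dz| and dr, plus
    the per-plane maximum profile along z."""

    table: pd.DataFrame
    profile: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="index"),
            "profile": self.profile.to_dict(orient="list"),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __getitem__(self, key):
        return self.table.loc[key]


def statistics(samples: DisplacementSamples, plane_gap_mm: float = 7.5) -> DistortionStats:
    """Distortion statistics per axis and total, plus per-z-plane maxima."""
    if len(samples) == 0:
        raise ValueError("empty samples")
    comps = {
        "x": np.abs(samples.d[:, 0]),
        "y": np.abs(samples.d[:, 1]),
        "z": np.abs(samples.d[:, 2]),
        "r": samples.dr,
    }
    table = pd.DataFrame(
        {
            "mean_mm": {k: float(v.mean()) for k, v in comps.items()},
            "std_mm": {k: float(v.std()) for k, v in comps.items()},
            "max_mm": {k: float(v.max()) for k, v in comps.items()},
        }
    )
    centers, labels = _cluster_1d(samples.sites[:, 2], plane_gap_mm)
    prof = {"z_mm": centers}
    for key, v in comps.items():
        prof[f"max_{key}_mm"] = np.array(
            [float(v[labels == i].max()) for i in range(len(centers))]
        )
    return DistortionStats(table=table, profile=pd.DataFrame(prof))


def residual_validation(corrected_volumes: dict, ct_points, pipeline_config=None):
    """Re-run the full mapping pipeline on corrected volumes; the remaining
    distortion is the method's residual.  Delegates to the study driver."""
    from .pipeline import measure_field  # late import: pipeline builds on field

    result = measure_field(corrected_volumes, ct_points, config=pipeline_config)
    return result
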