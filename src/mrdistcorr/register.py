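"""CT/MR control-point registration, artifact cleaning and correspondence.

The CT point set supplies the world (undistorted) coordinates; the MR set
the image (distorted) ones.  Registration is a pure translation: the
phantom is mounted on an alignment jig, so rotations are negligible.  The
z shift aligns the CT z-extent midplane with the MR isocenter plane (z=0);
the in-plane shift is the displacement between the CT and MR points nearest
the isocenter, where distortion is assumed negligible.

Residual detection artifacts (air bubbles and similar) are rejected by
fitting, per grid sheet, a low-order 2D polynomial that maps CT in-plane
coordinates to the detected MR coordinates: points far from the polynomial
prediction are artifacts.  The polynomial is used *only* for outlier
rejection, never as the distortion model itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detect import ControlPointSet

log = logging.getLogger(__name__)

#: axis permutations taking the transverse CT set into the frame of a
#: phantom re-oriented with its sheet normal along x (sagittal) or y
#: (coronal); the permutation swaps the sheet-pitch axis into place.
_ORIENTATION_PERM = {"transverse": (0, 1, 2), "sagittal": (2, 1, 0), "coronal": (0, 2, 1)}


@dataclass
class RigidShift:
    """CT -> MR frame translation (mm)."""

    dx_mm: float = 0.0
    dy_mm: float = 0.0
    dz_mm: float = 0.0

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.dx_mm, self.dy_mm, self.dz_mm])

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) + self.vector


@dataclass
class CorrespondenceSet:
    """Matched CT<->MR point pairs in the common isocenter frame.

    ``pairs`` columns: x_ct, y_ct, z_ct, x_mr, y_mr, z_mr, sheet.
    """

    pairs: pd.DataFrame
    grid_orientation: str = "transverse"
    read_polarity: str = "forward"
    unmatched_ct: int = 0
    removed_artifacts: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ct(self) -> np.ndarray:
        return self.pairs[["x_ct", "y_ct", "z_ct"]].to_numpy(float)

    @property
    def mr(self) -> np.ndarray:
        return self.pairs[["x_mr", "y_mr", "z_mr"]].to_numpy(float)

    def to_csv(self, path: str) -> None:
        self.pairs.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, **kw) -> "CorrespondenceSet":
        return cls(pd.read_csv(path), **kw)


def permute_orientation(ct: ControlPointSet, orientation: str) -> ControlPointSet:
    """Reformat the transverse CT point set to match a rotated acquisition.

    The single transverse CT scan serves as reference for all three MR
    orientations; since only point coordinates matter, re-slicing the CT
    volume is replaced by permuting the coordinate axes of its point set.
    """
    perm = _ORIENTATION_PERM[orientation]
    coords = ct.coords[:, list(perm)]
    out = ct.replace_coords(coords)
    out.grid_orientation = orientation
    return out


def register_ct_to_mr(
    ct: ControlPointSet,
    mr: ControlPointSet,
    pitch_mm: float = 15.0,
) -> RigidShift:
    """Estimate the CT -> MR translation from the isocenter neighbourhood.

    The z shift aligns the midplane of the CT z extent with MR z=0.  The
    x/y shift is read off the pair of points nearest the isocenter — valid
    because distortion is negligible there.
    """
    if len(ct) == 0 or len(mr) == 0:
        raise ValueError("registration requires non-empty point sets")
    ct_xyz = ct.coords
    mr_xyz = mr.coords
    dz = 0.0 - 0.5 * (ct_xyz[:, 2].min() + ct_xyz[:, 2].max())
    shifted_z = ct_xyz[:, 2] + dz
    mid = np.abs(shifted_z) < pitch_mm / 2.0
    if not mid.any():
        raise ValueError("no CT point within half a pitch of the isocenter plane")
    ct_mid = ct_xyz[mid]
    i_ct = np.argmin(np.hypot(ct_mid[:, 0], ct_mid[:, 1]))
    p_ct = ct_mid[i_ct]
    if np.hypot(p_ct[0], p_ct[1]) > pitch_mm / 2.0:
        raise ValueError("no CT point within half a pitch of the isocenter")
    d_mr = np.linalg.norm(mr_xyz, axis=1)
    i_mr = np.argmin(d_mr)
    if d_mr[i_mr] > pitch_mm / 2.0:
        raise ValueError("no MR point within half a pitch of the isocenter")
    p_mr = mr_xyz[i_mr]
    return RigidShift(float(p_mr[0] - p_ct[0]), float(p_mr[1] - p_ct[1]), float(dz))


def _poly2d_design(u: np.ndarray, v: np.ndarray, order: int) -> np.ndarray:
    cols = [u**i * v**j for i in range(order + 1) for j in range(order + 1 - i)]
    return np.column_stack(cols)


def clean_with_polynomial(
    mr: ControlPointSet,
    ct: ControlPointSet,
    order: int = 3,
    tol_mm: float = 3.0,
    pitch_mm: float = 15.0,
    shift: RigidShift | None = None,
) -> ControlPointSet:
    """Remove artifact points that stray from the per-sheet polynomial trend.

    For each MR sheet, a degree-``order`` 2D polynomial maps CT in-plane
    coordinates to the detected MR in-plane coordinates.  MR points whose
    in-plane distance from the prediction at their matched CT site exceeds
    ``tol_mm`` are dropped (air bubbles sit between grid points, several
    pitches of residual away).  Sheets with too few points for the fit pass
    through unfiltered with a warning.
    """
    from .phantom import ORIENTATION_INPLANE, ORIENTATION_NORMAL

    if len(mr) == 0:
        return mr
    orientation = mr.grid_orientation
    a_ax, b_ax = ORIENTATION_INPLANE[orientation]
    n_ax = ORIENTATION_NORMAL[orientation]
    ct_xyz = ct.coords if shift is None else shift.apply(ct.coords)
    n_coef = (order + 1) * (order + 2) // 2
    keep_mask = np.ones(len(mr), bool)
    df = mr.points
    for sheet, idx in df.groupby("sheet").groups.items():
        rows = df.loc[idx]
        muv = rows[["x_mm", "y_mm", "z_mm"]].to_numpy(float)[:, [a_ax, b_ax]]
        w_mean = rows[["x_mm", "y_mm", "z_mm"]].to_numpy(float)[:, n_ax].mean()
        # CT points of the matching sheet: within one sheet pitch through-plane
        near = np.abs(ct_xyz[:, n_ax] - w_mean) < pitch_mm / 2.0 + 2.0
        ct_sheet = ct_xyz[near][:, [a_ax, b_ax]]
        if len(ct_sheet) < n_coef or len(rows) < n_coef:
            log.warning(
                "clean_with_polynomial: sheet %s has too few points for a "
                "degree-%d fit; passed through unfiltered", sheet, order,
            )
            continue
        tree = cKDTree(ct_sheet)
        _, j = tree.query(muv)
        cuv = ct_sheet[j]
        a = _poly2d_design(cuv[:, 0], cuv[:, 1], order)
        # one robust re-fit pass: fit, drop gross outliers, fit again
        sel = np.ones(len(rows), bool)
        for _ in range(2):
            coef, *_ = np.linalg.lstsq(a[sel], muv[sel], rcond=None)
            pred = a @ coef
            res = np.linalg.norm(muv - pred, axis=1)
            new_sel = res < tol_mm
            if new_sel.sum() < n_coef or np.array_equal(new_sel, sel):
                sel = new_sel if new_sel.sum() >= n_coef else sel
                break
            sel = new_sel
        keep_mask[np.asarray(idx)[~sel]] = False
    removed = int((~keep_mask).sum())
    if removed:
        log.info("clean_with_polynomial: removed %d artifact point(s)", removed)
    out = ControlPointSet(
        df[keep_mask].reset_index(drop=True),
        mr.modality,
        mr.grid_orientation,
        mr.read_polarity,
    )
    return out


def match_correspondences(
    ct: ControlPointSet,
    mr: ControlPointSet,
    shift: RigidShift | None = None,
    match_radius_mm: float = 7.5,
) -> CorrespondenceSet:
    """One-to-one CT<->MR matching within a small region around each CT point.

    Each CT point claims its nearest MR point within ``match_radius_mm``;
    conflicting claims are resolved in favour of the closest pair and the
    loser re-queues for its next-nearest candidate.  The result is a
    bijection on the matched subset.
    """
    import heapq

    shift = shift or RigidShift()
    ct_xyz = shift.apply(ct.coords)
    mr_xyz = mr.coords
    if len(mr_xyz) == 0 or len(ct_xyz) == 0:
        return CorrespondenceSet(
            pd.DataFrame(columns=["x_ct", "y_ct", "z_ct", "x_mr", "y_mr", "z_mr", "sheet"]),
            mr.grid_orientation, mr.read_polarity, unmatched_ct=len(ct_xyz),
        )
    tree = cKDTree(mr_xyz)
    kmax = min(len(mr_xyz), 6)
    dists, nbrs = tree.query(ct_xyz, k=kmax, distance_upper_bound=match_radius_mm)
    if kmax == 1:
        dists, nbrs = dists[:, None], nbrs[:, None]
    heap = []
    for i in range(len(ct_xyz)):
        if np.isfinite(dists[i, 0]):
            heapq.heappush(heap, (float(dists[i, 0]), i, 0))
    owner_of_mr: dict[int, tuple[float, int, int]] = {}
    assigned_ct: dict[int, int] = {}
    while heap:
        d, i, rank = heapq.heappop(heap)
        if i in assigned_ct:
            continue
        j = int(nbrs[i, rank])
        if j in owner_of_mr:
            od, oi, _ = owner_of_mr[j]
            if d >= od:
                # re-queue this CT point for its next candidate
                nr = rank + 1
                if nr < kmax and np.isfinite(dists[i, nr]):
                    heapq.heappush(heap, (float(dists[i, nr]), i, nr))
                continue
            # displace the previous owner
            del assigned_ct[oi]
            orank = owner_of_mr[j][2] + 1
            if orank < kmax and np.isfinite(dists[oi, orank]):
                heapq.heappush(heap, (float(dists[oi, orank]), oi, orank))
        owner_of_mr[j] = (d, i, rank)
        assigned_ct[i] = j
    rows = []
    mr_sheet = mr.points["sheet"].to_numpy() if "sheet" in mr.points else np.zeros(len(mr_xyz))
    for i, j in sorted(assigned_ct.items()):
        rows.append(
            dict(
                x_ct=ct_xyz[i, 0], y_ct=ct_xyz[i, 1], z_ct=ct_xyz[i, 2],
                x_mr=mr_xyz[j, 0], y_mr=mr_xyz[j, 1], z_mr=mr_xyz[j, 2],
                sheet=int(mr_sheet[j]),
            )
        )
    pairs = pd.DataFrame(rows)
    unmatched = len(ct_xyz) - len(pairs)
    if unmatched > 0.05 * len(ct_xyz):
        log.warning(
            "match_correspondences: %d of %d CT points unmatched", unmatched, len(ct_xyz)
        )
    return CorrespondenceSet(
        pairs, mr.grid_orientation, mr.read_polarity, unmatched_ct=unmatched,
    )
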