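"""Displacement-field and deformation-gradient reconstruction from beads.

The chain: LoG spot detection -> two-step nearest-neighbour track linking ->
reference/target displacement field -> local weighted-least-squares estimate
of the 2x2 planar deformation gradient F on a grid -> right polar
decomposition F = R U separating rotation from pure stretch.  The z row and
column of F are excluded by design: only the in-plane field is observable in
the experiments this mirrors, and the in-plane claim under test is that a
well-working equibiaxial stretcher produces a diagonal (rotation- and
shear-free) F.

F follows the continuum-mechanics convention F = dx/dX with X in the
reference (undeformed) configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.ndimage as ndi
from scipy.spatial import Delaunay
from skimage.feature import peak_local_max

__all__ = [
    "StretchDecomposition",
    "detect_spots",
    "link_tracks",
    "displacement_field",
    "estimate_F",
    "decompose_F",
    "displacement_map",
    "radial_strain_profile",
]


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_spots(image: np.ndarray, sigma_px: float, pixel_size: float,
                 quality_threshold: Optional[float] = None) -> pd.DataFrame:
    """Detect bright spots as local maxima of the scale-normalized LoG
    response, refined to sub-pixel by an intensity-weighted centroid.

    ``quality_threshold`` is an absolute threshold on the LoG response; when
    omitted, a robust default of median + 5*MAD of the response is used.
    Returns a table (x_um, y_um, response).
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    img = np.asarray(image, float)
    if img.size == 0 or np.ptp(img) == 0:
        warnings.warn("blank or saturated image: no spots detectable", stacklevel=2)
        return pd.DataFrame(columns=["x_um", "y_um", "response"])
    # negative LoG of a bright blob is a positive peak; sigma^2 normalizes scale
    resp = -(sigma_px ** 2) * ndi.gaussian_laplace(img, sigma_px)
    if quality_threshold is None:
        med = np.median(resp)
        mad = np.median(np.abs(resp - med))
        quality_threshold = med + 5.0 * max(mad, 1e-12)
    peaks = peak_local_max(resp, min_distance=max(int(round(2 * sigma_px)), 1),
                           threshold_abs=quality_threshold, exclude_border=False)
    if len(peaks) == 0:
        return pd.DataFrame(columns=["x_um", "y_um", "response"])
    half = int(np.ceil(2 * sigma_px))          # (4 sigma)^2 refinement window
    rows_out = []
    nr, nc = img.shape
    for r0, c0 in peaks:
        rr = np.arange(max(r0 - half, 0), min(r0 + half + 1, nr))
        cc = np.arange(max(c0 - half, 0), min(c0 + half + 1, nc))
        patch = img[np.ix_(rr, cc)]
        w = patch - patch.min()
        tot = w.sum()
        if tot <= 0:
            cy, cx = float(r0), float(c0)
        else:
            cy = float((w.sum(axis=1) * rr).sum() / tot)
            cx = float((w.sum(axis=0) * cc).sum() / tot)
        rows_out.append(((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size,
                         float(resp[r0, c0])))
    out = pd.DataFrame(rows_out, columns=["x_um", "y_um", "response"])
    return out.sort_values(["x_um", "y_um"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _greedy_assign(pa: np.ndarray, pb: np.ndarray, max_dist: float):
    """Globally cost-ordered greedy one-to-one assignment between point sets.

    Ties in distance resolve deterministically by lowest (a, b) index pair.
    Returns list of (ia, ib).
    """
    if len(pa) == 0 or len(pb) == 0:
        return []
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    ia, ib = np.nonzero(d <= max_dist)
    order = np.lexsort((ib, ia, d[ia, ib]))     # distance, then lowest ids
    used_a = np.zeros(len(pa), bool)
    used_b = np.zeros(len(pb), bool)
    pairs = []
    for k in order:
        a, b = ia[k], ib[k]
        if not used_a[a] and not used_b[b]:
            used_a[a] = used_b[b] = True
            pairs.append((a, b))
    return pairs


def link_tracks(detections, max_disp: float, max_gap: int = 0) -> pd.DataFrame:
    """Two-step track linking: greedy frame-to-frame segment creation under
    ``max_disp``, then gap closing joining segment ends separated by up to
    ``max_gap`` missing frames within ``max_disp * gap`` distance.

    ``detections`` is either a per-frame list of (x_um, y_um) tables or one
    table with a ``frame`` column.  Returns a BeadTrackTable
    (track_id, frame, x_um, y_um).
    """
    if isinstance(detections, pd.DataFrame):
        frames = np.sort(detections.frame.unique())
        per_frame = {int(f): detections[detections.frame == f][["x_um", "y_um"]]
                     .to_numpy() for f in frames}
    else:
        per_frame = {f: np.atleast_2d(np.asarray(d)[..., :2]) if len(d) else
                     np.empty((0, 2)) for f, d in enumerate(detections)}
        frames = np.array(sorted(per_frame))
    # step 1: frame-to-frame segments
    segments = []   # each: list of (frame, x, y)
    active = {}     # det index in previous frame -> segment idx
    prev_f = None
    for f in frames:
        pts = per_frame[f]
        if prev_f is None or f != prev_f + 1 or len(active) == 0:
            new_active = {}
        else:
            pa = per_frame[prev_f]
            pairs = _greedy_assign(pa, pts, max_disp)
            new_active = {}
            for a, b in pairs:
                if a in active:
                    seg = active[a]
                    segments[seg].append((f, pts[b, 0], pts[b, 1]))
                    new_active[b] = seg
        for i in range(len(pts)):
            if i not in new_active:
                segments.append([(f, pts[i, 0], pts[i, 1])])
                new_active[i] = len(segments) - 1
        active = new_active
        prev_f = f
    # step 2: gap closing
    if max_gap > 0 and len(segments) > 1:
        starts = np.array([s[0][0] for s in segments])
        ends = np.array([s[-1][0] for s in segments])
        merged_into = np.arange(len(segments))
        cands = []
        for i in range(len(segments)):
            for j in range(len(segments)):
                if i == j:
                    continue
                gap = starts[j] - ends[i]
                if 2 <= gap <= max_gap + 1:
                    d = np.hypot(segments[i][-1][1] - segments[j][0][1],
                                 segments[i][-1][2] - segments[j][0][2])
                    if d <= max_disp * gap:
                        cands.append((d, i, j))
        cands.sort()
        tail_used = set()
        head_used = set()
        links = {}
        for d, i, j in cands:
            if i not in tail_used and j not in head_used:
                tail_used.add(i)
                head_used.add(j)
                links[i] = j
        # follow chains
        heads = [i for i in range(len(segments)) if i not in head_used]
        chains = []
        for h in heads:
            chain = [h]
            while chain[-1] in links:
                chain.append(links[chain[-1]])
            chains.append(chain)
        segments = [[pt for s in chain for pt in segments[s]] for chain in chains]
    # assemble, track ids ordered by (first frame, x, y) for determinism
    segments.sort(key=lambda s: (s[0][0], s[0][1], s[0][2]))
    rows = [(tid, f, x, y) for tid, seg in enumerate(segments) for f, x, y in seg]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])


# ---------------------------------------------------------------------------
# displacement field
# ---------------------------------------------------------------------------

def displacement_field(tracks: pd.DataFrame, frame_ref: int = 0,
                       frame_target: Optional[int] = None) -> pd.DataFrame:
    """Per-bead displacement between a reference and a target frame.

    Only tracks present in both frames contribute.  Returns a table
    (track_id, x0, y0, ux, uy); fewer than 3 usable tracks is an error (the
    field would be underdetermined for any local affine model).
    """
    if frame_target is None:
        frame_target = int(tracks.frame.max())
    a = tracks[tracks.frame == frame_ref].set_index("track_id")
    b = tracks[tracks.frame == frame_target].set_index("track_id")
    common = a.index.intersection(b.index)
    out = pd.DataFrame({
        "track_id": common,
        "x0": a.loc[common, "x_um"].to_numpy(),
        "y0": a.loc[common, "y_um"].to_numpy(),
        "ux": b.loc[common, "x_um"].to_numpy() - a.loc[common, "x_um"].to_numpy(),
        "uy": b.loc[common, "y_um"].to_numpy() - a.loc[common, "y_um"].to_numpy(),
    }).reset_index(drop=True)
    if frame_ref == frame_target:
        out[["ux", "uy"]] = 0.0
    if len(out) < 3:
        raise ValueError(f"only {len(out)} tracks span frames {frame_ref}->{frame_target}; "
                         "displacement field is underdetermined")
    return out


# ---------------------------------------------------------------------------
# deformation gradient
# ---------------------------------------------------------------------------

def estimate_F(dispfield: pd.DataFrame, center, radius: float,
               grid_spacing: Optional[float] = None,
               neighborhood_radius: Optional[float] = None,
               kernel: str = "gaussian") -> pd.DataFrame:
    """Local weighted-least-squares deformation-gradient map.

    At each node of a square grid clipped to the pillar disc, the local
    affine model ``u_i ~ a + (F - I)(p_i - node)`` is fitted to beads within
    ``neighborhood_radius`` with Gaussian kernel weights (bandwidth =
    neighborhood_radius / 2).  Nodes with fewer than 3 beads or collinear
    support are masked (dropped), never extrapolated.

    The default neighborhood adapts to bead density,
    ``max(1.5 * grid_spacing, radius * sqrt(10 / n_beads))`` (about ten beads
    of support), shrinking the smoothing scale — and with it the curvature
    bias of the local affine model near the pillar centre — as beads densify.

    Returns a DeformationGradientMap table with columns
    (x, y, Fxx, Fxy, Fyx, Fyy, n_support, rms_residual).
    """
    center = np.asarray(center, float)
    if grid_spacing is None:
        grid_spacing = radius / 20.0
    if neighborhood_radius is None:
        neighborhood_radius = max(1.5 * grid_spacing,
                                  radius * np.sqrt(10.0 / max(len(dispfield), 10)))
    h = neighborhood_radius / 2.0
    p = dispfield[["x0", "y0"]].to_numpy()
    u = dispfield[["ux", "uy"]].to_numpy()

    ax = np.arange(-radius, radius + grid_spacing / 2, grid_spacing)
    gx, gy = np.meshgrid(center[0] + ax, center[1] + ax)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    nodes = nodes[np.hypot(nodes[:, 0] - center[0], nodes[:, 1] - center[1]) <= radius]

    rows = []
    for q in nodes:
        d = np.linalg.norm(p - q, axis=1)
        sel = d <= neighborhood_radius
        n = int(sel.sum())
        if n < 3:
            continue
        dp = p[sel] - q
        if kernel == "gaussian":
            w = np.exp(-0.5 * (d[sel] / h) ** 2)
        elif kernel == "uniform":
            w = np.ones(n)
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
        sw = np.sqrt(w)
        X = np.column_stack([np.ones(n), dp[:, 0], dp[:, 1]]) * sw[:, None]
        # collinearity check on the weighted, centred positions
        if np.linalg.matrix_rank(X, tol=1e-8 * max(np.linalg.norm(X), 1e-30)) < 3:
            continue
        Y = u[sel] * sw[:, None]
        beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        M = beta[1:].T                      # gradient of u: (F - I)
        F = np.eye(2) + M
        resid = Y - X @ beta
        rms = float(np.sqrt(np.mean(resid ** 2)))
        rows.append((q[0], q[1], F[0, 0], F[0, 1], F[1, 0], F[1, 1], n, rms))
    return pd.DataFrame(rows, columns=["x", "y", "Fxx", "Fxy", "Fyx", "Fyy",
                                       "n_support", "rms_residual"])


def F_matrices(fmap: pd.DataFrame) -> np.ndarray:
    """Stack the per-node 2x2 matrices of a DeformationGradientMap."""
    return fmap[["Fxx", "Fxy", "Fyx", "Fyy"]].to_numpy().reshape(-1, 2, 2)


@dataclass(frozen=True)
class StretchDecomposition:
    """Right polar decomposition F = R(rotation) U of one gradient tensor."""

    rotation_deg: float
    lambda1: float              # principal stretches, lambda1 >= lambda2
    lambda2: float
    max_shear: float            # (lambda1 - lambda2) / 2
    offdiag_norm: float         # max(|Fxy|, |Fyx|) of the input tensor
    physical: bool              # det(F) > 0

    @property
    def equibiaxiality(self):
        """lambda2 / lambda1; 1 for a perfectly equibiaxial stretch."""
        return self.lambda2 / self.lambda1


def decompose_F(F: np.ndarray) -> StretchDecomposition:
    """Split a 2x2 deformation gradient into rotation and pure stretch.

    The reported rotation follows the package angle convention (CCW positive
    in the mathematical frame); non-positive det(F) is flagged non-physical.
    """
    F = np.asarray(F, float).reshape(2, 2)
    physical = bool(np.linalg.det(F) > 0)
    R, U = scipy.linalg.polar(F, side="right")
    lam = np.sort(np.linalg.eigvalsh(U))[::-1]
    # image coords: CCW mathematical rotation is [[c, s], [-s, c]]
    rotation = float(np.degrees(np.arctan2(R[0, 1], R[0, 0])))
    return StretchDecomposition(
        rotation_deg=rotation, lambda1=float(lam[0]), lambda2=float(lam[1]),
        max_shear=float((lam[0] - lam[1]) / 2.0),
        offdiag_norm=float(max(abs(F[0, 1]), abs(F[1, 0]))), physical=physical)


def decompose_map(fmap: pd.DataFrame) -> pd.DataFrame:
    """Per-node polar decomposition of a DeformationGradientMap."""
    recs = [decompose_F(F) for F in F_matrices(fmap)]
    out = fmap.copy()
    out["rotation_deg"] = [r.rotation_deg for r in recs]
    out["lambda1"] = [r.lambda1 for r in recs]
    out["lambda2"] = [r.lambda2 for r in recs]
    out["max_shear"] = [r.max_shear for r in recs]
    out["physical"] = [r.physical for r in recs]
    return out


# ---------------------------------------------------------------------------
# displacement magnitude map, strain bands
# ---------------------------------------------------------------------------

def displacement_map(dispfield: pd.DataFrame, grid_x: np.ndarray,
                     grid_y: np.ndarray, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted |u| on a grid, masked (NaN) outside the
    convex hull of the bead positions."""
    p = dispfield[["x0", "y0"]].to_numpy()
    mag = np.hypot(dispfield.ux, dispfield.uy).to_numpy()
    pts = np.column_stack([np.asarray(grid_x).ravel(), np.asarray(grid_y).ravel()])
    d = np.linalg.norm(pts[:, None, :] - p[None, :, :], axis=2)
    exact = d < 1e-9
    with np.errstate(divide="ignore"):
        w = 1.0 / d ** power
    w[exact] = 0.0
    vals = (w * mag).sum(axis=1) / w.sum(axis=1)
    hit_i, hit_j = np.nonzero(exact)
    vals[hit_i] = mag[hit_j]
    if len(p) >= 3:
        try:
            hull = Delaunay(p)
            vals[hull.find_simplex(pts) < 0] = np.nan
        except Exception:   # degenerate (collinear) bead sets: no mask
            pass
    return vals.reshape(np.asarray(grid_x).shape)


def radial_strain_profile(fmap: pd.DataFrame, center, radius: float,
                          n_bands: int = 3,
                          dispfield: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Band-averaged strain over equal-width annuli of the pillar.

    Strain per node is the mean principal stretch minus one,
    ``(lambda1 + lambda2)/2 - 1``; the bands mirror the three concentric
    areas used to stratify the deformation gradient.  When ``dispfield`` is
    given, per-band mean displacement magnitude is reported too.
    """
    center = np.asarray(center, float)
    dec = decompose_map(fmap)
    r = np.hypot(dec.x - center[0], dec.y - center[1]).to_numpy()
    strain = ((dec.lambda1 + dec.lambda2) / 2.0 - 1.0).to_numpy()
    edges = np.linspace(0.0, radius, n_bands + 1)
    rows = []
    for b in range(n_bands):
        sel = (r >= edges[b]) & (r < edges[b + 1] if b < n_bands - 1 else r <= edges[b + 1])
        rec = {"band": b, "r_lo": edges[b], "r_hi": edges[b + 1],
               "n_nodes": int(sel.sum())}
        if sel.sum() == 0:
            rec.update(mean_strain=np.nan, sd_strain=np.nan, mean_disp=np.nan,
                       missing=True)
        else:
            rec.update(mean_strain=float(strain[sel].mean()),
                       sd_strain=float(strain[sel].std(ddof=0)), missing=False)
            if dispfield is not None:
                rd = np.hypot(dispfield.x0 - center[0], dispfield.y0 - center[1])
                dsel = (rd >= edges[b]) & (rd < edges[b + 1])
                mag = np.hypot(dispfield.ux, dispfield.uy)[dsel]
                rec["mean_disp"] = float(mag.mean()) if len(mag) else np.nan
            else:
                rec["mean_disp"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
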