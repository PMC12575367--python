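"""Quantification of cell alignment to a radial micropattern.

The pillar area is partitioned into 10-degree theta-sectors; the angular
alignment gamma of an object is the axial difference between its orientation
(nucleus ellipse axis, or tile-level dominant actin orientation) and the
orientation of the sector containing it.  A population following the pattern
gives a gamma histogram peaked at 0 (Gaussian fit mu ~ 0) and per-sector mean
orientations regressing on sector orientation with slope ~ 1.  Stratifying by
annular r-band checks that the radial strain gradient does not perturb
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from skimage.measure import regionprops
from skimage.segmentation import clear_border

from .angles import (axial_circular_mean, axial_circular_std, mod_axial,
                     polar_angle_deg, wrap_axial_difference)

__all__ = [
    "SectorPartition",
    "partition",
    "measure_nucleus_orientation",
    "measure_dominant_orientation",
    "angular_alignment",
    "fit_gamma",
    "orientation_regression",
    "alignment_by_rband",
]


@dataclass(frozen=True)
class SectorPartition:
    """Polar sectorization of the pillar area.

    ``theta_width`` must divide 360; sector k covers polar angles
    [k*w, (k+1)*w) — a point exactly on a boundary belongs to the
    higher-index sector.  Sector orientation is the axial angle of the
    bisecting radius, in [0, 180).
    """

    center: tuple
    theta_width: float = 10.0
    r_edges: Sequence[float] = (0.0, 100.0, 200.0, 300.0)

    def __post_init__(self):
        n = 360.0 / self.theta_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("360 must be an integer multiple of theta_width")
        if np.any(np.diff(self.r_edges) <= 0):
            raise ValueError("r_edges must be strictly increasing")

    @property
    def n_sectors(self):
        return int(round(360.0 / self.theta_width))

    @property
    def n_bands(self):
        return len(self.r_edges) - 1

    def polar_angle(self, x, y):
        """Polar angle in [0, 360) of points about the centre."""
        return polar_angle_deg(np.asarray(x, float) - self.center[0],
                               np.asarray(y, float) - self.center[1]) % 360.0

    def sector_index(self, x, y):
        return np.floor(self.polar_angle(x, y) / self.theta_width).astype(int) \
            % self.n_sectors

    def sector_orientation(self, index):
        """Axial orientation (deg in [0,180)) of the sector bisector."""
        idx = np.asarray(index)
        return mod_axial((idx + 0.5) * self.theta_width)

    def band_index(self, x, y):
        """Annular band index, -1 outside [r_edges[0], r_edges[-1]]."""
        r = np.hypot(np.asarray(x, float) - self.center[0],
                     np.asarray(y, float) - self.center[1])
        idx = np.searchsorted(self.r_edges, r, side="right") - 1
        idx = np.where((r < self.r_edges[0]) | (r > self.r_edges[-1]), -1,
                       np.clip(idx, 0, self.n_bands - 1))
        return idx if idx.ndim else int(idx)


def partition(center, theta_width: float = 10.0,
              r_edges: Optional[Sequence[float]] = None,
              pillar_radius: Optional[float] = None,
              n_bands: int = 3) -> SectorPartition:
    """Build a sector partition; default r-bands are ``n_bands`` equal-width
    annuli over the pillar radius."""
    if r_edges is None:
        if pillar_radius is None:
            raise ValueError("give r_edges or pillar_radius")
        r_edges = tuple(np.linspace(0.0, pillar_radius, n_bands + 1))
    return SectorPartition(center=tuple(center), theta_width=theta_width,
                           r_edges=tuple(r_edges))


# ---------------------------------------------------------------------------
# orientation measurement
# ---------------------------------------------------------------------------

def _axial_orientation_from_coords(coords_rc: np.ndarray):
    """Axial orientation (deg, [0,180)) and axis ratio from region pixel
    coordinates (row, col), via second central moments in the package's
    mathematical angle convention (x = col, y = -row)."""
    x = coords_rc[:, 1].astype(float)
    y = -coords_rc[:, 0].astype(float)
    x -= x.mean()
    y -= y.mean()
    cxx, cyy, cxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    orient = mod_axial(0.5 * np.degrees(np.arctan2(2.0 * cxy, cxx - cyy)))
    tr, det = cxx + cyy, cxx * cyy - cxy ** 2
    disc = max(tr * tr / 4.0 - det, 0.0)
    l1 = tr / 2.0 + np.sqrt(disc)
    l2 = tr / 2.0 - np.sqrt(disc)
    ratio = np.sqrt(l1 / l2) if l2 > 1e-12 else np.inf
    return float(orient), float(ratio)


def measure_nucleus_orientation(label_image: np.ndarray, pixel_size: float,
                                min_axis_ratio: float = 1.05,
                                kind: str = "nucleus") -> pd.DataFrame:
    """Per-object orientation records from a label image.

    Each labelled object contributes its second-moment ellipse orientation;
    near-circular objects (axis ratio below ``min_axis_ratio``) are flagged
    unreliable and excluded from gamma statistics downstream.  Objects
    touching the image border are excluded outright.

    Returns (object_id, kind, x_um, y_um, orientation_deg, axis_ratio,
    area_um2, reliable).
    """
    cleared = clear_border(np.asarray(label_image))
    rows = []
    for rp in regionprops(cleared):
        orient, ratio = _axial_orientation_from_coords(rp.coords)
        cy, cx = rp.centroid
        rows.append((int(rp.label), kind, (cx + 0.5) * pixel_size,
                     (cy + 0.5) * pixel_size, orient, ratio,
                     rp.area * pixel_size ** 2, bool(ratio >= min_axis_ratio)))
    return pd.DataFrame(rows, columns=["object_id", "kind", "x_um", "y_um",
                                       "orientation_deg", "axis_ratio",
                                       "area_um2", "reliable"])


def measure_dominant_orientation(tile: np.ndarray, sigma: float = 2.0,
                                 n_bins: int = 90,
                                 coherence_threshold: float = 0.5):
    """Dominant axial orientation of image texture in a tile.

    A gradient structure-tensor orientation histogram (gradient-energy
    weighted) is smoothed circularly and its mode taken, as a directionality
    histogram would; returns ``(orientation_deg, dispersion_deg, coherent)``.
    Isotropic tiles (mean coherence below threshold) return
    ``(nan, nan, False)``.
    """
    import scipy.ndimage as ndi
    img = np.asarray(tile, float)
    # smooth first to suppress pixel noise
    sm = ndi.gaussian_filter(img, sigma)
    gr, gc = np.gradient(sm)
    gx, gy = gc, -gr                       # image -> mathematical convention
    jxx = ndi.uniform_filter(gx * gx, 9)
    jyy = ndi.uniform_filter(gy * gy, 9)
    jxy = ndi.uniform_filter(gx * gy, 9)
    energy = jxx + jyy
    coh = np.sqrt((jxx - jyy) ** 2 + 4 * jxy ** 2) / np.where(energy > 0, energy, 1.0)
    if float(np.average(coh, weights=np.maximum(energy, 1e-12))) < coherence_threshold:
        return float("nan"), float("nan"), False
    # structure orientation is perpendicular to the gradient orientation
    grad_orient = 0.5 * np.degrees(np.arctan2(2 * jxy, jxx - jyy))
    orient = mod_axial(grad_orient + 90.0)
    w = (energy * coh).ravel()
    hist, edges = np.histogram(orient.ravel(), bins=n_bins, range=(0.0, 180.0),
                               weights=w)
    kern = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    kern /= kern.sum()
    smoothed = np.convolve(np.r_[hist[-2:], hist, hist[:2]], kern, "same")[2:-2]
    mode_bin = int(np.argmax(smoothed))
    dominant = float((edges[mode_bin] + edges[mode_bin + 1]) / 2.0)
    gamma = wrap_axial_difference(orient.ravel() - dominant)
    dispersion = float(np.sqrt(np.average(gamma ** 2, weights=np.maximum(w, 1e-12))))
    return dominant, dispersion, True


# ---------------------------------------------------------------------------
# gamma statistics
# ---------------------------------------------------------------------------

def angular_alignment(records: pd.DataFrame, part: SectorPartition) -> pd.DataFrame:
    """Angular alignment gamma of each record w.r.t. its theta-sector.

    gamma = axial difference (orientation - sector orientation), wrapped to
    [-90, 90).  Records outside the annular analysis area, or flagged
    unreliable, are excluded (their count is retained in ``attrs``).
    """
    df = records.copy()
    if "reliable" in df.columns:
        n_unreliable = int((~df.reliable).sum())
        df = df[df.reliable]
    else:
        n_unreliable = 0
    band = np.atleast_1d(part.band_index(df.x_um, df.y_um))
    inside = band >= 0
    n_outside = int((~inside).sum())
    df = df[inside].copy()
    band = band[inside]
    sector = part.sector_index(df.x_um, df.y_um)
    sector_or = part.sector_orientation(sector)
    df["sector"] = sector
    df["sector_orientation"] = sector_or
    df["band"] = band
    df["gamma"] = wrap_axial_difference(df.orientation_deg.to_numpy() - sector_or)
    df.attrs["n_excluded_outside"] = n_outside
    df.attrs["n_excluded_unreliable"] = n_unreliable
    return df


def fit_gamma(gamma, n_bins: int = 36):
    """Gaussian fit of the gamma distribution.

    Primary: maximum-likelihood normal fit on the raw angles.  A
    least-squares Gaussian fit to the binned histogram is reported alongside
    (the histogram-level route), plus a wrapped (circular, angle-doubled)
    sd as a cross-check.  Refuses n < 10.
    """
    g = np.asarray(gamma, float)
    g = g[np.isfinite(g)]
    if len(g) < 10:
        raise ValueError(f"need >= 10 gamma values, got {len(g)}")
    mu, sigma = scipy.stats.norm.fit(g)
    degenerate = bool(sigma < 1e-9)
    counts, edges = np.histogram(g, bins=n_bins, range=(-90.0, 90.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist_mu, hist_sigma = np.nan, np.nan
    if not degenerate and counts.max() > 0:
        def gauss(x, a, m, s):
            return a * np.exp(-0.5 * ((x - m) / s) ** 2)
        try:
            popt, _ = scipy.optimize.curve_fit(
                gauss, centers, counts, p0=[counts.max(), mu, max(sigma, 1.0)],
                maxfev=5000)
            hist_mu, hist_sigma = float(popt[1]), float(abs(popt[2]))
        except RuntimeError:
            pass
    wrapped_sigma = axial_circular_std(g)   # gamma treated as axial residual
    return {"mu": float(mu), "sigma": float(sigma),
            "hist_mu": hist_mu, "hist_sigma": hist_sigma,
            "wrapped_sigma": wrapped_sigma, "n": int(len(g)),
            "degenerate": degenerate,
            "histogram": {"counts": counts.tolist(),
                          "bin_edges": edges.tolist()}}


def sector_means(aligned: pd.DataFrame, part: SectorPartition,
                 n_min: int = 5) -> pd.DataFrame:
    """Per-sector axial circular mean orientation; sectors with fewer than
    ``n_min`` objects or a degenerate circular mean are dropped.

    The mod-180 mean is moved to the sector's branch (mean +/- 180) only
    when it lies within 45 degrees of the sector orientation, so that
    pattern-following populations regress linearly across the 0/180 seam
    while a pattern-ignoring population keeps its flat (slope ~ 0) response.
    """
    rows = []
    for sec, grp in aligned.groupby("sector"):
        if len(grp) < n_min:
            continue
        t = np.radians(2.0 * grp.orientation_deg.to_numpy())
        resultant = np.hypot(np.mean(np.sin(t)), np.mean(np.cos(t)))
        if resultant < 1e-3:
            continue    # mean direction undefined
        m = axial_circular_mean(grp.orientation_deg)
        so = float(part.sector_orientation(sec))
        if abs(wrap_axial_difference(m - so)) < 45.0:
            m = so + wrap_axial_difference(m - so)   # branch of the sector
        rows.append((int(sec), so, m, len(grp)))
    return pd.DataFrame(rows, columns=["sector", "sector_orientation",
                                       "mean_orientation", "n"])


def orientation_regression(aligned: pd.DataFrame, part: SectorPartition,
                           n_min: int = 5):
    """OLS of per-sector mean object orientation on sector orientation.

    Perfect pattern-following gives slope 1, intercept 0, r^2 = 1; a
    population with a fixed lab-frame orientation gives slope ~ 0.  Requires
    at least 5 admissible sectors.
    """
    means = sector_means(aligned, part, n_min=n_min)
    if len(means) < 5:
        raise ValueError(f"only {len(means)} sectors with n >= {n_min}; "
                         "regression refused")
    res = scipy.stats.linregress(means.sector_orientation, means.mean_orientation)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2), "n_sectors": int(len(means)),
            "per_sector": means}


def alignment_by_rband(records: pd.DataFrame, part: SectorPartition,
                       n_min_band: int = 10, n_min_sector: int = 5) -> dict:
    """The gamma pipeline repeated within each annular band.

    Returns {band: summary-dict}; bands with fewer than ``n_min_band``
    records report ``{"insufficient": True, "n": ...}``.
    """
    aligned = angular_alignment(records, part)
    out = {}
    for b in range(part.n_bands):
        sub = aligned[aligned.band == b]
        if len(sub) < n_min_band:
            out[b] = {"insufficient": True, "n": int(len(sub))}
            continue
        summary = {"insufficient": False, "n": int(len(sub)),
                   "fit": fit_gamma(sub.gamma)}
        try:
            summary["regression"] = orientation_regression(sub, part,
                                                           n_min=n_min_sector)
        except ValueError:
            summary["regression"] = None
        out[b] = summary
    return out
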