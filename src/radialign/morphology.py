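"""Cell morphology, live/dead viability counting and group tests.

Morphology is area + aspect ratio from thresholded f-actin images (ellipse
moments); aspect ratio doubles as the polarity readout.  Viability is
two-channel component counting: live from the green (calcein) channel, dead
from the red (propidium iodide) channel, percentages normalized to the total
counted.  Group comparisons use one-way ANOVA and Kruskal-Wallis with
Holm-adjusted pairwise rank post-hocs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from skimage.filters import threshold_otsu
from skimage.measure import label as sklabel, regionprops
from skimage.segmentation import clear_border
from statsmodels.stats.multitest import multipletests

from .alignment import _axial_orientation_from_coords

__all__ = ["MorphologyRecord", "ViabilitySummary", "area_aspect", "live_dead",
           "proliferation", "group_tests"]


@dataclass(frozen=True)
class ViabilitySummary:
    n_live: int
    n_dead: int

    @property
    def n_total(self):
        return self.n_live + self.n_dead

    @property
    def pct_live(self):
        return 100.0 * self.n_live / self.n_total

    @property
    def pct_dead(self):
        return 100.0 * self.n_dead / self.n_total


def _binarize(image: np.ndarray, threshold: Optional[float]) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == bool:
        return img
    if threshold is None:
        if np.ptp(img) == 0:
            return np.zeros(img.shape, bool)
        threshold = threshold_otsu(np.asarray(img, float))
    return np.asarray(img, float) > threshold


def area_aspect(image: np.ndarray, pixel_size: float,
                threshold: Optional[float] = None, min_area_px: int = 9,
                condition: Optional[str] = None) -> pd.DataFrame:
    """Per-cell area and aspect ratio from an intensity image or binary mask.

    Global threshold (Otsu by default) -> connected components -> per
    component area and moment-ellipse axes.  Border-touching components are
    excluded; touching cells merge into one record (known limitation of
    global thresholding).  Returns (cell_id, area_um2, aspect_ratio,
    orientation_deg, x_um, y_um, condition).
    """
    mask = _binarize(image, threshold)
    lab = clear_border(sklabel(mask))
    rows = []
    for rp in regionprops(lab):
        if rp.area < min_area_px:
            continue
        orient, ratio = _axial_orientation_from_coords(rp.coords)
        cy, cx = rp.centroid
        rows.append((int(rp.label), rp.area * pixel_size ** 2, max(ratio, 1.0),
                     orient, (cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size,
                     condition))
    return pd.DataFrame(rows, columns=["cell_id", "area_um2", "aspect_ratio",
                                       "orientation_deg", "x_um", "y_um",
                                       "condition"])


def live_dead(green: np.ndarray, red: np.ndarray,
              green_threshold: Optional[float] = None,
              red_threshold: Optional[float] = None,
              min_area_px: int = 9) -> ViabilitySummary:
    """Live/dead percentages from calcein (green) and PI (red) channels.

    Each channel is thresholded and its components counted.  A green object
    overlapping the red mask is double-positive and counted dead (PI
    positivity dominates the interpretation).  Both channels empty raises.
    """
    gmask = _binarize(green, green_threshold)
    rmask = _binarize(red, red_threshold)
    glab = sklabel(gmask)
    rlab = sklabel(rmask)
    n_dead = sum(1 for rp in regionprops(rlab) if rp.area >= min_area_px)
    n_live = 0
    for rp in regionprops(glab):
        if rp.area < min_area_px:
            continue
        overlap = rmask[tuple(rp.coords.T)].any()
        if not overlap:
            n_live += 1
        # double-positive: already represented in the red (dead) count
    if n_live + n_dead == 0:
        raise ValueError("both channels empty: viability undefined")
    return ViabilitySummary(n_live=n_live, n_dead=n_dead)


def proliferation(counts: Sequence[int], n_t0: Optional[int] = None) -> np.ndarray:
    """Cell counts per timepoint as percentages of the count at time zero."""
    counts = np.asarray(counts, float)
    n0 = counts[0] if n_t0 is None else float(n_t0)
    if n0 <= 0:
        raise ValueError("time-zero count must be positive")
    return 100.0 * counts / n0


def group_tests(groups: Dict[str, Sequence[float]], alpha: float = 0.05) -> dict:
    """One-way ANOVA and Kruskal-Wallis across groups, with Holm-adjusted
    pairwise Mann-Whitney post-hocs.

    Refuses any group with n < 3.  Returns a dict with keys ``anova``
    (F, p), ``kruskal`` (H, p) and ``posthoc`` (DataFrame: group_a, group_b,
    U, p_raw, p_holm, reject).
    """
    names = list(groups)
    vals = [np.asarray(groups[g], float) for g in names]
    for g, v in zip(names, vals):
        if len(v) < 3:
            raise ValueError(f"group {g!r} has n = {len(v)} < 3")
    F, p_anova = scipy.stats.f_oneway(*vals)
    if all(np.ptp(v) == 0 for v in vals) and len({v[0] for v in vals}) == 1:
        H, p_kw = 0.0, 1.0       # identical constant groups: no evidence
    else:
        H, p_kw = scipy.stats.kruskal(*vals)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.ptp(np.concatenate([vals[i], vals[j]])) == 0:
                u, p = len(vals[i]) * len(vals[j]) / 2.0, 1.0
            else:
                u, p = scipy.stats.mannwhitneyu(vals[i], vals[j],
                                                alternative="two-sided")
            rows.append((names[i], names[j], float(u), float(p)))
    posthoc = pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p_raw"])
    if len(posthoc):
        reject, p_holm, _, _ = multipletests(posthoc.p_raw, alpha=alpha,
                                             method="holm")
        posthoc["p_holm"] = p_holm
        posthoc["reject"] = reject
    return {"anova": {"F": float(F) if np.isfinite(F) else 0.0,
                      "p": float(p_anova) if np.isfinite(p_anova) else 1.0},
            "kruskal": {"H": float(H), "p": float(p_kw)},
            "posthoc": posthoc, "alpha": alpha}
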