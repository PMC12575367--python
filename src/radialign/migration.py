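"""Migration persistence statistics and circular two-sample tests.

Trajectories of nuclei tracked once per minute yield step directions (rose
diagrams), turning angles (wrapped differences of consecutive step
directions, peaked at 0 for persistent motion), lognormal speed fits, and
cross-condition comparisons with the two-sample Kuiper test under Holm
step-down correction.

Turning angles are directional (period 360), wrapped to (-180, 180]; each
track with k non-degenerate steps contributes k - 1 turning angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .angles import circular_resultant_length, polar_angle_deg, wrap_directional
from .deformation import detect_spots, link_tracks
from .scene import TrajectorySet

__all__ = [
    "TrajectorySet",
    "track_cells",
    "step_and_turning_angles",
    "turning_angles",
    "rose_histogram",
    "speed_stats",
    "kuiper_statistic",
    "kuiper_two_sample",
    "kuiper_asymptotic_p",
    "pairwise_compare",
    "condition_panel",
    "persistence",
    "rayleigh_test",
]


def track_cells(stack: np.ndarray, pixel_size: float, sigma_px: float,
                frame_interval: float, max_disp: float, max_gap: int = 1,
                min_len: int = 2, quality_threshold: Optional[float] = None,
                condition: Optional[str] = None) -> TrajectorySet:
    """LoG-detect nuclei in every frame and link them into trajectories.

    Tracks shorter than ``min_len`` points are dropped.  Raises if no track
    survives (with per-frame detection counts in the message).
    """
    dets = []
    for f in range(stack.shape[0]):
        d = detect_spots(stack[f], sigma_px, pixel_size,
                         quality_threshold=quality_threshold)
        d["frame"] = f
        dets.append(d)
    det = pd.concat(dets, ignore_index=True)
    tracks = link_tracks(det, max_disp=max_disp, max_gap=max_gap) \
        if len(det) else pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
    if len(tracks):
        sizes = tracks.groupby("track_id").size()
        keep = sizes[sizes >= min_len].index
        tracks = tracks[tracks.track_id.isin(keep)].reset_index(drop=True)
    if len(tracks) == 0:
        counts = det.groupby("frame").size().to_dict() if len(det) else {}
        raise ValueError(f"no tracks of length >= {min_len}; "
                         f"detections per frame: {counts}")
    return TrajectorySet(tracks=tracks, frame_interval=frame_interval,
                         condition=condition)


# ---------------------------------------------------------------------------
# steps and turning angles
# ---------------------------------------------------------------------------

def step_and_turning_angles(trajs: TrajectorySet, min_step: float = 0.0):
    """Per-step directions and per-track turning angles.

    Steps shorter than ``min_step`` (stationary frames at the localization
    noise floor) are excluded from angle statistics; a track with fewer than
    3 points contributes no turning angle.  Returns ``(steps, turns)``
    tables; ``steps`` has (track_id, frame, dx, dy, length, direction_deg,
    speed), ``turns`` has (track_id, angle_deg).
    """
    steps_rows = []
    turn_rows = []
    for tid, grp in trajs.tracks.sort_values("frame").groupby("track_id"):
        p = grp[["x_um", "y_um"]].to_numpy()
        f = grp.frame.to_numpy()
        if len(p) < 2:
            continue
        d = np.diff(p, axis=0)
        length = np.hypot(d[:, 0], d[:, 1])
        keep = length > min_step
        direction = polar_angle_deg(d[:, 0], d[:, 1])
        dt = np.diff(f) * trajs.frame_interval
        for i in np.nonzero(keep)[0]:
            steps_rows.append((tid, int(f[i + 1]), d[i, 0], d[i, 1],
                               length[i], direction[i], length[i] / dt[i]))
        dirs = direction[keep]
        if len(dirs) >= 2:
            ta = wrap_directional(np.diff(dirs))
            turn_rows.extend((tid, a) for a in np.atleast_1d(ta))
    steps = pd.DataFrame(steps_rows, columns=["track_id", "frame", "dx", "dy",
                                              "length", "direction_deg", "speed"])
    turns = pd.DataFrame(turn_rows, columns=["track_id", "angle_deg"])
    return steps, turns


def turning_angles(trajs: TrajectorySet, min_step: float = 0.0) -> np.ndarray:
    """Convenience: pooled turning angles of a trajectory set."""
    _, turns = step_and_turning_angles(trajs, min_step=min_step)
    return turns.angle_deg.to_numpy()


def persistence(turning_angles_deg) -> float:
    """Mean resultant length of the turning angles; 1 for straight motion,
    -> 0 for an uncorrelated walk."""
    return circular_resultant_length(turning_angles_deg)


def rose_histogram(directions_deg, n_bins: int = 16):
    """Occurrence counts of directions over equal circular bins.

    Bins tile (-180, 180]; returns ``(counts, bin_edges)`` with
    ``counts.sum()`` equal to the number of inputs.
    """
    d = wrap_directional(np.asarray(directions_deg, float))
    counts, edges = np.histogram(d, bins=n_bins, range=(-180.0, 180.0))
    # values exactly at +180 wrap into the last bin already (range inclusive)
    return counts, edges


def net_directions(trajs: TrajectorySet) -> np.ndarray:
    """Per-track net displacement direction (start to end)."""
    out = []
    for tid, grp in trajs.tracks.sort_values("frame").groupby("track_id"):
        p = grp[["x_um", "y_um"]].to_numpy()
        if len(p) >= 2 and np.hypot(*(p[-1] - p[0])) > 0:
            out.append(polar_angle_deg(*(p[-1] - p[0])))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# speeds
# ---------------------------------------------------------------------------

def speed_stats(trajs: TrajectorySet) -> dict:
    """Lognormal fit of per-track mean speeds.

    Per-track mean speed = path length / elapsed time.  The lognormal MLE is
    the normal MLE on log speeds; the reported pdf peak (mode)
    ``exp(mu_log - sd_log^2)`` is the headline 'mean velocity' of a
    lognormal-speed population.  Refuses fewer than 5 tracks; an (almost)
    common speed is flagged degenerate.
    """
    speeds = []
    for tid, grp in trajs.tracks.sort_values("frame").groupby("track_id"):
        p = grp[["x_um", "y_um"]].to_numpy()
        f = grp.frame.to_numpy()
        if len(p) < 2:
            continue
        path = np.hypot(*np.diff(p, axis=0).T).sum()
        elapsed = (f[-1] - f[0]) * trajs.frame_interval
        if elapsed > 0:
            speeds.append(path / elapsed)
    speeds = np.asarray(speeds)
    if len(speeds) < 5:
        raise ValueError(f"need >= 5 tracks with >= 2 points, got {len(speeds)}")
    logs = np.log(speeds[speeds > 0])
    mu_log = float(np.mean(logs))
    sd_log = float(np.std(logs, ddof=0))
    degenerate = bool(sd_log < 1e-9)
    return {"n_tracks": int(len(speeds)), "log_mean": mu_log, "log_sd": sd_log,
            "pdf_peak": float(np.exp(mu_log - sd_log ** 2)),
            "mean": float(speeds.mean()), "degenerate": degenerate,
            "speeds": speeds}


# ---------------------------------------------------------------------------
# Kuiper two-sample test
# ---------------------------------------------------------------------------

def _kuiper_from_labels(z_sorted_labels: np.ndarray, n1: int, n2: int,
                        run_end: Optional[np.ndarray] = None):
    """Kuiper V from 0/1 labels of the pooled sample in sorted order.

    V = max(F1 - F2) + max(F2 - F1) over the pooled points; because the
    ECDF difference returns to 0 after the last point, this equals
    max(delta) - min(delta) with delta including its final zero and the
    baseline zero.  The running difference is accumulated in integer
    arithmetic (counts1 * n2 - counts2 * n1), so rotating both samples by a
    common offset — which merely cycles the delta sequence up to an integer
    baseline shift — leaves V bitwise identical.  ``run_end`` marks the last
    index of each run of tied pooled values: the ECDF difference is only
    meaningful once all tied observations are consumed (identical samples
    then give V = 0 exactly).
    Supports a (B, n) batch of label rows.
    """
    lab = np.atleast_2d(z_sorted_labels)
    c1 = np.cumsum(lab == 0, axis=1, dtype=np.int64)
    c2 = np.cumsum(lab == 1, axis=1, dtype=np.int64)
    delta = c1 * n2 - c2 * n1
    if run_end is not None:
        delta = delta[:, run_end]
    hi = np.maximum(delta.max(axis=1), 0)
    lo = np.minimum(delta.min(axis=1), 0)
    v = (hi - lo) / float(n1 * n2)
    return v if z_sorted_labels.ndim > 1 else float(v[0])


def _sorted_pool(angles_a, angles_b):
    a = np.asarray(angles_a, float) % 360.0
    b = np.asarray(angles_b, float) % 360.0
    pooled = np.concatenate([a, b])
    labels = np.r_[np.zeros(len(a), int), np.ones(len(b), int)]
    order = np.argsort(pooled, kind="stable")
    z = pooled[order]
    run_end = np.r_[z[1:] != z[:-1], True]
    return labels[order], run_end


def kuiper_statistic(angles_a, angles_b) -> float:
    """Two-sample Kuiper statistic V = D+ + D- on the circle (period 360)."""
    sorted_labels, run_end = _sorted_pool(angles_a, angles_b)
    return _kuiper_from_labels(sorted_labels, len(np.atleast_1d(angles_a)),
                               len(np.atleast_1d(angles_b)), run_end)


def kuiper_asymptotic_p(v: float, n1: int, n2: int) -> float:
    """Asymptotic tail probability of the two-sample Kuiper statistic, using
    the effective sample size n1*n2/(n1+n2)."""
    ne = n1 * n2 / (n1 + n2)
    lam = (np.sqrt(ne) + 0.155 + 0.24 / np.sqrt(ne)) * v
    if lam < 0.4:
        return 1.0
    k = np.arange(1, 101)
    terms = (4.0 * k ** 2 * lam ** 2 - 1.0) * np.exp(-2.0 * k ** 2 * lam ** 2)
    return float(min(max(2.0 * terms.sum(), 0.0), 1.0))


def kuiper_two_sample(angles_a, angles_b, n_perm: int = 999,
                      seed: Optional[int] = None):
    """Two-sample Kuiper test with a label-permutation p-value.

    The permutation p (primary, valid at small n) is
    ``(1 + #{V_perm >= V_obs}) / (1 + n_perm)``; the asymptotic p is also
    reported when both groups have n >= 20.  Refuses n < 5 in either sample.
    Returns ``(V, p_perm, p_asymptotic_or_nan)``.
    """
    a = np.asarray(angles_a, float)
    b = np.asarray(angles_b, float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need n >= 5 in both samples")
    sorted_labels, run_end = _sorted_pool(a, b)
    v_obs = _kuiper_from_labels(sorted_labels, len(a), len(b), run_end)
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(sorted_labels, (n_perm, 1)), axis=1)
    v_perm = _kuiper_from_labels(perm, len(a), len(b), run_end)
    p_perm = float((1 + np.sum(v_perm >= v_obs - 1e-12)) / (1 + n_perm))
    p_asym = kuiper_asymptotic_p(v_obs, len(a), len(b)) \
        if min(len(a), len(b)) >= 20 else float("nan")
    return float(v_obs), p_perm, p_asym


def pairwise_compare(groups: Dict[str, Sequence[float]], alpha: float = 0.05,
                     n_perm: int = 999, seed: Optional[int] = None) -> pd.DataFrame:
    """All pairwise Kuiper tests between named angle samples with Holm
    step-down adjustment.

    Returns a table (group_a, group_b, V, p_raw, p_holm, reject).
    """
    names = list(groups)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            v, p, _ = kuiper_two_sample(groups[names[i]], groups[names[j]],
                                        n_perm=n_perm,
                                        seed=int(rng.integers(2 ** 31)))
            rows.append((names[i], names[j], v, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "V", "p_raw"])
    if len(df):
        reject, p_holm, _, _ = multipletests(df.p_raw, alpha=alpha, method="holm")
        df["p_holm"] = p_holm
        df["reject"] = reject
    return df


# ---------------------------------------------------------------------------
# uniformity check, condition panel
# ---------------------------------------------------------------------------

def rayleigh_test(angles_deg):
    """Rayleigh test of circular uniformity; returns (Rbar, p)."""
    t = np.radians(np.asarray(angles_deg, float))
    n = len(t)
    rbar = np.hypot(np.mean(np.sin(t)), np.mean(np.cos(t)))
    z = n * rbar ** 2
    p = np.exp(-z) * (1 + (2 * z - z ** 2) / (4 * n)
                      - (24 * z - 132 * z ** 2 + 76 * z ** 3 - 9 * z ** 4) / (288 * n ** 2))
    return float(rbar), float(min(max(p, 0.0), 1.0))


def condition_panel(condition_sets: Dict[str, TrajectorySet], alpha: float = 0.05,
                    n_perm: int = 999, seed: Optional[int] = None,
                    n_bins: int = 16, min_step: float = 0.0) -> dict:
    """Composite migration report over experimental conditions.

    For each condition: step-direction rose counts, turning-angle histogram,
    persistence (mean resultant length of turning angles), and the lognormal
    speed fit.  Cross-condition: pairwise Kuiper/Holm table on turning
    angles.  Missing conditions are simply absent (partial report).
    """
    per_condition = {}
    angle_groups = {}
    for name, trajs in condition_sets.items():
        steps, turns = step_and_turning_angles(trajs, min_step=min_step)
        ta = turns.angle_deg.to_numpy()
        rose_counts, rose_edges = rose_histogram(steps.direction_deg, n_bins)
        turn_counts, turn_edges = rose_histogram(ta, n_bins)
        entry = {
            "n_tracks": int(trajs.tracks.track_id.nunique()),
            "n_steps": int(len(steps)),
            "n_turning_angles": int(len(ta)),
            "rose_counts": rose_counts.tolist(),
            "rose_bin_edges": rose_edges.tolist(),
            "rose_mode": "per_step",
            "turning_counts": turn_counts.tolist(),
            "persistence": persistence(ta),
        }
        try:
            fit = speed_stats(trajs)
            entry["speed_fit"] = {k: fit[k] for k in
                                  ("n_tracks", "log_mean", "log_sd", "pdf_peak",
                                   "mean", "degenerate")}
        except ValueError:
            entry["speed_fit"] = None
        per_condition[name] = entry
        angle_groups[name] = ta
    usable = {k: v for k, v in angle_groups.items() if len(v) >= 5}
    tests = pairwise_compare(usable, alpha=alpha, n_perm=n_perm, seed=seed) \
        if len(usable) >= 2 else pd.DataFrame()
    return {"conditions": per_condition, "pairwise_tests": tests,
            "missing": [c for c in condition_sets if c not in usable]}
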