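"""Synthetic experiment generator with exact ground truth.

Emulates the imaging experiments of a microfluidic equibiaxial-stretch
platform: fiducial nanobeads embedded in an elastic membrane stretched over a
circular pillar, cells aligned to a radial ridge/groove micropattern, and
nuclei migrating under four conditions (flat/patterned x undeformed/deformed).
Every generated object carries its analytic ground truth so the downstream
estimators can be tested for parameter recovery.

Geometry defaults: a 512x512 px field at 1.3 um/px (10x objective scale), a
300 um-radius deformation pillar centred in the image, frames every minute.
The deformation ramps linearly over the movie, mimicking a pressure ramp to a
held plateau; a 10 % strain plateau matches the physiological target strain of
the stretching experiments.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .angles import mod_axial, polar_angle_deg, unit_vector, wrap_directional

__all__ = [
    "SceneConfig",
    "PatternSpec",
    "FieldSpec",
    "RadialProfile",
    "MigrationSpec",
    "CONDITIONS",
    "ConfigurationError",
    "PatternField",
    "DeformationField",
    "TrajectorySet",
    "make_pattern",
    "generate_field",
    "simulate_bead_tracks",
    "simulate_cell_population",
    "simulate_migration",
    "render_beads",
    "render_nuclei",
]


class ConfigurationError(ValueError):
    """Raised when a scene specification is geometrically infeasible."""


# named child streams so each component draws from an independent,
# reproducible generator derived from the one root seed
_STREAMS = {
    "beads": 1,
    "bead_noise": 2,
    "cells": 3,
    "migration": 4,
    "render": 5,
    "misc": 6,
}


@dataclass(frozen=True)
class SceneConfig:
    """Full parameterization of one synthetic experiment."""

    seed: int = 0
    pixel_size: float = 1.3           # um / px
    image_shape: tuple = (512, 512)   # (rows, cols)
    pillar_center: Optional[tuple] = None  # (x, y) um; default image centre
    pillar_radius: float = 300.0      # um
    frame_interval: float = 1.0       # min

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        if self.pillar_center is None:
            cy = self.image_shape[0] * self.pixel_size / 2.0
            cx = self.image_shape[1] * self.pixel_size / 2.0
            object.__setattr__(self, "pillar_center", (cx, cy))
        cx, cy = self.pillar_center
        h = self.image_shape[0] * self.pixel_size
        w = self.image_shape[1] * self.pixel_size
        if not (self.pillar_radius <= cx <= w - self.pillar_radius
                and self.pillar_radius <= cy <= h - self.pillar_radius):
            raise ConfigurationError("pillar must lie fully inside the image")

    @property
    def field_of_view(self):
        """(width, height) in um."""
        return (self.image_shape[1] * self.pixel_size,
                self.image_shape[0] * self.pixel_size)

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for a named component stream."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) % (2**31), _STREAMS[stream]]))

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["pillar_center"] = list(d["pillar_center"])
        d["image_shape"] = list(d["image_shape"])
        return d


# ---------------------------------------------------------------------------
# radial micropattern
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternSpec:
    """Radial ridge/groove micropattern geometry.

    The stripe widths come from the fabricated topography: ridges up to 5 um
    wide, grooves no narrower than 2 um.  To keep the arc width of a stripe
    inside those bounds over a growing radius, the number of stripes doubles
    at fixed radii (see :class:`PatternField.zone_radii`).
    """

    center: Optional[tuple] = None       # (x, y) um; default pillar centre
    r_inner: float = 30.0                # um
    r_outer: float = 300.0               # um
    ridge_width_max: float = 5.0         # um
    groove_width_min: float = 2.0        # um

    def __post_init__(self):
        if not 0 < self.r_inner < self.r_outer:
            raise ConfigurationError("need 0 < r_inner < r_outer")
        if self.ridge_width_max < 2.0 * self.groove_width_min:
            # after a split widths halve; they must stay >= groove_width_min
            raise ConfigurationError(
                "infeasible widths: ridge_width_max must be >= 2*groove_width_min "
                "for the doubling subdivision rule")


class PatternField:
    """Realized micropattern: ridge mask, orientation field and analytic
    orientation lookup.

    Local pattern orientation at a point equals the polar angle of that point
    about the pattern centre, reduced modulo 180 (stripes run radially).
    """

    def __init__(self, spec: PatternSpec, cfg: SceneConfig):
        self.spec = spec
        self.cfg = cfg
        self.center = np.asarray(spec.center if spec.center is not None
                                 else cfg.pillar_center, float)
        if spec.r_outer > cfg.pillar_radius + 1e-9:
            raise ConfigurationError("pattern must not extend beyond the pillar")
        # stripes per full circle in the innermost zone: smallest even count
        # that keeps the stripe arc width at r_inner below ridge_width_max
        m0 = int(np.ceil(2 * np.pi * spec.r_inner / spec.ridge_width_max))
        if m0 % 2:
            m0 += 1
        self._m0 = max(m0, 2)
        # zone k ends where arc width of an m_k-stripe circle hits the max
        radii = []
        m = self._m0
        r = m * spec.ridge_width_max / (2 * np.pi)
        while r < spec.r_outer:
            radii.append(r)
            m *= 2
            r = m * spec.ridge_width_max / (2 * np.pi)
        self.zone_radii = np.asarray(radii)  # split radii, strictly inside annulus

    def stripes_at(self, r):
        """Number of stripes tiling the full circle at radius r."""
        r = np.asarray(r, float)
        k = np.searchsorted(self.zone_radii, r, side="right")
        return self._m0 * 2 ** k

    def orientation_at(self, x, y):
        """Axial pattern orientation (deg in [0,180)) at points (x, y) um."""
        theta = polar_angle_deg(np.asarray(x, float) - self.center[0],
                                np.asarray(y, float) - self.center[1])
        return mod_axial(theta)

    def inside_annulus(self, x, y):
        r = np.hypot(np.asarray(x, float) - self.center[0],
                     np.asarray(y, float) - self.center[1])
        return (r >= self.spec.r_inner) & (r <= self.spec.r_outer)

    def is_ridge(self, x, y):
        """Boolean ridge membership of points (x, y) um (False outside annulus)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        r = np.hypot(x - self.center[0], y - self.center[1])
        theta = np.radians(polar_angle_deg(x - self.center[0], y - self.center[1])) % (2 * np.pi)
        m = self.stripes_at(r)
        idx = np.floor(theta / (2 * np.pi / m)).astype(int)
        return (idx % 2 == 0) & self.inside_annulus(x, y)

    def rasterize(self, oversample: int = 1):
        """(ridge_mask, orientation_deg) images at ``oversample`` x the scene
        resolution; orientation is NaN outside the annulus."""
        rows, cols = self.cfg.image_shape
        px = self.cfg.pixel_size / oversample
        yy, xx = np.mgrid[0:rows * oversample, 0:cols * oversample]
        x = (xx + 0.5) * px
        y = (yy + 0.5) * px
        mask = self.is_ridge(x, y)
        orient = self.orientation_at(x, y)
        orient = np.where(self.inside_annulus(x, y), orient, np.nan)
        return mask, orient

    def ridge_area_fraction_annulus(self):
        """Exact ridge fraction of the annulus area (alternating equal-width
        angular stripes cover half of every circle)."""
        return 0.5


def make_pattern(spec: PatternSpec, cfg: SceneConfig) -> PatternField:
    """Build the radial micropattern for a scene."""
    return PatternField(spec, cfg)


# ---------------------------------------------------------------------------
# deformation fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadialProfile:
    """Monotone radial displacement magnitude g(r) with g(0) = 0."""

    g: Callable[[np.ndarray], np.ndarray]
    dg: Callable[[np.ndarray], np.ndarray]
    label: str = "custom"

    @classmethod
    def linear(cls, strain: float) -> "RadialProfile":
        """g(r) = strain * r — a spatially uniform equibiaxial stretch."""
        return cls(g=lambda r: strain * np.asarray(r, float),
                   dg=lambda r: np.full_like(np.asarray(r, float), strain),
                   label=f"linear({strain})")

    @classmethod
    def quadratic(cls, eps: float, R: float) -> "RadialProfile":
        """g(r) = eps * r^2 / R — strain grows linearly from centre to rim,
        the centre-to-boundary deformation gradient seen on the pillar."""
        return cls(g=lambda r: eps * np.asarray(r, float) ** 2 / R,
                   dg=lambda r: 2.0 * eps * np.asarray(r, float) / R,
                   label=f"quadratic(eps={eps}, R={R})")


@dataclass(frozen=True)
class FieldSpec:
    """Prescribed planar displacement field applied to the membrane."""

    kind: str = "radial_profile"         # {"affine", "radial_profile"}
    affine_matrix: Optional[np.ndarray] = None   # 2x2, for kind="affine"
    profile: Optional[RadialProfile] = None       # for kind="radial_profile"
    n_frames: int = 11
    ramp: str = "linear"                 # per-frame scaling of the full field

    def __post_init__(self):
        if self.kind not in ("affine", "radial_profile"):
            raise ConfigurationError(f"unknown field kind {self.kind!r}")
        if self.kind == "affine" and self.affine_matrix is None:
            raise ConfigurationError("affine kind needs affine_matrix")
        if self.kind == "radial_profile" and self.profile is None:
            raise ConfigurationError("radial_profile kind needs profile")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")


class DeformationField:
    """Callable displacement field with analytic deformation gradient.

    Displacements are material (Lagrangian): ``displacement(p, frame)`` maps
    reference positions to their offset at that frame.  For the radial
    profile the gradient in the local polar frame is
    ``diag(1 + g'(r), 1 + g(r)/r)`` (radial, tangential); the field is
    curl-free so F is symmetric everywhere.
    """

    def __init__(self, spec: FieldSpec, cfg: SceneConfig):
        self.spec = spec
        self.cfg = cfg
        self.center = np.asarray(cfg.pillar_center, float)
        if spec.ramp == "linear":
            self.ramp = np.linspace(0.0, 1.0, spec.n_frames)
        else:
            self.ramp = np.asarray(spec.ramp, float)
            if self.ramp.shape != (spec.n_frames,):
                raise ConfigurationError("ramp must have n_frames entries")

    @property
    def n_frames(self):
        return self.spec.n_frames

    def _scale(self, frame):
        return 1.0 if frame is None else self.ramp[int(frame)]

    def displacement(self, points, frame=None):
        """Displacement u(p) in um for reference points (N, 2); ``frame=None``
        evaluates the fully ramped field."""
        p = np.atleast_2d(np.asarray(points, float)) - self.center
        c = self._scale(frame)
        if self.spec.kind == "affine":
            A = np.asarray(self.spec.affine_matrix, float)
            u = p @ (A - np.eye(2)).T * c
        else:
            r = np.hypot(p[:, 0], p[:, 1])
            g = self.spec.profile.g(r)
            with np.errstate(invalid="ignore", divide="ignore"):
                rhat = np.where(r[:, None] > 0, p / np.where(r == 0, 1.0, r)[:, None], 0.0)
            u = c * g[:, None] * rhat
        return u

    def true_F(self, points, frame=None):
        """Analytic Cartesian deformation gradient at reference points.

        Returns an (N, 2, 2) array; at r = 0 the radial profile limit
        ``(1 + c g'(0)) I`` is used.
        """
        p = np.atleast_2d(np.asarray(points, float)) - self.center
        c = self._scale(frame)
        n = len(p)
        if self.spec.kind == "affine":
            A = np.asarray(self.spec.affine_matrix, float)
            F = np.eye(2) + c * (A - np.eye(2))
            return np.broadcast_to(F, (n, 2, 2)).copy()
        r = np.hypot(p[:, 0], p[:, 1])
        g = self.spec.profile.g(r)
        dg = self.spec.profile.dg(r)
        with np.errstate(invalid="ignore", divide="ignore"):
            g_over_r = np.where(r > 0, g / np.where(r == 0, 1.0, r), dg)
        rhat = np.where(r[:, None] > 0, p / np.where(r == 0, 1.0, r)[:, None], 0.0)
        P = rhat[:, :, None] * rhat[:, None, :]          # r_hat outer product
        eye = np.broadcast_to(np.eye(2), (n, 2, 2))
        lam_t = 1.0 + c * g_over_r                        # tangential stretch
        lam_r = 1.0 + c * dg                              # radial stretch
        F = lam_t[:, None, None] * (eye - P) + lam_r[:, None, None] * P
        # r = 0: isotropic limit
        at0 = r == 0
        if np.any(at0):
            F[at0] = (1.0 + c * dg[at0])[:, None, None] * np.eye(2)
        return F


def generate_field(spec: FieldSpec, cfg: SceneConfig) -> DeformationField:
    """Instantiate the prescribed displacement field for a scene."""
    return DeformationField(spec, cfg)


# ---------------------------------------------------------------------------
# bead tracks
# ---------------------------------------------------------------------------

def simulate_bead_tracks(n_beads: int, fld: DeformationField, noise_sd: float,
                         cfg: SceneConfig, region_radius: Optional[float] = None):
    """Advect fiducial beads through the ramped field.

    Beads start uniformly in the pillar disc and follow the material
    displacement; i.i.d. Gaussian localization noise of ``noise_sd`` um is
    added independently per frame.  Returns ``(observed, truth)`` long-format
    tables with columns (track_id, frame, x_um, y_um).
    """
    if n_beads <= 0:
        raise ValueError("n_beads must be positive")
    rng = cfg.rng("beads")
    R = cfg.pillar_radius if region_radius is None else region_radius
    cx, cy = cfg.pillar_center
    r = R * np.sqrt(rng.uniform(size=n_beads))
    th = rng.uniform(0, 2 * np.pi, size=n_beads)
    p0 = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])

    frames = np.arange(fld.n_frames)
    rows = []
    for f in frames:
        pos = p0 + fld.displacement(p0, frame=f)
        rows.append(pd.DataFrame({
            "track_id": np.arange(n_beads), "frame": f,
            "x_um": pos[:, 0], "y_um": pos[:, 1]}))
    truth = pd.concat(rows, ignore_index=True)
    observed = truth.copy()
    if noise_sd > 0:
        noise_rng = cfg.rng("bead_noise")
        observed[["x_um", "y_um"]] += noise_rng.normal(0.0, noise_sd, size=(len(observed), 2))
    return observed, truth


# ---------------------------------------------------------------------------
# oriented cell population
# ---------------------------------------------------------------------------

def simulate_cell_population(pattern: PatternField, n_cells: int,
                             angular_noise_sd: float, cfg: SceneConfig,
                             bias_deg: float = 0.0,
                             r_range: Optional[tuple] = None) -> pd.DataFrame:
    """Cells on the annulus, oriented along the local pattern direction plus
    wrapped-normal noise (optionally plus a fixed axial bias).

    Returns a table (cell_id, x_um, y_um, orientation_deg) with orientations
    reduced to [0, 180).  Centroids are uniform in area over the annulus.
    """
    rng = cfg.rng("cells")
    ri, ro = (pattern.spec.r_inner, pattern.spec.r_outer) if r_range is None else r_range
    r = np.sqrt(rng.uniform(ri ** 2, ro ** 2, size=n_cells))
    th = rng.uniform(0, 2 * np.pi, size=n_cells)
    x = pattern.center[0] + r * np.cos(th)
    y = pattern.center[1] + r * np.sin(th)
    base = pattern.orientation_at(x, y)
    noise = rng.normal(0.0, angular_noise_sd, size=n_cells) if angular_noise_sd > 0 else 0.0
    orientation = mod_axial(base + bias_deg + noise)
    return pd.DataFrame({"cell_id": np.arange(n_cells), "x_um": x, "y_um": y,
                         "orientation_deg": orientation})


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MigrationSpec:
    """Persistent-random-walk parameters for one experimental condition.

    ``turning_concentration`` is the von Mises kappa of the turning-angle
    distribution (kappa = 0 gives uniform turning, np.inf straight lines).
    ``drift`` emulates the collective, single-direction motion seen without
    deformation; ``radial_bias`` pulls deformed-condition headings toward the
    local radial (stretch) direction.
    """

    condition: str
    speed_lognormal: tuple = (np.log(0.5), 0.3)   # (log-mean, log-sd) um/min
    turning_concentration: float = 1.0            # kappa >= 0
    drift: Optional[float] = None                 # common direction, deg
    drift_weight: float = 0.0
    radial_bias: float = 0.0                      # weight toward local radial axis

    def __post_init__(self):
        if self.turning_concentration < 0:
            raise ConfigurationError("kappa must be >= 0")


# Condition presets.  Orderings are structural: deformed conditions are more
# persistent than undeformed ones, and deformation on the pattern gives the
# highest persistence and the highest/narrowest speed distribution; the
# undeformed conditions share a collective drift direction.
CONDITIONS = ("flat_undeformed", "patterned_undeformed",
              "flat_deformed", "patterned_deformed")

_PRESETS = {
    "flat_undeformed": MigrationSpec(
        "flat_undeformed", speed_lognormal=(np.log(0.40), 0.40),
        turning_concentration=0.3, drift=35.0, drift_weight=0.35),
    "patterned_undeformed": MigrationSpec(
        "patterned_undeformed", speed_lognormal=(np.log(0.45), 0.38),
        turning_concentration=0.3, drift=35.0, drift_weight=0.35),
    "flat_deformed": MigrationSpec(
        "flat_deformed", speed_lognormal=(np.log(0.55), 0.30),
        turning_concentration=1.5, radial_bias=0.15),
    "patterned_deformed": MigrationSpec(
        "patterned_deformed", speed_lognormal=(np.log(0.65), 0.20),
        turning_concentration=3.0, radial_bias=0.30),
}


def migration_preset(condition: str) -> MigrationSpec:
    try:
        return _PRESETS[condition]
    except KeyError:
        raise ConfigurationError(f"unknown condition {condition!r}") from None


@dataclass
class TrajectorySet:
    """Migration tracks: long-format table plus acquisition metadata."""

    tracks: pd.DataFrame            # columns track_id, frame, x_um, y_um
    frame_interval: float           # min
    condition: Optional[str] = None

    def positions(self, track_id):
        t = self.tracks[self.tracks.track_id == track_id].sort_values("frame")
        return t[["x_um", "y_um"]].to_numpy()

    @property
    def track_ids(self):
        return self.tracks.track_id.unique()


def _blend_heading(heading_deg, target_deg, weight):
    """Heading pulled toward a target direction by vector blending."""
    v = (1.0 - weight) * unit_vector(heading_deg) + weight * unit_vector(target_deg)
    return polar_angle_deg(v[..., 0], v[..., 1])


def simulate_migration(spec: MigrationSpec, n_cells: int, n_frames: int,
                       cfg: SceneConfig, start_radius: Optional[float] = None
                       ) -> TrajectorySet:
    """Persistent random walks with lognormal per-step speeds and von Mises
    turning angles; reflecting boundary at the image edges.

    The default 60-frame, 1 min cadence window reproduces the one-hour
    tracking protocol.
    """
    rng = cfg.rng("migration")
    cx, cy = cfg.pillar_center
    R = cfg.pillar_radius * 0.8 if start_radius is None else start_radius
    r = R * np.sqrt(rng.uniform(size=n_cells))
    th = rng.uniform(0, 2 * np.pi, size=n_cells)
    pos = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])

    if spec.drift is not None:
        heading = wrap_directional(spec.drift + rng.normal(0, 30.0, size=n_cells))
    else:
        heading = rng.uniform(-180.0, 180.0, size=n_cells)

    mu_log, sd_log = spec.speed_lognormal
    kappa = spec.turning_concentration
    W, H = cfg.field_of_view

    out = np.empty((n_frames, n_cells, 2))
    out[0] = pos
    for f in range(1, n_frames):
        if np.isinf(kappa):
            turn = np.zeros(n_cells)
        elif kappa == 0:
            turn = rng.uniform(-180.0, 180.0, size=n_cells)
        else:
            turn = np.degrees(rng.vonmises(0.0, kappa, size=n_cells))
        heading = wrap_directional(heading + turn)
        if spec.drift is not None and spec.drift_weight > 0:
            heading = _blend_heading(heading, spec.drift, spec.drift_weight)
        if spec.radial_bias > 0:
            radial = polar_angle_deg(pos[:, 0] - cx, pos[:, 1] - cy)
            # radial axis is axial: pull toward whichever of +/-r_hat is closer
            flip = np.abs(wrap_directional(radial - heading)) > 90.0
            target = wrap_directional(radial + 180.0 * flip)
            heading = _blend_heading(heading, target, spec.radial_bias)
        speed = rng.lognormal(mu_log, sd_log, size=n_cells)
        step = speed[:, None] * cfg.frame_interval * unit_vector(heading)
        pos = pos + step
        # reflecting boundary in both coordinates
        for d, lim in ((0, W), (1, H)):
            over = pos[:, d] > lim
            under = pos[:, d] < 0
            pos[over, d] = 2 * lim - pos[over, d]
            pos[under, d] = -pos[under, d]
            if np.any(over | under):
                v = unit_vector(heading)
                v[over | under, d] *= -1
                heading = polar_angle_deg(v[:, 0], v[:, 1])
        out[f] = pos

    frames = np.repeat(np.arange(n_frames), n_cells)
    ids = np.tile(np.arange(n_cells), n_frames)
    df = pd.DataFrame({"track_id": ids, "frame": frames,
                       "x_um": out.reshape(-1, 2)[:, 0],
                       "y_um": out.reshape(-1, 2)[:, 1]})
    df = df.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return TrajectorySet(tracks=df, frame_interval=cfg.frame_interval,
                         condition=spec.condition)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _solve_amplitude(snr, background, read_noise):
    # SNR defined at the spot peak: amp / sqrt(amp + background + read^2)
    b = background + read_noise ** 2
    s2 = snr ** 2
    return 0.5 * (s2 + np.sqrt(s2 ** 2 + 4 * s2 * b))


def render_beads(positions_um: np.ndarray, cfg: SceneConfig, sigma_px: float = 1.5,
                 snr: float = 20.0, background: float = 20.0,
                 read_noise: float = 2.0, rng: Optional[np.random.Generator] = None
                 ) -> np.ndarray:
    """Render one frame of Gaussian bead spots with Poisson + read noise.

    ``positions_um`` is (N, 2); returns a float image in photon counts.
    Set ``snr=np.inf`` to render noiselessly (pure model image).
    """
    if sigma_px < 0.5:
        warnings.warn("spot sigma below 0.5 px is sub-Nyquist", stacklevel=2)
    rows, cols = cfg.image_shape
    img = np.full((rows, cols), float(background))
    if np.isinf(snr):
        amp, noisy = 1000.0, False
    else:
        amp, noisy = _solve_amplitude(snr, background, read_noise), True
    half = int(np.ceil(4 * sigma_px))
    for x_um, y_um in np.atleast_2d(positions_um):
        # pixel-index position: pixel i has its centre at (i + 0.5)*pixel_size
        cx = x_um / cfg.pixel_size - 0.5
        cy = y_um / cfg.pixel_size - 0.5
        c0, r0 = int(round(cx)), int(round(cy))
        rr = np.arange(max(r0 - half, 0), min(r0 + half + 1, rows))
        cc = np.arange(max(c0 - half, 0), min(c0 + half + 1, cols))
        if rr.size == 0 or cc.size == 0:
            continue
        dy = (rr - cy)[:, None]
        dx = (cc - cx)[None, :]
        img[np.ix_(rr, cc)] += amp * np.exp(-(dx ** 2 + dy ** 2) / (2 * sigma_px ** 2))
    if noisy:
        rng = cfg.rng("render") if rng is None else rng
        img = rng.poisson(img).astype(float) + rng.normal(0, read_noise, img.shape)
    return img


def render_bead_stack(tracks: pd.DataFrame, cfg: SceneConfig, **kwargs) -> np.ndarray:
    """Render a multi-frame stack from a (track_id, frame, x_um, y_um) table."""
    rng = cfg.rng("render")
    frames = np.sort(tracks.frame.unique())
    stack = []
    for f in frames:
        sub = tracks[tracks.frame == f]
        stack.append(render_beads(sub[["x_um", "y_um"]].to_numpy(), cfg,
                                  rng=rng, **kwargs))
    return np.stack(stack)


def render_nuclei(cells: pd.DataFrame, cfg: SceneConfig,
                  axes_um: tuple = (12.0, 5.0), intensity: float = 200.0,
                  background: float = 10.0, read_noise: float = 2.0,
                  noisy: bool = True, rng: Optional[np.random.Generator] = None):
    """Render nuclei as filled ellipses oriented by ``orientation_deg``.

    Returns ``(image, labels)``: a noisy intensity image and the noise-free
    integer label image (cell_id + 1) used as segmentation ground truth.
    """
    rows, cols = cfg.image_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    x_um = (xx + 0.5) * cfg.pixel_size
    y_um = (yy + 0.5) * cfg.pixel_size
    labels = np.zeros((rows, cols), dtype=np.int32)
    a, b = axes_um
    for rec in cells.itertuples():
        phi = np.radians(rec.orientation_deg)
        u = np.array([np.cos(phi), -np.sin(phi)])   # image-coords major axis
        v = np.array([np.sin(phi), np.cos(phi)])
        dx = x_um - rec.x_um
        dy = y_um - rec.y_um
        q = ((dx * u[0] + dy * u[1]) / a) ** 2 + ((dx * v[0] + dy * v[1]) / b) ** 2
        labels[q <= 1.0] = rec.cell_id + 1
    img = np.where(labels > 0, intensity, 0.0) + background
    if noisy:
        rng = cfg.rng("render") if rng is None else rng
        img = rng.poisson(img).astype(float) + rng.normal(0, read_noise, img.shape)
    return img, labels
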