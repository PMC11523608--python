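"""Synthetic study generator: geometry, puncture cohorts, measurements, Likert.

The study's patient geometry and participant recordings are not public in
raw form, so this module generates every pipeline input with known ground
truth:

* a closed left-atrium (LA) ellipsoid and a circular fossa-ovalis (FO) disc
  (circularity 1.0) of 18.46 mm diameter with a radially parabolic thickness
  profile from 0.65 mm at the center to 1.75 mm at the rim — the fabricated
  FO insert's dimensions;
* an operator cohort (a trainee plus cardiologists with 10, 10, 14 and 25
  years of experience) whose puncture scatter on the FO shrinks with
  experience, and procedural times linear in the site's GII and
  centroid distance plus Gaussian noise, with coefficients calibrated so the
  population correlations match configured targets (defaults r = 0.656 for
  GII-time and r = 0.566 for distance-time);
* caliper-vs-STL measurement pairs with a small systematic bias
  (default 0.03 mm, the phantom reading smaller) per researcher;
* 1-5 Likert questionnaire responses matching target means in expectation.

Each output table draws from its own pseudo-random stream derived from the
master seed, so adding one table never perturbs another.  The time-model
calibration uses a fixed internal stream so that the generating correlation
is a property of the configuration, not of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .geometry_io import FOPatch, TriMesh, extract_fo_candidates
from .gii import GIIField

__all__ = [
    "OperatorSpec",
    "TimeModel",
    "MeasurementModel",
    "SyntheticConfig",
    "make_geometry",
    "make_fo_patch",
    "make_cohort",
    "make_measurements",
    "make_likert",
]

# stream keys: one per output table, combined with the master seed
_STREAM_COHORT = 1
_STREAM_MEASUREMENTS = 2
_STREAM_LIKERT = 3
# the calibration stream is fixed so the generating correlations do not
# depend on the cohort seed
_CALIBRATION_SEED = 20240930
_CALIBRATION_N = 4000


@dataclass(frozen=True)
class OperatorSpec:
    """One simulated operator: id, experience and in-plane scatter."""

    participant_id: str
    experience_years: float
    dispersion_mm: float
    n_trials: int = 4

    def __post_init__(self) -> None:
        if self.dispersion_mm <= 0:
            raise ValidationError("dispersion must be positive")
        if self.n_trials < 1:
            raise ValidationError("need at least one trial")


@dataclass(frozen=True)
class TimeModel:
    """Procedural-time model: t = intercept + b_g*GII + b_d*dist + noise.

    With ``gii_coeff``/``dist_coeff``/``noise_sd`` left ``None`` the
    coefficients are solved numerically (on a large calibration cohort) so
    that the population correlations of time with GII and with centroid
    distance equal ``target_r_gii`` and ``target_r_dist`` at an overall time
    SD of ``time_sd_s``; covariates are then centered so the mean time equals
    ``intercept_s``.
    """

    intercept_s: float = 120.0
    gii_coeff: float | None = None
    dist_coeff: float | None = None
    noise_sd: float | None = None
    time_sd_s: float = 20.0
    target_r_gii: float = 0.656
    target_r_dist: float = 0.566


@dataclass(frozen=True)
class MeasurementModel:
    """Caliper-vs-STL measurement pairs: physical = truth - bias + N(0, sd)."""

    bias_mm: float = 0.03
    sd_mm: float = 0.2
    n_per_researcher: int = 50
    n_researchers: int = 3
    feature_range_mm: tuple[float, float] = (2.0, 60.0)


def _default_operators() -> tuple[OperatorSpec, ...]:
    # scatter decreasing in experience; trainee coded 0 years.  The trainee's
    # dispersion spans most of the fossa while experienced operators cluster
    # within a few mm, so the trainee's mean distances are reliably largest.
    return (
        OperatorSpec("trainee", 0.0, 8.0, 4),
        OperatorSpec("cardio_10a", 10.0, 2.5, 4),
        OperatorSpec("cardio_10b", 10.0, 2.5, 4),
        OperatorSpec("cardio_14", 14.0, 2.0, 4),
        OperatorSpec("cardio_25", 25.0, 1.5, 4),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Master configuration; a fixed seed makes every output reproducible."""

    seed: int = 0
    la_semi_axes: tuple[float, float, float] = (24.0, 20.0, 16.0)
    fo_diameter: float = 18.46
    fo_thickness_range: tuple[float, float] = (0.65, 1.75)
    fo_rings: int = 8
    fo_segments: int = 24
    la_subdivisions: int = 3
    operators: tuple[OperatorSpec, ...] = field(default_factory=_default_operators)
    time_model: TimeModel = field(default_factory=TimeModel)
    measurement_model: MeasurementModel = field(default_factory=MeasurementModel)
    likert_question_means: tuple[float, ...] = (4.15, 4.50, 3.75, 4.00, 4.00, 4.60)
    likert_n_participants: int = 5

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# ---------------------------------------------------------------------------
# geometry


def make_geometry(cfg: SyntheticConfig) -> tuple[TriMesh, TriMesh, np.ndarray]:
    """Build the LA ellipsoid, the FO disc mesh and its thickness map.

    The LA is a closed icosphere scaled to ``la_semi_axes`` and centered at
    the origin.  The FO disc lies in the plane tangent to the ellipsoid at
    (-a, 0, 0) — the septal wall — with its inward normal (+x) pointing at
    the LA centroid.  Thickness grows parabolically with radius from
    ``fo_thickness_range[0]`` at the center vertex (the FO "centroid" in the
    thinnest-point convention) to ``fo_thickness_range[1]`` at the rim.
    """
    import trimesh

    a, b, c = cfg.la_semi_axes
    if min(a, b, c) <= 0:
        raise ValidationError("LA semi-axes must be positive")
    if cfg.fo_diameter <= 0:
        raise ValidationError("FO diameter must be positive")
    t_min, t_max = cfg.fo_thickness_range
    if not 0 < t_min < t_max:
        raise ValidationError("thickness range must satisfy 0 < min < max")
    radius = cfg.fo_diameter / 2.0
    if radius >= 0.8 * min(b, c):
        raise ValidationError("FO does not fit on the LA wall patch")

    sphere = trimesh.creation.icosphere(subdivisions=cfg.la_subdivisions, radius=1.0)
    la_vertices = sphere.vertices * np.array([a, b, c])
    la = TriMesh(la_vertices, np.asarray(sphere.faces), name="la")

    # planar disc tangent at (-a, 0, 0); in-plane axes y (posterior) and
    # z (superior), inward normal +x
    center = np.array([-a, 0.0, 0.0])
    verts = [center]
    thickness = [t_min]
    for j in range(1, cfg.fo_rings + 1):
        r = radius * j / cfg.fo_rings
        t = t_min + (t_max - t_min) * (r / radius) ** 2
        for k in range(cfg.fo_segments):
            ang = 2 * math.pi * k / cfg.fo_segments
            verts.append(center + np.array([0.0, r * math.cos(ang), r * math.sin(ang)]))
            thickness.append(t)
    faces = []
    for k in range(cfg.fo_segments):
        faces.append([0, 1 + k, 1 + (k + 1) % cfg.fo_segments])
    for j in range(1, cfg.fo_rings):
        inner = 1 + (j - 1) * cfg.fo_segments
        outer = 1 + j * cfg.fo_segments
        for k in range(cfg.fo_segments):
            k2 = (k + 1) % cfg.fo_segments
            faces.append([inner + k, outer + k, outer + k2])
            faces.append([inner + k, outer + k2, inner + k2])
    fo = TriMesh(np.array(verts), np.array(faces), name="fo")
    return la, fo, np.array(thickness)


def make_fo_patch(cfg: SyntheticConfig, fo: TriMesh, thickness: np.ndarray) -> FOPatch:
    """FOPatch for the synthetic disc with its anatomical frame attached.

    Superior is +z and posterior +y in the phantom frame; normals point
    toward the LA centroid at the origin.
    """
    return extract_fo_candidates(
        fo,
        thickness,
        la_reference=np.zeros(3),
        superior=np.array([0.0, 0.0, 1.0]),
        posterior=np.array([0.0, 1.0, 0.0]),
    )


# ---------------------------------------------------------------------------
# puncture cohort


def _disc_frame(points: np.ndarray):
    """In-plane orthonormal axes, center and radius of the (planar) FO disc."""
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center)
    e1, e2 = vt[0], vt[1]
    radius = float(np.linalg.norm(points - center, axis=1).max())
    return center, e1, e2, radius


def _draw_punctures(
    rng: np.random.Generator,
    ops: tuple[OperatorSpec, ...],
    n_per_op: np.ndarray,
    scatter_center: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    disc_center: np.ndarray,
    disc_radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Tangent-plane Gaussian scatter per operator, clamped to the disc."""
    pts = []
    op_index = []
    for i, (op, n) in enumerate(zip(ops, n_per_op)):
        offs = rng.normal(0.0, op.dispersion_mm, size=(int(n), 2))
        p = scatter_center + offs[:, :1] * e1 + offs[:, 1:] * e2
        # clamp radially so every puncture stays on the FO insert
        rel = p - disc_center
        rad = np.linalg.norm(rel, axis=1, keepdims=True)
        lim = 0.98 * disc_radius
        scale = np.where(rad > lim, lim / rad, 1.0)
        pts.append(disc_center + rel * scale)
        op_index.extend([i] * int(n))
    return np.concatenate(pts), np.asarray(op_index)


def _covariates(points: np.ndarray, field_: GIIField, centroid: np.ndarray):
    tree = cKDTree(field_.fo_points)
    _, idx = tree.query(points)
    g = field_.scores[idx]
    d = np.linalg.norm(points - np.asarray(centroid, dtype=float), axis=1)
    return g, d


def calibrate_time_model(
    cfg: SyntheticConfig, field_: GIIField, centroid: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Solve (b_g, b_d, noise_sd) so population correlations hit the targets.

    Draws a large calibration cohort from the configured operator mixture
    (its own fixed stream), measures the covariance of (GII, distance) and
    solves the linear system  Sigma b = (rho_g sigma_g sigma_t,
    rho_d sigma_d sigma_t)  at the configured overall time SD; the residual
    noise variance is sigma_t^2 - b' Sigma b.  Raises when the targets are
    jointly infeasible.  Returns (b_g, b_d, noise_sd, mean_g, mean_d).
    """
    tm = cfg.time_model
    rng = np.random.default_rng(_CALIBRATION_SEED)
    weights = np.array([op.n_trials for op in cfg.operators], dtype=float)
    weights /= weights.sum()
    n_per_op = rng.multinomial(_CALIBRATION_N, weights)
    disc_center, e1, e2, disc_radius = _disc_frame(field_.fo_points)
    scatter_center = (np.asarray(centroid, dtype=float) + field_.argmax_point) / 2.0
    pts, _ = _draw_punctures(
        rng, cfg.operators, n_per_op, scatter_center, e1, e2, disc_center, disc_radius
    )
    g, d = _covariates(pts, field_, centroid)
    sigma = np.cov(np.stack([g, d]))
    sg, sd_ = math.sqrt(sigma[0, 0]), math.sqrt(sigma[1, 1])
    if sg == 0 or sd_ == 0:
        raise ValidationError("degenerate covariate distribution; cannot calibrate")
    st = tm.time_sd_s
    v = np.array([tm.target_r_gii * sg * st, tm.target_r_dist * sd_ * st])
    b = np.linalg.solve(sigma, v)
    noise_var = st**2 - float(b @ v)
    if noise_var <= 0:
        raise ValidationError(
            "target correlations are infeasible for the covariate geometry"
        )
    return float(b[0]), float(b[1]), math.sqrt(noise_var), float(g.mean()), float(d.mean())


def make_cohort(
    cfg: SyntheticConfig, field_: GIIField, centroid: np.ndarray
) -> pd.DataFrame:
    """Generate the puncture table (participant, experience, trial, xyz, time).

    Punctures scatter isotropically in the FO plane around the midpoint of
    the centroid and the max-GII site, with each operator's dispersion;
    procedural times follow the (possibly calibrated) linear time model.
    """
    if len(cfg.operators) == 0:
        raise ValidationError("operator list is empty")
    tm = cfg.time_model
    rng = cfg.rng(_STREAM_COHORT)
    disc_center, e1, e2, disc_radius = _disc_frame(field_.fo_points)
    scatter_center = (np.asarray(centroid, dtype=float) + field_.argmax_point) / 2.0
    n_per_op = np.array([op.n_trials for op in cfg.operators])
    pts, op_index = _draw_punctures(
        rng, cfg.operators, n_per_op, scatter_center, e1, e2, disc_center, disc_radius
    )
    g, d = _covariates(pts, field_, centroid)

    if tm.gii_coeff is None or tm.dist_coeff is None or tm.noise_sd is None:
        b_g, b_d, noise_sd, g0, d0 = calibrate_time_model(cfg, field_, centroid)
    else:
        b_g, b_d, noise_sd, g0, d0 = tm.gii_coeff, tm.dist_coeff, tm.noise_sd, 0.0, 0.0
    times = tm.intercept_s + b_g * (g - g0) + b_d * (d - d0)
    if noise_sd > 0:
        times = times + rng.normal(0.0, noise_sd, size=len(times))
    times = np.maximum(times, 1e-3)  # procedural times must stay positive

    rows = []
    trial_counter = {i: 0 for i in range(len(cfg.operators))}
    for k, i in enumerate(op_index):
        trial_counter[i] += 1
        op = cfg.operators[i]
        rows.append(
            (op.participant_id, op.experience_years, trial_counter[i],
             pts[k, 0], pts[k, 1], pts[k, 2], times[k])
        )
    return pd.DataFrame(
        rows, columns=["participant", "experience_years", "trial", "x", "y", "z", "time_s"]
    )


# ---------------------------------------------------------------------------
# measurements and questionnaire


def make_measurements(cfg: SyntheticConfig) -> pd.DataFrame:
    """Paired STL-vs-caliper table (feature, researcher, stl_mm, physical_mm).

    Each researcher measures the same features; the physical phantom reads
    smaller than the STL by ``bias_mm`` on average with Gaussian measurement
    noise, mirroring a small uniform manufacturing shrinkage.
    """
    mm = cfg.measurement_model
    if mm.n_per_researcher < 2:
        raise ValidationError("need at least 2 measurements per researcher")
    rng = cfg.rng(_STREAM_MEASUREMENTS)
    lo, hi = mm.feature_range_mm
    truth = rng.uniform(lo, hi, size=mm.n_per_researcher)
    rows = []
    for r in range(mm.n_researchers):
        noise = rng.normal(0.0, mm.sd_mm, size=mm.n_per_researcher) if mm.sd_mm > 0 else 0.0
        physical = truth - mm.bias_mm + noise
        for f in range(mm.n_per_researcher):
            rows.append((f, f"researcher_{r + 1}", truth[f],
                         physical[f] if np.ndim(physical) else truth[f] - mm.bias_mm))
    return pd.DataFrame(rows, columns=["feature", "researcher", "stl_mm", "physical_mm"])


def make_likert(
    cfg: SyntheticConfig, question_means: tuple[float, ...] | None = None
) -> pd.DataFrame:
    """Integer 1-5 responses whose per-question mean matches the target in
    expectation (two-point floor/ceil mixture)."""
    means = question_means if question_means is not None else cfg.likert_question_means
    means = np.asarray(means, dtype=float)
    if np.any((means < 1) | (means > 5)):
        raise ValidationError("target Likert means must lie in [1, 5]")
    rng = cfg.rng(_STREAM_LIKERT)
    rows = []
    for q, m in enumerate(means, start=1):
        lo = math.floor(m)
        frac = m - lo
        draws = lo + (rng.random(cfg.likert_n_participants) < frac).astype(int)
        draws = np.clip(draws, 1, 5)
        for p, s in enumerate(draws, start=1):
            rows.append((f"P{p}", f"Q{q}", int(s)))
    return pd.DataFrame(rows, columns=["participant", "question", "score"])
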