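"""Constant-curvature catheter kinematics pivoting at a septal puncture site.

The inserted catheter segment is modelled as a single circular arc of length
``ell`` launched tangentially along the pivot axis (the inward fossa-ovalis
normal).  A configuration is ``(phi, theta, ell)``: the bending-plane angle
about the axis, the total bend angle ``theta = kappa * ell``, and the inserted
arc length.  For Jacobian computations the control vector is
``u = (phi, theta, s)`` with ``s = ell / ell_max`` dimensionless, so that all
three Jacobian columns carry units of mm per unit control and a singular-value
ratio is meaningful.  The alternative parameterization ``(phi, kappa, ell)``
is available for sensitivity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError

__all__ = [
    "CatheterConfig",
    "PivotFrame",
    "KinematicLimits",
    "forward_kinematics",
    "inverse_kinematics",
    "jacobian",
    "tip_local",
    "ik_batch",
    "jacobian_batch_local",
]

# Below this bend angle the arc terms are evaluated by Taylor series to keep
# the theta -> 0 straight-catheter limit continuous.
_THETA_SERIES_SWITCH = 1e-6
# Curvature below this is treated as a straight insertion in the IK.
_KAPPA_TOL = 1e-9


@dataclass(frozen=True)
class CatheterConfig:
    """One catheter configuration at the pivot.

    Parameters
    ----------
    phi : float
        Bending-plane angle about the insertion axis, rad, in [-pi, pi].
    theta : float
        Total bend angle ``kappa * ell``, rad, >= 0.
    ell : float
        Inserted arc length, mm, > 0.
    """

    phi: float
    theta: float
    ell: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.phi, self.theta, self.ell]).all():
            raise ValidationError("catheter configuration must be finite")
        if self.theta < 0:
            raise ValidationError(f"theta must be >= 0, got {self.theta}")
        if self.ell <= 0:
            raise ValidationError(f"ell must be > 0, got {self.ell}")

    @property
    def kappa(self) -> float:
        """Arc curvature in mm^-1."""
        return self.theta / self.ell


@dataclass(frozen=True)
class PivotFrame:
    """Orthonormal frame anchored at the puncture site.

    ``axis`` is the unit insertion direction (the inward septal normal,
    pointing from the right into the left atrium); ``ref`` is a unit in-plane
    reference from which the bending-plane angle ``phi`` is measured.
    """

    origin: np.ndarray
    axis: np.ndarray
    ref: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        ref = np.asarray(self.ref, dtype=float)
        for name, v in (("origin", origin), ("axis", axis), ("ref", ref)):
            if v.shape != (3,) or not np.isfinite(v).all():
                raise ValidationError(f"{name} must be a finite 3-vector")
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9 or abs(np.linalg.norm(ref) - 1.0) > 1e-9:
            raise ValidationError("axis and ref must be unit vectors (tol 1e-9)")
        if abs(float(axis @ ref)) > 1e-9:
            raise ValidationError("axis and ref must be orthogonal (tol 1e-9)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "ref", ref)

    @property
    def rotation(self) -> np.ndarray:
        """World-from-local rotation; columns are (ref, axis x ref, axis)."""
        y = np.cross(self.axis, self.ref)
        return np.column_stack([self.ref, y, self.axis])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation

    def to_world(self, points_local: np.ndarray) -> np.ndarray:
        return np.asarray(points_local, dtype=float) @ self.rotation.T + self.origin


@dataclass(frozen=True)
class KinematicLimits:
    """Configuration limits encoding "simple, no-loop" catheter use.

    Defaults: at most a half-turn bend (theta_max = pi), insertion between 5
    and 100 mm, and a 10 mm minimum bend radius (kappa_max = 0.1 mm^-1),
    typical of an ablation catheter.
    """

    theta_max: float = np.pi
    ell_min: float = 5.0
    ell_max: float = 100.0
    kappa_max: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.ell_min < self.ell_max):
            raise ValidationError("require 0 < ell_min < ell_max")
        if not (0 < self.theta_max <= np.pi):
            raise ValidationError("require 0 < theta_max <= pi")
        if self.kappa_max <= 0:
            raise ValidationError("require kappa_max > 0")

    def contains(self, config: CatheterConfig, atol: float = 1e-9) -> bool:
        """True if ``config`` satisfies every limit (with tolerance ``atol``)."""
        return bool(
            config.theta <= self.theta_max + atol
            and self.ell_min - atol <= config.ell <= self.ell_max + atol
            and config.theta / config.ell <= self.kappa_max + atol
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "KinematicLimits":
        with open(path) as fh:
            return cls(**json.load(fh))


def _arc_terms(theta):
    """Return a = (1-cos t)/t and b = sin t / t, series-expanded near zero."""
    theta = np.asarray(theta, dtype=float)
    small = theta < _THETA_SERIES_SWITCH
    t = np.where(small, 1.0, theta)
    # 2 sin^2(t/2) == 1 - cos t without catastrophic cancellation near zero
    a = np.where(small, theta / 2 - theta**3 / 24, 2 * np.sin(t / 2) ** 2 / t)
    b = np.where(small, 1 - theta**2 / 6, np.sin(t) / t)
    return a, b


def _arc_terms_d(theta):
    """Derivatives da/dtheta, db/dtheta with series below the switch."""
    theta = np.asarray(theta, dtype=float)
    small = theta < _THETA_SERIES_SWITCH
    t = np.where(small, 1.0, theta)
    da_exact = (t * np.sin(t) - 2 * np.sin(t / 2) ** 2) / t**2
    db_exact = (t * np.cos(t) - np.sin(t)) / t**2
    da = np.where(small, 0.5 - theta**2 / 8, da_exact)
    db = np.where(small, -theta / 3 + theta**3 / 30, db_exact)
    return da, db


def tip_local(phi, theta, ell):
    """Tip position in pivot-frame coordinates, vectorized.

    ``(a*ell*cos(phi), a*ell*sin(phi), b*ell)`` with a, b the arc terms; the
    z-axis is the insertion axis and phi rotates the bending plane about it.
    """
    a, b = _arc_terms(theta)
    ell = np.asarray(ell, dtype=float)
    return np.stack(
        [a * ell * np.cos(phi), a * ell * np.sin(phi), b * ell], axis=-1
    )


def forward_kinematics(frame: PivotFrame, config: CatheterConfig) -> np.ndarray:
    """World-frame tip position (mm) of the arc at ``config``."""
    return frame.to_world(tip_local(config.phi, config.theta, config.ell))


def inverse_kinematics(
    frame: PivotFrame, target: np.ndarray, limits: KinematicLimits | None = None
) -> CatheterConfig | None:
    """Closed-form inverse kinematics; ``None`` when the target is out of reach.

    The circular arc through the origin tangent to the axis that passes
    through local target (x, y, z) has curvature ``kappa = 2 r / (r^2 + z^2)``
    with ``r = hypot(x, y)``, bend ``theta = atan2(z kappa, 1 - r kappa)``
    (taken in [0, 2 pi)) and length ``ell = theta / kappa``.  Returns ``None``
    when the resulting configuration violates ``limits`` or the target lies on
    the negative axis.

    Raises
    ------
    ValidationError
        If the target coincides with the pivot origin.
    """
    limits = limits or KinematicLimits()
    target = np.asarray(target, dtype=float)
    p = frame.to_local(target)
    if np.allclose(p, 0.0):
        raise ValidationError("IK target coincides with the pivot origin")
    cfg = _ik_local(p[0], p[1], p[2])
    if cfg is None or not limits.contains(cfg):
        return None
    return cfg


def _ik_local(x: float, y: float, z: float) -> CatheterConfig | None:
    r = float(np.hypot(x, y))
    kappa = 2.0 * r / (r * r + z * z)
    if kappa < _KAPPA_TOL:
        # Straight insertion: only targets on the positive axis are reachable.
        if z <= 0:
            return None
        return CatheterConfig(phi=0.0, theta=0.0, ell=float(z))
    theta = float(np.arctan2(z * kappa, 1.0 - r * kappa)) % (2.0 * np.pi)
    return CatheterConfig(phi=float(np.arctan2(y, x)), theta=theta, ell=theta / kappa)


def ik_batch(frame: PivotFrame, targets: np.ndarray, limits: KinematicLimits):
    """Vectorized IK over ``targets`` (n, 3).

    Returns ``(reachable, phi, theta, ell)``; configuration entries are NaN
    where unreachable.  Straight-line solutions get ``theta = 0``.
    """
    p = frame.to_local(np.atleast_2d(targets))
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    r = np.hypot(x, y)
    d2 = r * r + z * z
    at_origin = d2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(at_origin, np.nan, 2.0 * r / d2)
    straight = kappa < _KAPPA_TOL
    theta = np.arctan2(z * kappa, 1.0 - r * kappa) % (2.0 * np.pi)
    theta = np.where(straight, 0.0, theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        ell = np.where(straight, z, theta / kappa)
    phi = np.where(straight, 0.0, np.arctan2(y, x))
    kappa_eff = np.where(straight, 0.0, kappa)
    ok = (
        ~at_origin
        & (theta <= limits.theta_max + 1e-9)
        & (ell >= limits.ell_min - 1e-9)
        & (ell <= limits.ell_max + 1e-9)
        & (kappa_eff <= limits.kappa_max + 1e-9)
        & ~(straight & (z <= 0))
    )
    phi = np.where(ok, phi, np.nan)
    theta = np.where(ok, theta, np.nan)
    ell = np.where(ok, ell, np.nan)
    return ok, phi, theta, ell


def _jacobian_local(phi, theta, ell, limits: KinematicLimits, parameterization: str):
    """Stacked 3x3 Jacobians d tip / d u in the pivot frame, vectorized."""
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    ell = np.asarray(ell, dtype=float)
    a, b = _arc_terms(theta)
    da, db = _arc_terms_d(theta)
    c, s = np.cos(phi), np.sin(phi)
    zero = np.zeros_like(phi * theta * ell)
    # column d/d phi: rotation of the tip about the axis
    col_phi = np.stack([-a * ell * s, a * ell * c, zero], axis=-1)
    col_theta = np.stack([da * ell * c, da * ell * s, db * ell], axis=-1)
    if parameterization == "phi_theta_s":
        # d/ds with s = ell / ell_max at fixed theta
        col3 = np.stack([a * c, a * s, b + zero], axis=-1) * limits.ell_max
    elif parameterization == "phi_kappa_ell":
        # theta = kappa * ell: d/dkappa at fixed ell, d/dell at fixed kappa
        col_kappa = col_theta * ell[..., None]
        col_ell = np.stack(
            [(a + theta * da) * c, (a + theta * da) * s, b + theta * db], axis=-1
        )
        return np.stack([col_phi, col_kappa, col_ell], axis=-1)
    else:
        raise ValidationError(f"unknown parameterization {parameterization!r}")
    return np.stack([col_phi, col_theta, col3], axis=-1)


def jacobian(
    frame: PivotFrame,
    config: CatheterConfig,
    limits: KinematicLimits | None = None,
    parameterization: str = "phi_theta_s",
) -> np.ndarray:
    """Analytic 3x3 tip Jacobian in world coordinates (mm per unit control).

    Columns are derivatives with respect to ``(phi, theta, s = ell/ell_max)``
    by default, or ``(phi, kappa, ell)`` with
    ``parameterization="phi_kappa_ell"``.
    """
    limits = limits or KinematicLimits()
    J_local = _jacobian_local(config.phi, config.theta, config.ell, limits, parameterization)
    return frame.rotation @ J_local


def jacobian_batch_local(phi, theta, ell, limits: KinematicLimits) -> np.ndarray:
    """Stacked pivot-frame Jacobians for arrays of configurations.

    Singular values are rotation-invariant, so scoring code may use these
    without mapping to world coordinates.
    """
    return _jacobian_local(phi, theta, ell, limits, "phi_theta_s")
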