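"""Reachability classification of left-atrial points from a puncture pivot.

A target is reachable when the closed-form inverse kinematics yields a
configuration inside the kinematic limits whose forward-kinematics tip lands
within a placement tolerance of the target.  Reachability is tip-only: no
shaft-wall collision test is applied (a documented limitation).  Points
behind the pivot plane are unreachable by construction, since the arc
launches tangent to the axis and bends at most pi.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry_io import LASamples
from .kinematics import CatheterConfig, KinematicLimits, PivotFrame, ik_batch, tip_local

__all__ = ["ReachabilityMap", "classify_point", "map_reachability", "DEFAULT_TOL_MM"]

# Order of the EM-tracking / clinical placement precision.
DEFAULT_TOL_MM = 1.0


@dataclass
class ReachabilityMap:
    """Per-point reachable flags with the realizing configurations."""

    points: np.ndarray
    reachable: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    ell: np.ndarray
    tolerance: float

    @property
    def fraction_reachable(self) -> float:
        return float(self.reachable.mean()) if len(self.reachable) else 0.0

    def config_at(self, i: int) -> CatheterConfig | None:
        if not self.reachable[i]:
            return None
        return CatheterConfig(float(self.phi[i]), float(self.theta[i]), float(self.ell[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                "reachable": self.reachable.astype(int),
                "phi": self.phi,
                "theta": self.theta,
                "ell": self.ell,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def classify_point(
    frame: PivotFrame,
    target: np.ndarray,
    limits: KinematicLimits | None = None,
    tol: float = DEFAULT_TOL_MM,
) -> tuple[bool, CatheterConfig | None]:
    """Classify one target; returns (reachable, realizing config or None)."""
    if tol <= 0:
        raise ValidationError("tolerance must be positive")
    limits = limits or KinematicLimits()
    ok, phi, theta, ell = ik_batch(frame, np.asarray(target, dtype=float)[None, :], limits)
    if not ok[0]:
        return False, None
    cfg = CatheterConfig(float(phi[0]), float(theta[0]), float(ell[0]))
    tip = frame.to_world(tip_local(cfg.phi, cfg.theta, cfg.ell))
    if np.linalg.norm(tip - target) > tol:
        return False, None
    return True, cfg


def map_reachability(
    frame: PivotFrame,
    la: LASamples,
    limits: KinematicLimits | None = None,
    tol: float = DEFAULT_TOL_MM,
) -> ReachabilityMap:
    """Classify every LA sample point from the pivot, vectorized."""
    if tol <= 0:
        raise ValidationError("tolerance must be positive")
    if len(la) == 0:
        raise ValidationError("LA sample set is empty")
    limits = limits or KinematicLimits()
    ok, phi, theta, ell = ik_batch(frame, la.points, limits)
    if ok.any():
        tips = frame.to_world(
            tip_local(np.where(ok, phi, 0.0), np.where(ok, theta, 0.0), np.where(ok, ell, 1.0))
        )
        miss = np.linalg.norm(tips - la.points, axis=1) > tol
        ok = ok & ~miss
    phi = np.where(ok, phi, np.nan)
    theta = np.where(ok, theta, np.nan)
    ell = np.where(ok, ell, np.nan)
    return ReachabilityMap(
        points=la.points.copy(),
        reachable=ok,
        phi=phi,
        theta=theta,
        ell=ell,
        tolerance=float(tol),
    )
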