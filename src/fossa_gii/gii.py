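"""Global isotropy index (GII) scoring of candidate puncture sites.

For a catheter pivoting at a fossa-ovalis point, the Jacobian J = dx/du maps
small control changes u = (phi, theta, s) to tip displacements x in the left
atrium.  The GII of a single configuration is sigma_min(J) / sigma_max(J):
1 means the catheter moves equally easily in every direction, 0 means a
direction of motion is lost.

Two aggregation modes are exposed because a per-site score must summarize a
whole workspace of configurations:

* ``global`` (default): min over reachable configurations of sigma_min,
  divided by max over reachable configurations of sigma_max — a worst-case
  isotropy over every left-atrial sample point the site can reach.
* ``local``: the single-configuration ratio at the nominal configuration
  reaching the LA sample centroid.

A site that can reach no sample point scores 0 (worst maneuverability), which
keeps the argmax well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry_io import FOPatch, LASamples
from .kinematics import KinematicLimits, PivotFrame, ik_batch, jacobian_batch_local

__all__ = ["GIIField", "gii_of_matrix", "score_fo_point", "score_field", "mode_score",
           "pivot_frame_at"]


@dataclass
class GIIField:
    """Per-candidate GII scores over the FO with argmax and histogram."""

    fo_points: np.ndarray
    scores: np.ndarray
    argmax_index: int
    argmax_point: np.ndarray
    argmax_score: float
    bin_edges: np.ndarray
    counts: np.ndarray
    mode: str = "global"

    def __post_init__(self) -> None:
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValidationError("GII scores must lie in [0, 1]")
        if int(self.counts.sum()) != len(self.scores):
            raise ValidationError("histogram counts must sum to the number of points")

    def __len__(self) -> int:
        return len(self.scores)


def gii_of_matrix(J: np.ndarray) -> float:
    """sigma_min(J) / sigma_max(J); 0 for the all-zero matrix."""
    J = np.asarray(J, dtype=float)
    if not np.isfinite(J).all():
        raise ValidationError("Jacobian has non-finite entries")
    sv = np.linalg.svd(J, compute_uv=False)
    if sv[0] == 0.0:
        return 0.0
    return float(sv[-1] / sv[0])


def pivot_frame_at(patch: FOPatch, index: int) -> PivotFrame:
    """Pivot frame at candidate ``index``: axis = inward normal, ref in-plane.

    The reference direction is any unit vector orthogonal to the axis; GII and
    reachability are invariant to this choice (it only fixes where phi = 0).
    """
    axis = patch.normals[index]
    helper = np.array([1.0, 0.0, 0.0])
    if abs(float(axis @ helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    ref = np.cross(axis, helper)
    ref /= np.linalg.norm(ref)
    return PivotFrame(origin=patch.points[index], axis=axis, ref=ref)


def _reachable_sigmas(pivot: PivotFrame, la: LASamples, limits: KinematicLimits):
    """Singular values of the local Jacobian at the IK solution of each sample."""
    ok, phi, theta, ell = ik_batch(pivot, la.points, limits)
    if not ok.any():
        return None
    J = jacobian_batch_local(phi[ok], theta[ok], ell[ok], limits)
    # singular values are invariant to the frame rotation, so local J suffices
    sv = np.linalg.svd(J, compute_uv=False)
    return sv


def score_fo_point(
    pivot: PivotFrame,
    la: LASamples,
    limits: KinematicLimits | None = None,
    mode: str = "global",
) -> float:
    """GII score of one candidate pivot over the sampled LA workspace."""
    limits = limits or KinematicLimits()
    if len(la) == 0:
        raise ValidationError("LA sample set is empty")
    if mode == "global":
        sv = _reachable_sigmas(pivot, la, limits)
        if sv is None:
            return 0.0
        smax = float(sv[:, 0].max())
        if smax == 0.0:
            return 0.0
        return float(sv[:, -1].min() / smax)
    if mode == "local":
        ok, phi, theta, ell = ik_batch(pivot, la.centroid[None, :], limits)
        if not ok[0]:
            return 0.0
        J = jacobian_batch_local(phi[:1], theta[:1], ell[:1], limits)[0]
        return gii_of_matrix(J)
    raise ValidationError(f"unknown GII mode {mode!r}")


def score_field(
    patch: FOPatch,
    la: LASamples,
    limits: KinematicLimits | None = None,
    bin_width: float = 0.01,
    mode: str = "global",
) -> GIIField:
    """Score every FO candidate and assemble the field summary.

    The argmax takes the lowest index on exact ties; the histogram uses fixed
    ``bin_width`` bins over [0, 1] (default 0.01).
    """
    limits = limits or KinematicLimits()
    if len(patch) == 0:
        raise ValidationError("FO patch is empty")
    if not 0 < bin_width <= 1:
        raise ValidationError("bin width must lie in (0, 1]")
    scores = np.empty(len(patch))
    for i in range(len(patch)):
        scores[i] = score_fo_point(pivot_frame_at(patch, i), la, limits, mode=mode)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    counts, edges = np.histogram(scores, bins=edges)
    amax = int(np.argmax(scores))
    return GIIField(
        fo_points=patch.points.copy(),
        scores=scores,
        argmax_index=amax,
        argmax_point=patch.points[amax].copy(),
        argmax_score=float(scores[amax]),
        bin_edges=edges,
        counts=counts,
        mode=mode,
    )


def mode_score(field: GIIField) -> tuple[float, int]:
    """Most frequent histogram bin, reported by (bin center, count).

    Ties resolve to the lowest bin.
    """
    if len(field) == 0:
        raise ValidationError("GII field is empty")
    i = int(np.argmax(field.counts))
    center = float((field.bin_edges[i] + field.bin_edges[i + 1]) / 2)
    return center, int(field.counts[i])
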