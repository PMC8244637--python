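"""Dense correspondence of face surfaces against a base mesh.

Every study surface is re-expressed as an ordered list of M points,
index-aligned with the base mesh, so that point i denotes the same
anatomical location on every face.  The correspondence engine is a
landmark-anchored thin-plate-spline warp of the base mesh followed by
closest-point projection onto the target surface — deterministic, one
pass, no iterative free-form refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator

from ._geometry import SurfaceProjector
from .errors import CorrespondenceError
from .mesh import FaceSurface, LandmarkSet, reflect_surface


@dataclass
class BaseMesh:
    """The reference mesh whose vertex order defines the correspondence."""

    vertices: np.ndarray  # (M, 3)
    triangles: np.ndarray  # (t, 3)
    landmarks: LandmarkSet
    #: vertex permutation with vertices[perm[i]] the mirror partner of
    #: vertices[i]; present on templates built symmetric about x = 0.
    mirror_permutation: np.ndarray | None = field(default=None)
    #: vertex index of each named landmark (templates whose landmarks
    #: coincide with mesh vertices).
    landmark_vertex_indices: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.triangles = np.asarray(self.triangles, np.int64)

    @property
    def n_points(self) -> int:
        return len(self.vertices)


@dataclass
class CorrespondedSurface:
    """M base-mesh-ordered surface points for one (possibly mirrored) face."""

    subject_id: str
    mirrored: bool
    points: np.ndarray  # (M, 3) mm
    #: points that could not be projected within the distance cap and
    #: retain their warped (unprojected) position.
    off_surface: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)


def tps_warp(source_landmarks: np.ndarray, target_landmarks: np.ndarray,
             points: np.ndarray) -> np.ndarray:
    """Thin-plate-spline interpolant anchored at landmark pairs.

    Exactly interpolates the landmark pairs and reproduces any affine map
    (degree-1 polynomial tail), so a translated or rotated target yields
    the same rigid motion of every base vertex.
    """
    src = np.asarray(source_landmarks, float)
    d2 = np.sum((src[:, None] - src[None]) ** 2, axis=2)
    d2[np.diag_indices_from(d2)] = np.inf
    if d2.min() == 0.0:
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        raise CorrespondenceError(
            f"TPS system singular: coincident anchor landmarks {i} and {j}")
    try:
        interp = RBFInterpolator(
            src,
            np.asarray(target_landmarks, float),
            kernel="thin_plate_spline",
            degree=1,
        )
    except np.linalg.LinAlgError as exc:
        raise CorrespondenceError(f"TPS system singular: {exc}") from exc
    except ValueError as exc:
        raise CorrespondenceError(f"TPS system could not be built: {exc}") from exc
    return interp(np.asarray(points, float))


def densify(base: BaseMesh, target: FaceSurface,
            projection_cap_factor: float = 10.0,
            max_off_surface_fraction: float = 0.05) -> CorrespondedSurface:
    """Correspond one target face against the base mesh.

    Base vertices are warped by a TPS anchored at the 22 landmark pairs,
    then projected to the closest point on the target surface.  Points
    whose projection distance exceeds ``projection_cap_factor`` times the
    target's median edge length keep the warped position and are flagged
    (this guards the PCA against mesh-boundary artifacts).
    """
    src = base.landmarks.points
    dst = target.landmarks.reordered(base.landmarks.names).points
    warped = tps_warp(src, dst, base.vertices)

    projector = SurfaceProjector(target.vertices, target.triangles)
    projected, dist = projector.project(warped)

    edges = target.vertices[target.triangles[:, [0, 1, 2]]] - \
        target.vertices[target.triangles[:, [1, 2, 0]]]
    median_edge = float(np.median(np.linalg.norm(edges.reshape(-1, 3), axis=1)))
    cap = projection_cap_factor * median_edge

    off = dist > cap
    if off.mean() > max_off_surface_fraction:
        raise CorrespondenceError(
            f"{off.sum()} of {len(off)} points failed projection within "
            f"{cap:.2f} mm on subject {target.subject_id!r}"
        )
    points = np.where(off[:, None], warped, projected)
    return CorrespondedSurface(subject_id=target.subject_id, mirrored=False,
                               points=points, off_surface=off)


def correspond_cohort(base: BaseMesh, faces: list[FaceSurface],
                      include_mirrors: bool = True,
                      projection_cap_factor: float = 10.0) -> list[CorrespondedSurface]:
    """Correspond every face (and, optionally, its mirrored form).

    Mirrored faces are reflected about x = 0 and landmark-relabelled
    *before* correspondence, so index i is anatomically consistent across
    originals and mirrors.
    """
    out: list[CorrespondedSurface] = []
    for face in faces:
        try:
            out.append(densify(base, face, projection_cap_factor))
        except CorrespondenceError as exc:
            raise CorrespondenceError(f"subject {face.subject_id!r}: {exc}") from exc
        if include_mirrors:
            mirrored = reflect_surface(face)
            try:
                cs = densify(base, mirrored, projection_cap_factor)
            except CorrespondenceError as exc:
                raise CorrespondenceError(
                    f"subject {face.subject_id!r} (mirrored): {exc}") from exc
            cs.mirrored = True
            out.append(cs)
    return out


def surfaces_to_matrix(surfaces: list[CorrespondedSurface]) -> np.ndarray:
    """Stack corresponded surfaces into an (n, 3M) data matrix."""
    if not surfaces:
        return np.empty((0, 0))
    return np.stack([s.points.reshape(-1) for s in surfaces])
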