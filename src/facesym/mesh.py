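"""Face meshes, landmark sets, rigid alignment and anthropometric distances.

Coordinate convention (millimetres): x lateral (subject's right at
positive x after alignment is *not* assumed — only that reflection about
x = 0 swaps sides), y vertical, z depth (out of the face).

The 22-landmark scheme used throughout the package is a standard facial
anthropometry set; the source study does not enumerate its landmarks, so
the list below is this package's documented convention and every routine
accepts any scheme whose left/right pairing follows the ``_l``/``_r``
suffix convention (or an explicit pairing map).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .errors import AlignmentError, FormatError, InputError

#: Canonical 22-landmark scheme: 8 midline + 7 bilateral pairs.
CANONICAL_LANDMARKS: tuple[str, ...] = (
    "glabella",
    "nasion",
    "pronasale",
    "subnasale",
    "labiale_superius",
    "labiale_inferius",
    "sublabiale",
    "gnathion",
    "exocanthion_l", "exocanthion_r",
    "endocanthion_l", "endocanthion_r",
    "alare_l", "alare_r",
    "cheilion_l", "cheilion_r",
    "tragion_l", "tragion_r",
    "zygion_l", "zygion_r",
    "gonion_l", "gonion_r",
)


def build_pairing(names: tuple[str, ...] | list[str]) -> dict[str, str]:
    """Left/right pairing involution from the ``_l``/``_r`` suffix convention.

    Midline names map to themselves.  Raises :class:`InputError` when a
    sided name lacks its partner.
    """
    names = list(names)
    pairing: dict[str, str] = {}
    for name in names:
        if name.endswith("_l"):
            partner = name[:-2] + "_r"
        elif name.endswith("_r"):
            partner = name[:-2] + "_l"
        else:
            partner = name
        if partner != name and partner not in names:
            raise InputError(f"sided landmark {name!r} has no partner {partner!r}")
        pairing[name] = partner
    return pairing


@dataclass
class LandmarkSet:
    """Named 3D landmarks with a left/right pairing involution."""

    names: list[str]
    points: np.ndarray  # (n, 3) mm
    pairing: dict[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise InputError(f"duplicate landmark names: {dupes}")
        if self.points.shape != (len(self.names), 3):
            raise InputError(
                f"landmark points shape {self.points.shape} does not match "
                f"{len(self.names)} names"
            )
        if not np.all(np.isfinite(self.points)):
            raise InputError("non-finite landmark coordinates")
        if self.pairing is None:
            self.pairing = build_pairing(self.names)
        covered = set(self.pairing) | set(self.pairing.values())
        if covered != set(self.names) or any(
            self.pairing[self.pairing[n]] != n for n in self.names
        ):
            raise InputError("pairing is not an involution covering all names")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise InputError(f"unknown landmark {name!r}") from None

    def point(self, name: str) -> np.ndarray:
        return self.points[self.index(name)]

    def reflected(self) -> "LandmarkSet":
        """Mirror about x = 0 and relabel each name through the pairing."""
        pts = self.points.copy()
        pts[:, 0] = -pts[:, 0]
        names = [self.pairing[n] for n in self.names]
        return LandmarkSet(names=names, points=pts, pairing=dict(self.pairing))

    def reordered(self, names: list[str]) -> "LandmarkSet":
        idx = [self.index(n) for n in names]
        return LandmarkSet(names=list(names), points=self.points[idx],
                           pairing=dict(self.pairing))


def landmark_distance(lms: LandmarkSet, a: str, b: str) -> float:
    """Euclidean distance between two named landmarks, in mm."""
    return float(np.linalg.norm(lms.point(a) - lms.point(b)))


@dataclass
class FaceSurface:
    """A triangulated face surface with named anatomical landmarks."""

    subject_id: str
    vertices: np.ndarray  # (n, 3) mm
    triangles: np.ndarray  # (t, 3) int
    landmarks: LandmarkSet

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InputError("vertices must be (n, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise InputError("non-finite vertex coordinates")
        if len(self.vertices) < 100:
            raise InputError(f"face mesh has only {len(self.vertices)} vertices (min 100)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise InputError("triangle indexes an invalid vertex")
        # tolerance absorbs single-precision round-off in PLY files
        lo = self.vertices.min(axis=0) - 1e-3
        hi = self.vertices.max(axis=0) + 1e-3
        pts = self.landmarks.points
        if np.any(pts < lo) or np.any(pts > hi):
            bad = [
                self.landmarks.names[i]
                for i in range(len(pts))
                if np.any(pts[i] < lo) or np.any(pts[i] > hi)
            ]
            raise InputError(f"landmarks outside mesh bounding box: {bad}")

    def copy(self) -> "FaceSurface":
        return FaceSurface(
            subject_id=self.subject_id,
            vertices=self.vertices.copy(),
            triangles=self.triangles.copy(),
            landmarks=LandmarkSet(
                names=list(self.landmarks.names),
                points=self.landmarks.points.copy(),
                pairing=dict(self.landmarks.pairing),
            ),
        )


@dataclass
class CohortRecord:
    """Clinical metadata for one subject."""

    subject_id: str
    age: float
    gender: str  # 'F' or 'M'
    group: str  # CTRL, FC, FS, IGE
    duration: float | None = None
    facial_injury: bool = False
    lesion_side: str = "none"  # left, right, none

    def __post_init__(self) -> None:
        if self.gender not in ("F", "M"):
            raise InputError(f"gender must be F or M, got {self.gender!r}")
        if self.group not in ("CTRL", "FC", "FS", "IGE"):
            raise InputError(f"unknown group {self.group!r}")
        if self.age < 0:
            raise InputError("age must be non-negative")
        if self.duration is not None and self.duration > self.age:
            raise InputError("duration of illness cannot exceed age")
        if self.lesion_side not in ("left", "right", "none"):
            raise InputError(f"unknown lesion side {self.lesion_side!r}")


# ---------------------------------------------------------------------------
# I/O


def read_landmarks(path, expected_names=CANONICAL_LANDMARKS) -> LandmarkSet:
    """Read a ``name x y z`` whitespace-delimited landmark file."""
    names: list[str] = []
    pts: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"bad landmark line {line!r} in {path}")
            names.append(parts[0])
            try:
                pts.append([float(v) for v in parts[1:]])
            except ValueError:
                raise FormatError(f"non-numeric coordinate in {line!r}") from None
    if expected_names is not None:
        missing = sorted(set(expected_names) - set(names))
        extra = sorted(set(names) - set(expected_names))
        if missing or extra:
            raise InputError(
                f"landmark scheme mismatch in {path}: missing {missing}, unexpected {extra}"
            )
        lms = LandmarkSet(names=names, points=np.asarray(pts))
        return lms.reordered(list(expected_names))
    return LandmarkSet(names=names, points=np.asarray(pts))


def write_landmarks(lms: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        for name, p in zip(lms.names, lms.points):
            fh.write(f"{name} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def read_face(mesh_path, landmark_path, subject_id: str | None = None,
              expected_names=CANONICAL_LANDMARKS) -> FaceSurface:
    """Load an OBJ or PLY mesh plus its landmark text file."""
    try:
        mesh = trimesh.load(str(mesh_path), process=False, force="mesh")
    except Exception as exc:  # trimesh raises a zoo of types
        raise FormatError(f"unreadable mesh {mesh_path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise FormatError(f"{mesh_path} did not contain a triangulated surface")
    lms = read_landmarks(landmark_path, expected_names=expected_names)
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(mesh_path)))[0]
    return FaceSurface(
        subject_id=subject_id,
        vertices=np.asarray(mesh.vertices, dtype=float),
        triangles=np.asarray(mesh.faces, dtype=np.int64),
        landmarks=lms,
    )


def write_face(face: FaceSurface, mesh_path, landmark_path=None) -> None:
    mesh = trimesh.Trimesh(vertices=face.vertices, faces=face.triangles, process=False)
    mesh.export(str(mesh_path))
    if landmark_path is not None:
        write_landmarks(face.landmarks, landmark_path)


# ---------------------------------------------------------------------------
# Geometry


def reflect_surface(face: FaceSurface, plane: float = 0.0) -> FaceSurface:
    """Mirror a face about the plane x = ``plane``.

    Vertex x-coordinates are reflected, triangle winding is flipped so
    outward normals are preserved, and landmark names are relabelled
    through the left/right pairing (left exocanthion becomes right).
    """
    out = face.copy()
    out.vertices[:, 0] = 2.0 * plane - out.vertices[:, 0]
    out.triangles = out.triangles[:, ::-1].copy()
    lms = out.landmarks
    pts = lms.points.copy()
    pts[:, 0] = 2.0 * plane - pts[:, 0]
    out.landmarks = LandmarkSet(
        names=[lms.pairing[n] for n in lms.names], points=pts, pairing=dict(lms.pairing)
    )
    return out


def rigid_transform(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping source points onto target.

    No scaling: millimetre lengths are preserved (anthropometric distances
    must survive alignment).  Returns ``(R, t)`` with ``aligned = src @ R.T + t``.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    sc = source - source.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = sc.T @ tc
    if np.linalg.matrix_rank(sc) < 3:
        raise AlignmentError("degenerate landmark configuration (rank < 3)")
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = target.mean(axis=0) - r @ source.mean(axis=0)
    return r, t


def procrustes_align(
    faces: list[FaceSurface], reference: LandmarkSet
) -> tuple[list[FaceSurface], np.ndarray]:
    """Rigidly align each face's landmarks to a reference landmark set.

    Returns the aligned faces and the per-face RMS landmark residual (mm).
    """
    aligned: list[FaceSurface] = []
    residuals = np.empty(len(faces))
    for i, face in enumerate(faces):
        lms = face.landmarks.reordered(reference.names)
        r, t = rigid_transform(lms.points, reference.points)
        out = face.copy()
        out.vertices = out.vertices @ r.T + t
        out.landmarks = LandmarkSet(
            names=list(face.landmarks.names),
            points=face.landmarks.points @ r.T + t,
            pairing=dict(face.landmarks.pairing),
        )
        moved = lms.points @ r.T + t
        residuals[i] = float(np.sqrt(np.mean(np.sum((moved - reference.points) ** 2, axis=1))))
        aligned.append(out)
    return aligned, residuals
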