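"""Face signatures: per-point displacement from matched controls in SD units.

A signature expresses a face's corresponded points as z-scores against
the per-point, per-axis mean and standard deviation of age/gender-matched
healthy controls.  The signature weight — the square root of the sum of
squared normalized differences over all points — is a scalar summary of
dysmorphism; the same machinery applied to original-minus-mirrored
difference surfaces yields the asymmetry analyses in
:mod:`facesym.asymmetry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ModelError, StatisticsError
from .mesh import CohortRecord

#: Standard-deviation floor (mm) preventing division blow-ups at
#: low-variance points.
SD_FLOOR = 0.01


@dataclass
class ControlReference:
    """Per-point mean and SD of matched controls' corresponded points."""

    matched_ids: list[str]
    point_mean: np.ndarray  # (M, 3) mm
    point_sd: np.ndarray    # (M, 3) mm, floored strictly positive
    age_window: float = np.nan  # final window used (years)


@dataclass
class Signature:
    subject_id: str
    z: np.ndarray  # (M, 3) unitless normalized differences
    weight: float = field(init=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        self.weight = float(np.sqrt(np.sum(self.z**2)))


def reference_from_points(matched_ids: list[str], points: np.ndarray,
                          sd_floor: float = SD_FLOOR,
                          age_window: float = np.nan) -> ControlReference:
    """Build a control reference from an (n, M, 3) stack of control surfaces."""
    points = np.asarray(points, float)
    mean = points.mean(axis=0)
    sd = points.std(axis=0, ddof=1) if len(points) > 1 else np.zeros_like(mean)
    sd = np.maximum(sd, sd_floor)
    return ControlReference(matched_ids=list(matched_ids), point_mean=mean,
                            point_sd=sd, age_window=age_window)


def match_control_ids(subject: CohortRecord, controls: list[CohortRecord],
                      age_window: float = 10.0, min_n: int = 20,
                      widen_step: float = 5.0) -> tuple[list[str], float]:
    """Ids of same-gender controls within ±age_window years of the subject.

    The window widens in ``widen_step``-year increments until at least
    ``min_n`` controls match (the subject itself is never its own control).
    Returns (ids, final window).
    """
    candidates = [c for c in controls
                  if c.gender == subject.gender and c.subject_id != subject.subject_id]
    if len(candidates) < min_n:
        raise StatisticsError(
            f"only {len(candidates)} {subject.gender} controls available, need {min_n}")
    window = age_window
    while True:
        ids = [c.subject_id for c in candidates if abs(c.age - subject.age) <= window]
        if len(ids) >= min_n:
            return ids, window
        window += widen_step


def matched_controls(subject: CohortRecord, controls: list[CohortRecord],
                     control_points: dict[str, np.ndarray],
                     age_window: float = 10.0, min_n: int = 20,
                     sd_floor: float = SD_FLOOR) -> ControlReference:
    """Control reference from the subject's age/gender-matched controls.

    ``control_points`` maps control subject ids to their (M, 3)
    corresponded point arrays (or any per-subject (M, 3) field, e.g. raw
    asymmetry surfaces for the SAI).
    """
    ids, window = match_control_ids(subject, controls, age_window, min_n)
    stack = np.stack([control_points[i] for i in ids])
    return reference_from_points(ids, stack, sd_floor=sd_floor, age_window=window)


def compute_signature(points: np.ndarray, ref: ControlReference,
                      subject_id: str = "") -> Signature:
    """z[i, axis] = (points − mean) / sd; weight = √(Σ z²)."""
    points = np.asarray(points, float)
    if points.shape != ref.point_mean.shape:
        raise ModelError(
            f"surface shape {points.shape} does not match reference "
            f"{ref.point_mean.shape}")
    z = (points - ref.point_mean) / ref.point_sd
    return Signature(subject_id=subject_id, z=z)


def heat_map(sig: Signature, axis: str = "normal",
             vertex_normals: np.ndarray | None = None,
             clip: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex scalar field and diverging colors for a signature.

    axis 'x'/'y'/'z' extracts that z-score component (lateral, vertical,
    depth); 'normal' projects the per-vertex z-vector onto the base-mesh
    vertex normal, so positive values are outward displacement.  Colors
    run blue → green → red over [−clip, +clip] with green at zero
    coincidence with the matched-control mean.

    Returns (scalars (M,), rgb uint8 (M, 3)).
    """
    from .errors import InputError

    axes = {"x": 0, "y": 1, "z": 2}
    if axis in axes:
        scalars = sig.z[:, axes[axis]]
    elif axis == "normal":
        if vertex_normals is None:
            raise InputError("axis='normal' requires base-mesh vertex normals")
        normals = np.asarray(vertex_normals, float)
        scalars = np.einsum("ij,ij->i", sig.z, normals)
    else:
        raise InputError(f"unknown heat-map axis {axis!r}")

    t = np.clip(scalars / clip, -1.0, 1.0)
    rgb = np.zeros((len(t), 3))
    pos = t >= 0
    rgb[pos, 0] = t[pos]          # green toward red
    rgb[pos, 1] = 1.0 - t[pos]
    rgb[~pos, 2] = -t[~pos]       # green toward blue
    rgb[~pos, 1] = 1.0 + t[~pos]
    return scalars, (rgb * 255).astype(np.uint8)
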