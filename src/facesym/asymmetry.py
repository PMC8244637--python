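"""Facial asymmetry: raw asymmetry surfaces, the signature asymmetry
index (SAI), asymmetry-encoding principal components, and lateral
anthropometric asymmetry measures.

The raw asymmetry of a face is the per-point difference between the
shape-model (retained-mode) representations of the face and of its
mirrored form; a perfectly symmetric face yields the zero field.  The
SAI is the natural log of the signature weight of that difference
measured against matched controls' raw asymmetries.  The log-weight is
the quantity used in all statistics: it is approximately normally
distributed, and for meshes of 10^3–10^4 points its magnitude is of
order ln √(3M) ≈ 4–5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .correspondence import CorrespondedSurface
from .dsm import DSMModel, PCScores, project, reconstruct
from .errors import DomainError, InputError, ModelError, StatisticsError
from .mesh import LandmarkSet, landmark_distance
from .signature import ControlReference, compute_signature


@dataclass
class SAIRecord:
    subject_id: str
    asym_weight: float       # signature weight of the raw-asymmetry surface
    sai: float               # ln(asym_weight); NaN when flagged
    flagged: bool = False    # asym_weight == 0 (exactly at control mean)


@dataclass
class AsymmetryPCEntry:
    pc_index: int
    orig_reflected_correlation: float  # Pearson r in [−1, 1]
    variance_fraction: float
    flagged: bool = False


def raw_asymmetry(model: DSMModel, orig: CorrespondedSurface,
                  mirr: CorrespondedSurface) -> np.ndarray:
    """Original-minus-mirrored displacement field in the retained-mode space.

    reconstruct(project(orig)) − reconstruct(project(mirr)), per point, mm.
    """
    if orig.subject_id != mirr.subject_id:
        raise InputError(
            f"subject mismatch: {orig.subject_id!r} vs {mirr.subject_id!r}")
    ro = reconstruct(model, project(model, orig))
    rm = reconstruct(model, project(model, mirr))
    return ro.points - rm.points


def compute_sai(subject_id: str, raw_diff: np.ndarray,
                control_ref: ControlReference) -> SAIRecord:
    """SAI = ln of the signature weight of a raw-asymmetry field.

    ``control_ref`` is built (via :func:`facesym.signature.matched_controls`)
    from the raw-asymmetry fields of the subject's age/gender-matched
    controls.  A weight of exactly zero (subject at the control mean
    asymmetry) leaves the log undefined and flags the record.
    """
    sig = compute_signature(np.asarray(raw_diff, float), control_ref,
                            subject_id=subject_id)
    if sig.weight == 0.0:
        return SAIRecord(subject_id=subject_id, asym_weight=0.0,
                         sai=float("nan"), flagged=True)
    return SAIRecord(subject_id=subject_id, asym_weight=sig.weight,
                     sai=float(np.log(sig.weight)))


def asymmetry_pcs(model: DSMModel, scores: list[PCScores],
                  subject_ids: list[str] | None = None,
                  threshold: float = -0.9) -> list[AsymmetryPCEntry]:
    """League table of shape modes by original-vs-reflected score correlation.

    Modes capturing a common asymmetry show strongly *inverse* Pearson
    correlation between the scores of original faces and of their
    reflections; entries with r below ``threshold`` are flagged.  The
    table is sorted ascending (most negative first); zero-variance modes
    have no defined correlation and are excluded.

    ``subject_ids`` restricts the computation to a subgroup.
    """
    orig = {s.subject_id: s.scores for s in scores if not s.mirrored}
    mirr = {s.subject_id: s.scores for s in scores if s.mirrored}
    ids = sorted(orig) if subject_ids is None else list(subject_ids)
    missing = [i for i in ids if i not in orig or i not in mirr]
    if missing:
        raise InputError(f"subjects missing original or reflected scores: {missing}")
    if len(ids) < 3:
        raise StatisticsError(f"subgroup of {len(ids)} subjects is too small")

    a = np.stack([orig[i] for i in ids])  # (n, retained)
    b = np.stack([mirr[i] for i in ids])
    total = model.variances.sum()
    entries: list[AsymmetryPCEntry] = []
    for j in range(a.shape[1]):
        sa, sb = a[:, j], b[:, j]
        if np.std(sa) == 0.0 or np.std(sb) == 0.0:
            continue  # degenerate: correlation undefined
        r = float(stats.pearsonr(sa, sb)[0])
        entries.append(AsymmetryPCEntry(
            pc_index=j, orig_reflected_correlation=r,
            variance_fraction=float(model.variances[j] / total),
            flagged=r < threshold))
    entries.sort(key=lambda e: e.orig_reflected_correlation)
    return entries


def lateral_asymmetry(right: float, left: float) -> float:
    """(R − L)/(R + L): unitless lateral asymmetry of paired measures."""
    if right + left <= 0:
        raise DomainError(f"R + L must be positive, got {right + left}")
    return (right - left) / (right + left)


#: Landmark constructs for the anthropometric asymmetry measures paired
#: with specific asymmetry modes: (left measure, right measure), each an
#: endpoint pair.
PC_MEASURE_LANDMARKS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    # horizontal deflection of the nose tip
    "nose_deflection": (("subnasale", "exocanthion_l"), ("subnasale", "exocanthion_r")),
    # nose rotation with vertical mouth-corner displacement
    "nose_mouth": (("pronasale", "cheilion_l"), ("pronasale", "cheilion_r")),
    # eye-depth asymmetry
    "eye_depth": (("nasion", "endocanthion_l"), ("nasion", "endocanthion_r")),
    # orbit/mouth lateral asymmetry
    "orbit_mouth": (("exocanthion_l", "cheilion_l"), ("exocanthion_r", "cheilion_r")),
}


def pc_asymmetry_measures(lms: LandmarkSet, pc_kind: str) -> tuple[float, float, float]:
    """(L, R) distance pair in mm and their (R − L)/(R + L) for one construct."""
    try:
        (la, lb), (ra, rb) = PC_MEASURE_LANDMARKS[pc_kind]
    except KeyError:
        raise InputError(
            f"unknown pc_kind {pc_kind!r}; choose from "
            f"{sorted(PC_MEASURE_LANDMARKS)}") from None
    left = landmark_distance(lms, la, lb)
    right = landmark_distance(lms, ra, rb)
    return left, right, lateral_asymmetry(right, left)
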