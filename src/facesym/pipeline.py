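"""High-level study orchestration: corresponded cohort → shape model →
per-subject SAI table → cohort statistics.

These functions operate on stacked point arrays (n, M, 3) so that the
repeated-simulation studies stay fast; they are algebraically identical
to chaining the per-subject operations in :mod:`facesym.asymmetry`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .correspondence import CorrespondedSurface
from .dsm import DSMModel, fit_dsm
from .errors import InputError
from .mesh import CohortRecord, FaceSurface, landmark_distance
from .signature import SD_FLOOR, match_control_ids


def _records_from_frame(cohort: pd.DataFrame) -> list[CohortRecord]:
    recs = []
    for row in cohort.itertuples(index=False):
        dur = getattr(row, "duration", None)
        if dur is not None and (isinstance(dur, float) and np.isnan(dur)):
            dur = None
        recs.append(CohortRecord(
            subject_id=str(row.subject_id), age=float(row.age),
            gender=str(row.gender), group=str(row.group), duration=dur,
            facial_injury=bool(getattr(row, "facial_injury", False)),
            lesion_side=str(getattr(row, "lesion_side", "none"))))
    return recs


def fit_cohort_dsm(orig_points: np.ndarray, mirr_points: np.ndarray,
                   subject_ids: list[str], coverage: float = 0.99) -> DSMModel:
    """Shape model over originals and mirrored forms together."""
    surfaces = [CorrespondedSurface(sid, False, p)
                for sid, p in zip(subject_ids, orig_points)]
    surfaces += [CorrespondedSurface(sid, True, p)
                 for sid, p in zip(subject_ids, mirr_points)]
    return fit_dsm(surfaces, coverage=coverage)


def sai_table(orig_points: np.ndarray, mirr_points: np.ndarray,
              cohort: pd.DataFrame, coverage: float = 0.99,
              age_window: float = 10.0, min_n: int = 20,
              sd_floor: float = SD_FLOOR,
              model: DSMModel | None = None) -> tuple[pd.DataFrame, DSMModel]:
    """Per-subject signature asymmetry index for a corresponded cohort.

    Fits the mirror-inclusive shape model, forms each subject's raw
    asymmetry in the retained-mode space, normalizes it against the raw
    asymmetries of the subject's age/gender-matched controls, and returns
    the SAI (= ln signature weight) table aligned to ``cohort`` rows.
    """
    orig_points = np.asarray(orig_points, float)
    mirr_points = np.asarray(mirr_points, float)
    if orig_points.shape != mirr_points.shape:
        raise InputError("original and mirrored point stacks differ in shape")
    n, m, _ = orig_points.shape
    if len(cohort) != n:
        raise InputError("cohort table does not match the number of surfaces")
    ids = cohort["subject_id"].astype(str).tolist()
    if model is None:
        model = fit_cohort_dsm(orig_points, mirr_points, ids, coverage)

    # raw asymmetry of every subject in the retained-mode representation
    vk = model.modes[: model.retained]  # (k, 3M)
    diff = (orig_points - mirr_points).reshape(n, -1)
    raw = (diff @ vk.T) @ vk  # (n, 3M): model-space original-minus-mirrored

    records = _records_from_frame(cohort)
    controls = [r for r in records if r.group == "CTRL"]
    ctrl_idx = {r.subject_id: i for i, r in enumerate(records) if r.group == "CTRL"}
    rows = []
    for i, rec in enumerate(records):
        matched, window = match_control_ids(rec, controls, age_window, min_n)
        sel = raw[[ctrl_idx[c] for c in matched]]
        mean = sel.mean(axis=0)
        sd = np.maximum(sel.std(axis=0, ddof=1), sd_floor)
        z = (raw[i] - mean) / sd
        weight = float(np.sqrt(np.sum(z**2)))
        rows.append({
            "subject_id": rec.subject_id, "group": rec.group, "age": rec.age,
            "gender": rec.gender,
            "asym_weight": weight,
            "sai": float(np.log(weight)) if weight > 0 else np.nan,
            "flagged": weight == 0.0,
            "matched_n": len(matched), "matched_window": window,
        })
    return pd.DataFrame(rows), model


#: measures of Table-2 style anthropometric comparisons (endpoint pairs;
#: bilateral measures report the mean of the two sides)
ANTHROPOMETRIC_MEASURES = {
    "palpebral_fissure_length": [("exocanthion_l", "endocanthion_l"),
                                 ("exocanthion_r", "endocanthion_r")],
    "nose_length": [("nasion", "subnasale")],
}


def anthropometric_table(faces: list[FaceSurface],
                         cohort: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-subject anthropometric length table (mm)."""
    meta = cohort.set_index("subject_id")
    rows = []
    for face in faces:
        for measure, pairs in ANTHROPOMETRIC_MEASURES.items():
            val = float(np.mean([landmark_distance(face.landmarks, a, b)
                                 for a, b in pairs]))
            rows.append({"subject_id": face.subject_id,
                         "gender": meta.loc[face.subject_id, "gender"],
                         "group": meta.loc[face.subject_id, "group"],
                         "measure": measure, "value": val})
    return pd.DataFrame(rows)
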