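"""Synthetic faces, cohorts and regional brain tables.

The generator provides every input the analysis pipeline consumes, with
the statistical structure the method assumes: a symmetric template face
deformed by shared symmetric shape modes and lateralized asymmetric
modes (with a group-specific asymmetry amplitude), capture noise applied
independently to a subject's original and mirrored corresponded forms,
and long-format regional brain tables with covariate structure, an
optional planted duration–thickness-asymmetry correlation and an
optional sparse BASI→SAI link.

Everything is reproducible bit-for-bit from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import Delaunay

from .brain import DEFAULT_REGION_MANIFEST
from .correspondence import BaseMesh
from .errors import ConfigError
from .mesh import CANONICAL_LANDMARKS, CohortRecord, FaceSurface, LandmarkSet

# ---------------------------------------------------------------------------
# Template face

_FACE_HALF_WIDTH = 80.0   # mm, lateral semi-axis of the face disk
_FACE_HALF_HEIGHT = 95.0  # mm, vertical semi-axis

#: nominal landmark positions in the (x, y) parameter plane, mm.  Sided
#: entries give the right-side (x > 0) position; the left partner is the
#: exact mirror.  Landmarks snap to the nearest template vertex.
_LANDMARK_PLAN: dict[str, tuple[float, float]] = {
    "glabella": (0.0, 58.0),
    "nasion": (0.0, 50.0),
    "pronasale": (0.0, 12.0),
    "subnasale": (0.0, 2.0),
    "labiale_superius": (0.0, -16.0),
    "labiale_inferius": (0.0, -28.0),
    "sublabiale": (0.0, -38.0),
    "gnathion": (0.0, -60.0),
    "exocanthion_r": (45.0, 40.0),
    "endocanthion_r": (17.0, 40.0),
    "alare_r": (14.0, -2.0),
    "cheilion_r": (26.0, -24.0),
    "tragion_r": (76.0, 20.0),
    "zygion_r": (62.0, 18.0),
    "gonion_r": (52.0, -45.0),
}


def _face_depth(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Smooth face-like depth field (mm): dome, nose ridge, eye sockets,
    lips, chin.  Even in x by construction (evaluated on one half and
    mirrored exactly)."""
    r2 = (x / 85.0) ** 2 + (y / 100.0) ** 2
    dome = 45.0 * np.sqrt(np.clip(1.0 - r2, 0.0, None)) - 25.0
    nose = 22.0 * np.exp(-(x**2) / 120.0 - ((y - 15.0) ** 2) / 900.0)
    sockets = -6.0 * (
        np.exp(-((x - 32.0) ** 2) / 180.0 - ((y - 38.0) ** 2) / 80.0)
        + np.exp(-((x + 32.0) ** 2) / 180.0 - ((y - 38.0) ** 2) / 80.0)
    )
    lips = 3.0 * np.exp(-(x**2) / 500.0 - ((y + 22.0) ** 2) / 40.0)
    chin = 5.0 * np.exp(-(x**2) / 600.0 - ((y + 70.0) ** 2) / 300.0)
    return dome + nose + sockets + lips + chin


def _disk_points(m: int) -> tuple[np.ndarray, np.ndarray]:
    """m unit-disk points in concentric rings, exactly symmetric about u = 0.

    Returns (uv (m, 2), mirror permutation).  Off-axis points are built
    for the u > 0 half and mirrored by negation, so symmetry is exact in
    floating point; axis points carry u = 0.0 exactly.
    """
    center = m % 2  # odd m gets a center point
    half = (m - center) // 2  # Σ_j q_j
    n_rings = max(2, int(round(np.sqrt(2.0 * half / np.pi))))
    q = [max(1, int(round(np.pi * j))) for j in range(1, n_rings + 1)]
    # adjust ring counts to hit the total exactly
    diff = half - sum(q)
    j = n_rings - 1
    while diff != 0:
        step = 1 if diff > 0 else -1
        if q[j] + step >= 1:
            q[j] += step
            diff -= step
        j = j - 1 if j > 0 else n_rings - 1

    uv: list[tuple[float, float]] = []
    perm: list[int] = []
    if center:
        uv.append((0.0, 0.0))
        perm.append(0)
    for j, qj in enumerate(q, start=1):
        rho = j / n_rings
        base = len(uv)
        uv.append((0.0, -rho))  # bottom axis point
        perm.append(base)
        uv.append((0.0, rho))   # top axis point
        perm.append(base + 1)
        for k in range(1, qj):
            theta = -np.pi / 2 + np.pi * k / qj
            u = rho * np.cos(theta)
            v = rho * np.sin(theta)
            right = len(uv)
            uv.append((u, v))
            uv.append((-u, v))
            perm.extend([right + 1, right])
    return np.asarray(uv, float), np.asarray(perm, np.int64)


def make_template(m: int = 1000) -> BaseMesh:
    """A smooth face-like template mesh, exactly symmetric about x = 0.

    ``m`` vertices in concentric rings over an elliptical face outline,
    Delaunay-triangulated in the parameter plane, with the canonical 22
    landmarks snapped to mesh vertices (midline landmarks on x = 0,
    bilateral pairs exactly mirrored).  The mirror permutation of the
    vertex set is carried on the returned mesh.
    """
    if m < 500:
        raise ConfigError(f"template needs at least 500 vertices, got {m}")
    uv, perm = _disk_points(m)
    x = uv[:, 0] * _FACE_HALF_WIDTH
    y = uv[:, 1] * _FACE_HALF_HEIGHT
    # evaluate depth on the x >= 0 representative of each mirror pair and
    # copy to the partner, so z is exactly even in x (right-side points are
    # always appended before their mirrors, so min(i, perm[i]) has x >= 0)
    rep = np.minimum(np.arange(m), perm)
    z = _face_depth(x[rep], y[rep])
    vertices = np.column_stack([x, y, z])

    tri = Delaunay(uv).simplices.astype(np.int64)

    lm_names: list[str] = []
    lm_idx: list[int] = []
    for name in CANONICAL_LANDMARKS:
        if name.endswith("_l"):
            continue  # assigned with its right partner
        px, py = _LANDMARK_PLAN[name]
        if px == 0.0:
            cand = np.flatnonzero(x == 0.0)
        else:
            cand = np.flatnonzero(x > 0.0)
        d2 = (x[cand] - px) ** 2 + (y[cand] - py) ** 2
        idx = int(cand[np.argmin(d2)])
        lm_names.append(name)
        lm_idx.append(idx)
        if name.endswith("_r"):
            lm_names.append(name[:-2] + "_l")
            lm_idx.append(int(perm[idx]))
    order = [lm_names.index(n) for n in CANONICAL_LANDMARKS]
    lm_names = [lm_names[i] for i in order]
    lm_idx = [lm_idx[i] for i in order]

    landmarks = LandmarkSet(names=lm_names, points=vertices[lm_idx])
    return BaseMesh(vertices=vertices, triangles=tri, landmarks=landmarks,
                    mirror_permutation=perm,
                    landmark_vertex_indices=np.asarray(lm_idx, np.int64))


def mirror_field(field_arr: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Reflect-and-relabel a per-vertex displacement field (or surface)."""
    out = field_arr[perm].copy()
    out[:, 0] = -out[:, 0]
    return out


def _smooth_field(vertices: np.ndarray, rng: np.random.Generator,
                  n_bumps: int = 6) -> np.ndarray:
    """A smooth random (M, 3) displacement field: sum of Gaussian bumps."""
    m = len(vertices)
    out = np.zeros((m, 3))
    centers = vertices[rng.integers(0, m, size=n_bumps)]
    widths = rng.uniform(15.0, 40.0, size=n_bumps)
    coeffs = rng.normal(size=(n_bumps, 3))
    for c, w, a in zip(centers, widths, coeffs):
        d2 = np.sum((vertices - c) ** 2, axis=1)
        out += np.exp(-d2 / (2.0 * w**2))[:, None] * a
    return out


def make_mode_fields(template: BaseMesh, n_symmetric: int, n_asymmetric: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Unit shape-mode fields: symmetric (reflect-and-relabel invariant)
    and antisymmetric (reflect-and-relabel negates), normalized so a unit
    amplitude produces ~1 mm RMS displacement per coordinate."""
    perm = template.mirror_permutation
    m = template.n_points
    sym, asym = [], []
    while len(sym) < n_symmetric or len(asym) < n_asymmetric:
        g = _smooth_field(template.vertices, rng)
        gm = mirror_field(g, perm)
        if len(sym) < n_symmetric:
            s = (g + gm) / 2.0
            norm = np.linalg.norm(s)
            if norm > 1e-9:
                sym.append(s * (np.sqrt(3.0 * m) / norm))
                continue
        if len(asym) < n_asymmetric:
            a = (g - gm) / 2.0
            norm = np.linalg.norm(a)
            if norm > 1e-9:
                asym.append(a * (np.sqrt(3.0 * m) / norm))
    shape_s = np.stack(sym) if sym else np.empty((0, m, 3))
    shape_a = np.stack(asym) if asym else np.empty((0, m, 3))
    return shape_s, shape_a


# ---------------------------------------------------------------------------
# Face cohort simulation


@dataclass
class FaceSimConfig:
    mesh_resolution: int = 1000
    #: default cohort sizes (about one third of a typical clinical study)
    n_per_group: dict = field(default_factory=lambda: {
        "CTRL": 68, "FS": 61, "FC": 48, "IGE": 17})
    sym_mode_sds: tuple = (2.0, 1.5, 1.0)   # mm RMS per coordinate
    asym_mode_sds: tuple = (0.5, 0.3)       # mm RMS per coordinate
    #: extra asymmetric-mode SD per group (mm); the lateralized-lesion
    #: group carries the planted effect by default
    group_asym_amplitude: dict = field(default_factory=lambda: {
        "CTRL": 0.0, "FC": 0.0, "FS": 1.0, "IGE": 0.0})
    noise_sd: float = 0.2                   # mm, per corresponded form
    age_range: tuple = (18.0, 77.0)
    male_fraction: float = 0.45
    duration_asym_coupling: float = 0.0     # years per mm of |asym amplitude|
    facial_injury_rate: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.mesh_resolution < 500:
            raise ConfigError("mesh_resolution must be ≥ 500")
        if any(s < 0 for s in self.sym_mode_sds + self.asym_mode_sds):
            raise ConfigError("mode SDs must be non-negative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ConfigError("group sizes must be non-negative")
        if not all(np.isfinite(v) for v in self.group_asym_amplitude.values()):
            raise ConfigError("group asymmetry amplitudes must be finite")


@dataclass
class SimulatedFaceCohort:
    template: BaseMesh
    faces: list[FaceSurface]
    records: list[CohortRecord]
    cohort: pd.DataFrame
    #: corresponded original forms (n, M, 3): simulated faces are built on
    #: the template so their vertices are index-aligned by construction
    orig_points: np.ndarray
    #: corresponded mirrored forms (n, M, 3), independently noised
    mirr_points: np.ndarray
    sym_fields: np.ndarray
    asym_fields: np.ndarray
    config: FaceSimConfig


def simulate_faces(cfg: FaceSimConfig,
                   template: BaseMesh | None = None) -> SimulatedFaceCohort:
    """Generate a landmarked synthetic face cohort with planted asymmetry.

    Each face is template + Σ aᵢ·symmetric-modeᵢ + Σ bⱼ·asymmetric-modeⱼ
    with a ~ N(0, SDᵢ²) and b ~ N(0, (SDⱼ + δ_group)²).  Capture noise is
    applied independently to the original and mirrored corresponded
    forms, emulating per-capture measurement and correspondence error.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    if template is None:
        template = make_template(cfg.mesh_resolution)
    perm = template.mirror_permutation
    sym_fields, asym_fields = make_mode_fields(
        template, len(cfg.sym_mode_sds), len(cfg.asym_mode_sds), rng)

    records: list[CohortRecord] = []
    faces: list[FaceSurface] = []
    orig_list, mirr_list = [], []
    counter = 0
    for group in ("CTRL", "FC", "FS", "IGE"):
        delta = float(cfg.group_asym_amplitude.get(group, 0.0))
        for _ in range(int(cfg.n_per_group.get(group, 0))):
            counter += 1
            sid = f"S{counter:04d}"
            age = float(rng.uniform(*cfg.age_range))
            gender = "M" if rng.random() < cfg.male_fraction else "F"
            a = rng.normal(size=len(cfg.sym_mode_sds)) * np.asarray(cfg.sym_mode_sds)
            b = rng.normal(size=len(cfg.asym_mode_sds)) * (
                np.asarray(cfg.asym_mode_sds) + delta)
            clean = template.vertices.copy()
            for coef, fld in zip(a, sym_fields):
                clean += coef * fld
            for coef, fld in zip(b, asym_fields):
                clean += coef * fld
            if cfg.noise_sd > 0:
                orig = clean + rng.normal(scale=cfg.noise_sd, size=clean.shape)
                mirr = mirror_field(clean, perm) + rng.normal(
                    scale=cfg.noise_sd, size=clean.shape)
            else:
                orig = clean
                mirr = mirror_field(clean, perm)

            duration = None
            lesion = "none"
            if group != "CTRL":
                base = float(rng.uniform(1.0, max(2.0, age - 15.0)))
                if cfg.duration_asym_coupling:
                    base += cfg.duration_asym_coupling * float(np.sum(np.abs(b)))
                duration = float(np.clip(base, 0.5, age))
            if group == "FS":
                lesion = "left" if rng.random() < 0.5 else "right"
            rec = CohortRecord(
                subject_id=sid, age=age, gender=gender, group=group,
                duration=duration,
                facial_injury=bool(rng.random() < cfg.facial_injury_rate),
                lesion_side=lesion)
            records.append(rec)
            lm_idx = template.landmark_vertex_indices
            faces.append(FaceSurface(
                subject_id=sid, vertices=orig, triangles=template.triangles,
                landmarks=LandmarkSet(names=list(template.landmarks.names),
                                      points=orig[lm_idx])))
            orig_list.append(orig)
            mirr_list.append(mirr)

    cohort = pd.DataFrame([{
        "subject_id": r.subject_id, "age": r.age, "gender": r.gender,
        "group": r.group, "duration": r.duration,
        "facial_injury": r.facial_injury, "lesion_side": r.lesion_side,
    } for r in records])
    n = len(records)
    m = template.n_points
    orig_points = np.stack(orig_list) if n else np.empty((0, m, 3))
    mirr_points = np.stack(mirr_list) if n else np.empty((0, m, 3))
    return SimulatedFaceCohort(template=template, faces=faces, records=records,
                               cohort=cohort, orig_points=orig_points,
                               mirr_points=mirr_points, sym_fields=sym_fields,
                               asym_fields=asym_fields, config=cfg)


# ---------------------------------------------------------------------------
# Brain table simulation


@dataclass
class BrainSimConfig:
    manifest: list = field(default_factory=lambda: list(DEFAULT_REGION_MANIFEST))
    #: baseline (mean, SD across subjects) per measure kind
    thickness_baseline: tuple = (2.5, 0.1)        # mm
    volume_baseline: tuple = (4000.0, 350.0)      # mm³ (subcortical)
    subfield_baseline: tuple = (500.0, 50.0)      # mm³ (hippocampal subfields)
    area_baseline: tuple = (90_000.0, 8_000.0)    # mm² (total surface area)
    basi_noise_sd: float = 0.02                   # per-region BASI units
    hemi_noise_frac: float = 0.002                # per-hemisphere measurement noise
    #: planted correlation between duration of illness and the summary
    #: thickness BASI (negative: longer illness, thinner left relative to right)
    duration_thickness_r: float = -0.19
    regional_duration_weight: float = 0.5
    #: sparse BASI→SAI link: number of linked features and per-feature SNR
    n_linked_features: int = 0
    link_snr: float = 5.0
    link_scale: float = 0.03
    scanner_count: int = 2
    scanner_offset_frac: float = 0.01             # additive offset per scanner step
    icv_effect_frac: float = 0.04                 # per ICV z-score
    age_effect_frac: float = -0.02                # per age z-score
    sex_effect_frac: float = 0.01                 # male minus female
    seed: int = 0

    def validate(self) -> None:
        if abs(self.duration_thickness_r) > 1:
            raise ConfigError("planted correlation must have |r| ≤ 1")
        if self.n_linked_features > len(self.manifest):
            raise ConfigError("more linked features than regions")
        if self.basi_noise_sd <= 0:
            raise ConfigError("basi_noise_sd must be positive")


def _kind_baseline(cfg: BrainSimConfig, region: str, measure: str) -> tuple[float, float]:
    if measure == "thickness":
        return cfg.thickness_baseline
    if measure == "area":
        return cfg.area_baseline
    from .brain import HIPPOCAMPAL_SUBFIELD_REGIONS

    if region in HIPPOCAMPAL_SUBFIELD_REGIONS:
        return cfg.subfield_baseline
    return cfg.volume_baseline


def simulate_brain(cfg: BrainSimConfig, sai: np.ndarray,
                   cohort: pd.DataFrame | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Long-format regional measures + covariates for ``len(sai)`` subjects.

    Returns (measures, covariates, linked_feature_names).  Left/right
    values are constructed from latent per-region asymmetries so that the
    resulting BASI matrix carries (i) the planted duration correlation on
    the summary thickness BASI and (ii) an optional sparse linear link to
    the supplied SAI vector at the configured per-feature SNR.  Covariates
    (ICV, age, sex, scanner) enter both hemispheres additively with known
    effects, to be removed by linear adjustment.
    """
    cfg.validate()
    sai = np.asarray(sai, float)
    n = len(sai)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    if cohort is not None:
        if len(cohort) != n:
            raise ConfigError("cohort length does not match SAI vector")
        subjects = cohort["subject_id"].astype(str).tolist()
        age = cohort["age"].to_numpy(float)
        sex = cohort["gender"].astype(str).tolist()
        duration = cohort["duration"].to_numpy(float)
    else:
        subjects = [f"S{i + 1:04d}" for i in range(n)]
        age = rng.uniform(18.0, 77.0, n)
        sex = ["M" if rng.random() < 0.45 else "F" for _ in range(n)]
        duration = rng.uniform(1.0, 40.0, n)

    icv = rng.normal(1.45e6, 1.3e5, n)
    scanner = [f"scanner_{int(rng.integers(cfg.scanner_count))}" for _ in range(n)]
    covariates = pd.DataFrame({"subject_id": subjects, "icv": icv, "age": age,
                               "sex": sex, "scanner": scanner})

    def zscore(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, float)
        ok = np.isfinite(v)
        out = np.zeros(n)
        if ok.sum() > 1 and np.nanstd(v[ok]) > 0:
            out[ok] = (v[ok] - v[ok].mean()) / v[ok].std()
        return out

    # subject-level thickness-asymmetry latent with the planted duration corr
    rho = cfg.duration_thickness_r
    z_dur = zscore(duration)
    thick_latent = rho * z_dur + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n)
    area_latent = rng.normal(size=n)
    z_y = zscore(sai)

    linked = [f"{r}_{m}" for r, m in cfg.manifest[: cfg.n_linked_features]]
    z_icv = zscore(icv)
    z_age = zscore(age)
    male = np.array([1.0 if s == "M" else 0.0 for s in sex])
    scan_idx = np.array([int(s.rsplit("_", 1)[1]) for s in scanner], float)

    rows: list[dict] = []

    def emit(region: str, measure: str, basi_latent: np.ndarray,
             mean: float, sd: float) -> None:
        m_r = float(rng.normal(mean, sd * 0.2))  # region-specific baseline
        per_subj = m_r + rng.normal(scale=sd, size=n)  # shared bilateral size
        cov_effect = abs(m_r) * (cfg.icv_effect_frac * z_icv
                                 + cfg.age_effect_frac * z_age
                                 + cfg.sex_effect_frac * male
                                 + cfg.scanner_offset_frac * scan_idx)
        noise = abs(m_r) * cfg.hemi_noise_frac
        left = per_subj * (1 + basi_latent / 2) + cov_effect + rng.normal(scale=noise, size=n)
        right = per_subj * (1 - basi_latent / 2) + cov_effect + rng.normal(scale=noise, size=n)
        for i, sid in enumerate(subjects):
            rows.append({"subject_id": sid, "region": region, "hemisphere": "left",
                         "measure": measure, "value": left[i]})
            rows.append({"subject_id": sid, "region": region, "hemisphere": "right",
                         "measure": measure, "value": right[i]})

    for region, measure in cfg.manifest:
        b = cfg.basi_noise_sd * rng.normal(size=n)
        if measure == "thickness":
            b = b + cfg.basi_noise_sd * cfg.regional_duration_weight * thick_latent
        name = f"{region}_{measure}"
        if name in linked:
            e = rng.normal(size=n) / np.sqrt(cfg.link_snr)
            b = cfg.link_scale * (z_y + e)
        mean, sd = _kind_baseline(cfg, region, measure)
        emit(region, measure, b, mean, sd)

    # hemispheric summary measures
    emit("mean_thickness", "thickness", cfg.basi_noise_sd * thick_latent,
         *cfg.thickness_baseline)
    emit("total_surface_area", "area", cfg.basi_noise_sd * area_latent,
         *cfg.area_baseline)

    measures = pd.DataFrame(rows)
    return measures, covariates, linked


def inject_outlier(table: pd.DataFrame, subject_id: str, region: str,
                   hemisphere: str, measure: str, z: float) -> pd.DataFrame:
    """Overwrite one cell so its cohort z-score equals ``z`` exactly.

    Solves for the value whose z within the *modified* column (sample
    mean and ddof-1 SD including the new value) is the target; requires
    |z| < (n−1)/√n.
    """
    out = table.copy()
    col = (out["region"] == region) & (out["hemisphere"] == hemisphere) & \
        (out["measure"] == measure)
    cell = col & (out["subject_id"] == subject_id)
    if cell.sum() != 1:
        raise ConfigError("outlier cell not found (or not unique)")
    others = out.loc[col & ~cell, "value"].to_numpy(float)
    n = len(others) + 1
    if abs(z) >= (n - 1) / np.sqrt(n):
        raise ConfigError(f"|z|={abs(z)} not reachable in a sample of {n}")

    def f(v: float) -> float:
        vals = np.append(others, v)
        return (v - vals.mean()) / vals.std(ddof=1) - z

    m0, s0 = others.mean(), others.std(ddof=1)
    lo, hi = m0, m0 + np.sign(z) * 1000.0 * max(s0, 1e-9)
    if z < 0:
        lo, hi = hi, lo
    value = brentq(f, lo, hi)
    out.loc[cell, "value"] = value
    return out
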