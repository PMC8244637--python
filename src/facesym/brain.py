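"""Regional brain measures: covariate adjustment, cohort-level QC, and
brain asymmetry indices (BASI).

Input is a long-format table emulating FreeSurfer Desikan-Killiany
outputs — one row per (subject, region, hemisphere, measure kind) —
plus per-subject covariates (intracranial volume, age, sex, scanner).
The BASI of a paired region is (left − right) divided by the average of
the two covariate-adjusted measures, an antisymmetric, scale-invariant
laterality index in [−2, 2].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InputError, StatisticsError

MEASURE_COLUMNS = ["subject_id", "region", "hemisphere", "measure", "value"]
COVARIATE_COLUMNS = ["subject_id", "icv", "age", "sex", "scanner"]

# 51 paired regions: 30 Desikan-Killiany cortical thicknesses, 8
# subcortical volumes, 13 hippocampal-subfield volumes.  The source
# atlas has more cortical labels; this manifest is the package default
# and every routine accepts a user-supplied (region, measure) list.
CORTICAL_THICKNESS_REGIONS = [
    "caudal_anterior_cingulate", "caudal_middle_frontal", "cuneus",
    "entorhinal", "frontal_pole", "fusiform", "inferior_parietal",
    "inferior_temporal", "insula", "lateral_occipital",
    "lateral_orbitofrontal", "lingual", "medial_orbitofrontal",
    "middle_temporal", "paracentral", "parahippocampal", "pars_opercularis",
    "pars_orbitalis", "pars_triangularis", "pericalcarine", "postcentral",
    "posterior_cingulate", "precentral", "precuneus",
    "rostral_anterior_cingulate", "rostral_middle_frontal",
    "superior_frontal", "superior_parietal", "superior_temporal",
    "supramarginal",
]
SUBCORTICAL_VOLUME_REGIONS = [
    "thalamus", "caudate", "putamen", "pallidum", "hippocampus",
    "amygdala", "accumbens", "ventral_dc",
]
HIPPOCAMPAL_SUBFIELD_REGIONS = [
    "ca1", "ca3", "ca4", "gc_ml_dg", "subiculum", "presubiculum",
    "parasubiculum", "molecular_layer", "hata", "fimbria",
    "hippocampal_tail", "hippocampal_fissure", "whole_hippocampus",
]

#: (region, measure kind) pairs defining the default 51-column BASI matrix.
DEFAULT_REGION_MANIFEST: list[tuple[str, str]] = (
    [(r, "thickness") for r in CORTICAL_THICKNESS_REGIONS]
    + [(r, "volume") for r in SUBCORTICAL_VOLUME_REGIONS]
    + [(r, "volume") for r in HIPPOCAMPAL_SUBFIELD_REGIONS]
)

#: hemispheric summary measures carried alongside the regional ones
SUMMARY_MEASURES = [("mean_thickness", "thickness"), ("total_surface_area", "area")]


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in MEASURE_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"measure table missing columns {missing}")
    bad = set(table["hemisphere"]) - {"left", "right"}
    if bad:
        raise InputError(f"unknown hemisphere labels {sorted(bad)}")


def adjust_measures(table: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Adjust regional measures for ICV, age, sex and scanner by OLS.

    Per (region, hemisphere, measure) the model
    ``value ~ 1 + icv + age + sex + scanner`` is fitted and the adjusted
    value is the residual plus the fit at covariate means, keeping the
    result on the original positive scale.  Scanner enters as categorical
    dummies (first level as reference); a rank-deficient dummy is dropped
    with a warning.
    """
    _check_table(table)
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing:
        raise InputError(f"covariates missing columns {missing}")
    cov = covariates.set_index("subject_id")
    subjects = pd.Index(sorted(table["subject_id"].unique()), name="subject_id")
    absent = subjects.difference(cov.index)
    if len(absent):
        raise InputError(f"no covariates for subjects {list(absent)[:5]} ...")
    cov = cov.loc[subjects]

    sex = (cov["sex"].astype(str).str.upper().isin(["M", "MALE", "1"])).astype(float)
    cols = [np.ones(len(subjects)), cov["icv"].to_numpy(float),
            cov["age"].to_numpy(float), sex.to_numpy()]
    names = ["intercept", "icv", "age", "sex"]
    scanners = sorted(cov["scanner"].astype(str).unique())
    for s in scanners[1:]:
        cols.append((cov["scanner"].astype(str) == s).to_numpy(float))
        names.append(f"scanner[{s}]")
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # drop scanner dummies that add no rank beyond the core covariates
        keep = [0, 1, 2, 3]
        for j in range(4, x.shape[1]):
            base_rank = np.linalg.matrix_rank(x[:, keep])
            if np.linalg.matrix_rank(x[:, keep + [j]]) > base_rank:
                keep.append(j)
            else:
                warnings.warn(f"dropping collinear covariate column {names[j]}")
        x = x[:, keep]

    # wide matrix of outcomes: one column per (region, hemisphere, measure)
    wide = table.pivot_table(index="subject_id", columns=["region", "hemisphere", "measure"],
                             values="value", aggfunc="first").loc[subjects]
    y = wide.to_numpy(float)
    complete = ~np.isnan(y).any(axis=1)
    beta, *_ = np.linalg.lstsq(x[complete], y[complete], rcond=None)
    fitted_at_mean = x[complete].mean(axis=0) @ beta
    adjusted = y - x @ beta + fitted_at_mean

    out = pd.DataFrame(adjusted, index=wide.index, columns=wide.columns).stack(
        ["region", "hemisphere", "measure"], future_stack=True).rename("value").reset_index()
    return out.dropna(subset=["value"])[MEASURE_COLUMNS]


def qc_outliers(table: pd.DataFrame, z_threshold: float = 4.7) -> pd.DataFrame:
    """Cohort-distribution outlier flags per (region, hemisphere, measure).

    z = (value − cohort mean)/cohort SD; cells with |z| ≥ threshold (in
    either direction, inclusive) are flagged for manual review and
    downstream exclusion.  The comparison carries a 1e-9 relative guard so
    values constructed to sit exactly on the threshold flag regardless of
    round-off.  Zero-SD cells yield no flags (with a warning).
    """
    _check_table(table)
    out = table.copy()
    grp = out.groupby(["region", "hemisphere", "measure"])["value"]
    mean = grp.transform("mean")
    sd = grp.transform(lambda v: v.std(ddof=1))
    zero = sd == 0
    if zero.any():
        warnings.warn("zero-variance cells encountered during QC; not flagged")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (out["value"] - mean) / sd
    out["z"] = z.where(~zero, 0.0)
    out["outlier"] = np.abs(out["z"]) >= z_threshold * (1.0 - 1e-9)
    return out


def compute_basi(left: float, right: float) -> float:
    """(left − right) / ((left + right)/2): unitless brain asymmetry index."""
    avg = (left + right) / 2.0
    if avg <= 0:
        raise DomainError(f"hemispheric average must be positive, got {avg}")
    return (left - right) / avg


def basi_table(adjusted: pd.DataFrame,
               manifest: list[tuple[str, str]] | None = None,
               qc_flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Subject × region BASI matrix from an adjusted long table.

    ``manifest`` lists the (region, measure) pairs to include (default:
    the packaged 51).  Cells missing a hemisphere, or QC-flagged in
    either hemisphere, are left NaN rather than imputed.  Summary
    columns ``basi_mean_thickness`` and ``basi_total_surface_area`` are
    added when the hemispheric summary measures are present.
    """
    _check_table(adjusted)
    manifest = DEFAULT_REGION_MANIFEST if manifest is None else manifest
    work = adjusted
    if qc_flags is not None:
        flagged = qc_flags.loc[qc_flags["outlier"],
                               ["subject_id", "region", "hemisphere", "measure"]]
        if len(flagged):
            merged = work.merge(flagged.assign(_drop=True), how="left",
                                on=["subject_id", "region", "hemisphere", "measure"])
            work = merged.loc[merged["_drop"].isna(), MEASURE_COLUMNS]

    wide = work.pivot_table(index="subject_id",
                            columns=["region", "measure", "hemisphere"],
                            values="value", aggfunc="first")
    subjects = wide.index
    out = pd.DataFrame(index=subjects)
    for region, measure in manifest + SUMMARY_MEASURES:
        name = {"mean_thickness": "basi_mean_thickness",
                "total_surface_area": "basi_total_surface_area"}.get(
            region, f"{region}_{measure}")
        try:
            left = wide[(region, measure, "left")]
            right = wide[(region, measure, "right")]
        except KeyError:
            if (region, measure) in SUMMARY_MEASURES:
                continue
            out[name] = np.nan
            continue
        avg = (left + right) / 2.0
        vals = (left - right) / avg
        vals[avg <= 0] = np.nan
        out[name] = vals
    out.index.name = "subject_id"
    return out


def duration_correlations(basi: pd.DataFrame, cohort: pd.DataFrame) -> dict[str, dict]:
    """Pearson r (and p) of illness duration vs the summary BASI columns.

    Subjects with missing duration are excluded listwise; requires ≥ 3
    subjects per correlation.
    """
    if "duration" not in cohort.columns:
        raise InputError("cohort table lacks a 'duration' column")
    dur = cohort.set_index("subject_id")["duration"].reindex(basi.index)
    results: dict[str, dict] = {}
    for col in ("basi_mean_thickness", "basi_total_surface_area"):
        if col not in basi.columns:
            continue
        ok = dur.notna() & basi[col].notna()
        if ok.sum() < 3:
            raise StatisticsError(f"fewer than 3 subjects with duration for {col}")
        d = dur[ok].to_numpy(float)
        b = basi.loc[ok, col].to_numpy(float)
        if np.std(d) == 0 or np.std(b) == 0:
            raise StatisticsError(f"constant series; correlation undefined for {col}")
        r, p = stats.pearsonr(d, b)
        results[col] = {"r": float(r), "p": float(p), "n": int(ok.sum())}
    return results
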