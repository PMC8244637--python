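"""Brain-measure contracts: adjustment, QC, BASI, duration correlations."""

import numpy as np
import pandas as pd
import pytest

from facesym.brain import (DEFAULT_REGION_MANIFEST, adjust_measures, basi_table,
                           compute_basi, duration_correlations, qc_outliers)
from facesym.errors import DomainError, InputError, StatisticsError
from facesym.simulate import BrainSimConfig, inject_outlier, simulate_brain


def _long_table(values, region="r", measure="thickness"):
    """values: dict subject → (left, right)."""
    rows = []
    for sid, (left, right) in values.items():
        rows.append({"subject_id": sid, "region": region, "hemisphere": "left",
                     "measure": measure, "value": left})
        rows.append({"subject_id": sid, "region": region, "hemisphere": "right",
                     "measure": measure, "value": right})
    return pd.DataFrame(rows)


def _covariates(subjects, icv=1.4e6, age=40.0, sex="F", scanner="s0"):
    def pick(v, i):
        return v[i] if isinstance(v, (list, np.ndarray)) else v

    return pd.DataFrame([{
        "subject_id": s, "icv": pick(icv, i), "age": pick(age, i),
        "sex": pick(sex, i), "scanner": pick(scanner, i),
    } for i, s in enumerate(subjects)])


# ---------------------------------------------------------------------------
# compute_basi


def test_basi_formula_and_antisymmetry():
    assert compute_basi(2.5, 2.5) == 0.0
    assert compute_basi(3.0, 1.0) == pytest.approx(1.0)
    a, b = 3.7, 2.1
    assert compute_basi(a, b) == pytest.approx(-compute_basi(b, a))
    with pytest.raises(DomainError):
        compute_basi(1.0, -1.0)


def test_basi_scale_invariant(rng):
    left, right = rng.uniform(1, 5, 20), rng.uniform(1, 5, 20)
    for l, r in zip(left, right):
        assert compute_basi(7.3 * l, 7.3 * r) == pytest.approx(
            compute_basi(l, r), rel=1e-12)


def test_basi_bounded_for_positive_measures(rng):
    for _ in range(50):
        v = rng.uniform(0.01, 100.0, 2)
        assert -2.0 < compute_basi(v[0], v[1]) < 2.0


# ---------------------------------------------------------------------------
# adjustment


def test_constant_covariates_leave_values_unchanged(rng):
    subjects = [f"s{i}" for i in range(12)]
    vals = {s: tuple(rng.uniform(2, 3, 2)) for s in subjects}
    table = _long_table(vals)
    adjusted = adjust_measures(table, _covariates(subjects))
    merged = table.merge(adjusted, on=["subject_id", "region", "hemisphere",
                                       "measure"], suffixes=("", "_adj"))
    np.testing.assert_allclose(merged["value_adj"], merged["value"], atol=1e-9)


def test_planted_age_effect_removed_exactly(rng):
    """Zero-noise linear age effect: the adjusted values have zero
    regression slope on age (exact least squares)."""
    subjects = [f"s{i}" for i in range(20)]
    age = np.linspace(20, 70, 20)
    base = 2.5
    vals = {s: (base + 0.01 * a, base + 0.01 * a) for s, a in zip(subjects, age)}
    table = _long_table(vals)
    adjusted = adjust_measures(table, _covariates(subjects, age=age))
    left = adjusted[adjusted["hemisphere"] == "left"].set_index("subject_id")
    y = left.loc[subjects, "value"].to_numpy()
    slope = np.polyfit(age, y, 1)[0]
    assert abs(slope) < 1e-10
    # re-centered at covariate means, so the overall level is preserved
    assert y.mean() == pytest.approx(base + 0.01 * age.mean(), abs=1e-9)


def test_scanner_offset_removed(rng):
    subjects = [f"s{i}" for i in range(40)]
    scanner = ["s0"] * 20 + ["s1"] * 20
    offset = np.where(np.arange(40) < 20, 0.0, 0.4)
    vals = {s: (2.5 + o + rng.normal(scale=0.01),
                2.5 + o + rng.normal(scale=0.01))
            for s, o in zip(subjects, offset)}
    table = _long_table(vals)
    adjusted = adjust_measures(table, _covariates(subjects, scanner=scanner))
    left = adjusted[adjusted["hemisphere"] == "left"].set_index("subject_id")
    y = left.loc[subjects, "value"].to_numpy()
    gap = abs(y[:20].mean() - y[20:].mean())
    assert gap < 0.02  # raw gap was 0.4


def test_missing_covariates_rejected(rng):
    table = _long_table({"s0": (2.0, 2.0), "s1": (2.1, 2.1)})
    with pytest.raises(InputError, match="covariates"):
        adjust_measures(table, _covariates(["s0"]))
    with pytest.raises(InputError, match="columns"):
        adjust_measures(table, pd.DataFrame({"subject_id": ["s0", "s1"]}))


# ---------------------------------------------------------------------------
# QC


def _clean_table(rng, n=40):
    subjects = [f"s{i}" for i in range(n)]
    vals = {s: tuple(2.5 + rng.normal(scale=0.1, size=2)) for s in subjects}
    return _long_table(vals)


def test_qc_threshold_boundary_inclusive(rng):
    table = _clean_table(rng)
    at = inject_outlier(table, "s0", "r", "left", "thickness", z=4.7)
    flags = qc_outliers(at)
    assert flags.loc[(flags["subject_id"] == "s0")
                     & (flags["hemisphere"] == "left"), "outlier"].item()

    below = inject_outlier(table, "s0", "r", "left", "thickness", z=4.69)
    flags = qc_outliers(below)
    assert not flags["outlier"].any()

    neg = inject_outlier(table, "s0", "r", "left", "thickness", z=-4.7)
    flags = qc_outliers(neg)
    assert flags.loc[(flags["subject_id"] == "s0")
                     & (flags["hemisphere"] == "left"), "outlier"].item()


def test_qc_flag_at_z_five(rng):
    table = _clean_table(rng)
    bad = inject_outlier(table, "s3", "r", "right", "thickness", z=5.0)
    flags = qc_outliers(bad)
    hit = flags.loc[flags["outlier"]]
    assert len(hit) == 1
    assert hit.iloc[0]["subject_id"] == "s3"
    assert hit.iloc[0]["hemisphere"] == "right"


def test_qc_zero_variance_warns_and_skips():
    table = _long_table({f"s{i}": (2.5, 2.5) for i in range(12)})
    with pytest.warns(UserWarning, match="zero-variance"):
        flags = qc_outliers(table)
    assert not flags["outlier"].any()


def test_qc_invariant_to_affine_rescaling(rng):
    table = _clean_table(rng)
    bad = inject_outlier(table, "s5", "r", "left", "thickness", z=5.2)
    f1 = qc_outliers(bad)["outlier"].to_numpy()
    scaled = bad.copy()
    scaled["value"] = 3.0 * scaled["value"] + 10.0
    f2 = qc_outliers(scaled)["outlier"].to_numpy()
    np.testing.assert_array_equal(f1, f2)


# ---------------------------------------------------------------------------
# BASI tables


def test_symmetric_brain_gives_zero_basi(rng):
    rows = []
    for region, measure in DEFAULT_REGION_MANIFEST:
        v = float(rng.uniform(2, 4))
        for sid in ("s0", "s1"):
            for hemi in ("left", "right"):
                rows.append({"subject_id": sid, "region": region,
                             "hemisphere": hemi, "measure": measure, "value": v})
    table = basi_table(pd.DataFrame(rows))
    assert table.shape == (2, 51)
    np.testing.assert_array_equal(table.to_numpy(), 0.0)


def test_uniform_two_percent_left_excess(rng):
    rows = []
    for region, measure in DEFAULT_REGION_MANIFEST:
        v = float(rng.uniform(2, 4))
        rows.append({"subject_id": "s0", "region": region, "hemisphere": "left",
                     "measure": measure, "value": 1.02 * v})
        rows.append({"subject_id": "s0", "region": region, "hemisphere": "right",
                     "measure": measure, "value": v})
    table = basi_table(pd.DataFrame(rows))
    np.testing.assert_allclose(table.to_numpy(), 0.02 / 1.01, rtol=1e-12)


def test_missing_hemisphere_left_nan():
    df = _long_table({"s0": (2.0, 2.1)}, region="cuneus")
    df = df[df["hemisphere"] == "left"]
    table = basi_table(df, manifest=[("cuneus", "thickness")])
    assert np.isnan(table.loc["s0", "cuneus_thickness"])


def test_qc_flagged_cells_excluded(rng):
    table = _clean_table(rng)
    bad = inject_outlier(table, "s1", "r", "left", "thickness", z=5.0)
    flags = qc_outliers(bad)
    basi = basi_table(bad, manifest=[("r", "thickness")], qc_flags=flags)
    assert np.isnan(basi.loc["s1", "r_thickness"])
    assert basi["r_thickness"].notna().sum() == len(basi) - 1


def test_summary_columns_present_when_summary_measures_exist(rng):
    cfg = BrainSimConfig(seed=1)
    sai = rng.normal(5.0, 0.3, 30)
    measures, covariates, _ = simulate_brain(cfg, sai)
    adjusted = adjust_measures(measures, covariates)
    table = basi_table(adjusted)
    assert "basi_mean_thickness" in table.columns
    assert "basi_total_surface_area" in table.columns
    assert table.shape[1] == 53


# ---------------------------------------------------------------------------
# duration correlations


def test_planted_duration_correlation_recovered(rng):
    cfg = BrainSimConfig(seed=2, duration_thickness_r=-0.5)
    n = 200
    sai = rng.normal(5.0, 0.3, n)
    cohort = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "age": rng.uniform(20, 70, n),
        "gender": rng.choice(["F", "M"], n),
        "duration": rng.uniform(1, 40, n),
    })
    measures, covariates, _ = simulate_brain(cfg, sai, cohort=cohort)
    table = basi_table(adjust_measures(measures, covariates))
    res = duration_correlations(table, cohort)
    r = res["basi_mean_thickness"]["r"]
    # sampling SE of r at n=200 ≈ 0.05; allow ±3 SE around the planted −0.5
    assert abs(r - (-0.5)) < 0.16
    assert res["basi_mean_thickness"]["n"] == n


def test_constant_duration_rejected(rng):
    cfg = BrainSimConfig(seed=3)
    n = 30
    sai = rng.normal(5.0, 0.3, n)
    cohort = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "age": rng.uniform(20, 70, n),
        "gender": ["F"] * n,
        "duration": [10.0] * n,
    })
    measures, covariates, _ = simulate_brain(cfg, sai, cohort=cohort)
    table = basi_table(adjust_measures(measures, covariates))
    with pytest.raises(StatisticsError, match="constant"):
        duration_correlations(table, cohort)


def test_missing_duration_column_rejected(rng):
    with pytest.raises(InputError, match="duration"):
        duration_correlations(pd.DataFrame(index=["s0"]),
                              pd.DataFrame({"subject_id": ["s0"]}))
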