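"""Brain asymmetry indices (BASI) and the repeated-LASSO protocol.

Simulates regional brain measures for the epilepsy cases of a face
cohort (with the default planted duration → thickness-asymmetry
correlation of −0.19), adjusts them for ICV/age/sex/scanner, screens
outliers at |z| ≥ 4.7, builds the 51-region BASI matrix, and runs the
repeated cross-validated LASSO predicting facial asymmetry (SAI) from
the BASI features.
"""

from facesym.brain import (adjust_measures, basi_table,
                           duration_correlations, qc_outliers)
from facesym.lasso import normalize_features, run_protocol, \
    selection_frequencies
from facesym.pipeline import sai_table
from facesym.simulate import (BrainSimConfig, FaceSimConfig, simulate_brain,
                              simulate_faces)

cfg = FaceSimConfig(n_per_group={"CTRL": 40, "FS": 30, "FC": 20, "IGE": 10},
                    seed=3)
sim = simulate_faces(cfg)
sai, _ = sai_table(sim.orig_points, sim.mirr_points, sim.cohort, min_n=10)
cases = sim.cohort["group"] != "CTRL"

bcfg = BrainSimConfig(seed=3)  # duration_thickness_r defaults to -0.19
measures, covariates, linked = simulate_brain(
    bcfg, sai.loc[cases.to_numpy(), "sai"].to_numpy(),
    cohort=sim.cohort.loc[cases])
print(f"{measures['subject_id'].nunique()} cases, "
      f"{len(measures)} measure rows, linked features: {linked or 'none'}")

adjusted = adjust_measures(measures, covariates)
qc = qc_outliers(adjusted)
print(f"QC at |z| >= 4.7: {int(qc['outlier'].sum())} flagged cells")

basi = basi_table(adjusted, qc_flags=qc)
print(f"BASI matrix: {basi.shape[0]} subjects x {basi.shape[1]} columns "
      f"(51 regions + 2 hemispheric summaries)")

dur = duration_correlations(basi, sim.cohort.loc[cases])
r = dur["basi_mean_thickness"]
print(f"duration vs mean-thickness BASI: r={r['r']:+.3f} "
      f"(p={r['p']:.3f}, n={r['n']}) — planted r = -0.19\n")

feature_cols = [c for c in basi.columns
                if c not in ("basi_mean_thickness", "basi_total_surface_area")]
x = basi[feature_cols].dropna()
y = sai.set_index("subject_id").loc[x.index, "sai"].to_numpy(float)
result = run_protocol(normalize_features(x), y, n_rep=200, seed=17)
print(f"repeated LASSO (200 reps, 80/20 splits, 10-fold CV, alpha 2^-16..2^-4):")
print(f"  mean test Spearman rho {result.mean_rho:+.3f}, "
      f"mean MSE {result.mean_mse:.4f}")
print(f"  intercept-only repetitions: {result.n_intercept_only}/200")
print("  top-5 selection frequencies (%):")
print(selection_frequencies(result).head(5).round(1).to_string())
print("\nNo BASI→SAI link is planted by default: at n=60 the protocol "
      "mostly chases\ndataset-level chance correlations, so the mean held-out "
      "rho is small and the\nselection frequencies are unstable between seeds.")
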