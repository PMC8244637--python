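"""Detect which shape-model modes encode asymmetry.

A mode that captures a common facial asymmetry correlates strongly and
*negatively* between the scores of original faces and of their mirrored
forms: reflecting the face flips the sign of its asymmetric component.
Symmetric shape modes correlate strongly positively.  The league table
sorts modes by that correlation and flags entries below −0.9.
"""

from facesym.asymmetry import asymmetry_pcs, pc_asymmetry_measures
from facesym.correspondence import CorrespondedSurface
from facesym.dsm import project
from facesym.pipeline import fit_cohort_dsm
from facesym.simulate import FaceSimConfig, simulate_faces

cfg = FaceSimConfig(
    n_per_group={"CTRL": 50, "FS": 0, "FC": 0, "IGE": 0},
    sym_mode_sds=(2.0, 1.5, 1.0),   # three planted symmetric modes (mm)
    asym_mode_sds=(0.5, 0.3),       # two planted antisymmetric modes (mm)
    noise_sd=0.1,
    seed=21,
)
sim = simulate_faces(cfg)
ids = sim.cohort["subject_id"].astype(str).tolist()
model = fit_cohort_dsm(sim.orig_points, sim.mirr_points, ids)
print(f"{len(ids)} faces; retained {model.retained} modes "
      f"(3 symmetric + 2 antisymmetric planted)\n")

scores = []
for sid, orig, mirr in zip(ids, sim.orig_points, sim.mirr_points):
    scores.append(project(model, CorrespondedSurface(sid, False, orig)))
    scores.append(project(model, CorrespondedSurface(sid, True, mirr)))

print("league table: original-vs-reflected score correlation per mode")
print(f"{'mode':>4} {'r(orig, reflected)':>20} {'% variance':>11} {'flagged':>8}")
for e in asymmetry_pcs(model, scores, threshold=-0.9):
    print(f"{e.pc_index:>4} {e.orig_reflected_correlation:>+20.6f} "
          f"{100 * e.variance_fraction:>10.1f}% {str(e.flagged):>8}")

print("\nThe two flagged modes are exactly the planted antisymmetric fields;")
print("the symmetric modes sit near +1 (capture noise keeps them off ±1).\n")

print("anthropometric lateral asymmetry (R − L)/(R + L) on the template:")
for kind in ("nose_deflection", "eye_depth"):
    left, right, asym = pc_asymmetry_measures(sim.template.landmarks, kind)
    print(f"  {kind:<16s} L={left:7.2f} mm  R={right:7.2f} mm  "
          f"asym={asym:+.5f}  (template is exactly symmetric)")
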