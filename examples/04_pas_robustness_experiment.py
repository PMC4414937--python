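"""The full synthetic experiment: why half contours help under shadowing.

Runs two seeded cohorts end to end (generation -> segmentation -> features
-> ROC evaluation): 25 benign + 25 malignant cases all carrying a posterior
acoustic shadow, and a 5+5 cohort without shadowing.  Prints the per-feature
report rows for tumor circularity (TC) and the standard deviation of degree
(SDD).
"""

from halfcontour import PipelineConfig, run_experiment

print("=== shadowed cohort (n=50, attenuation 0.4) ===")
cfg = PipelineConfig(
    n_benign=25, n_malignant=25, pas_fraction=1.0, pas_attenuation=0.4,
    master_seed=1,
)
report = run_experiment(cfg).report
cols = ["feature", "mode", "accuracy_pct", "sensitivity_pct", "specificity_pct", "auc", "p"]
sel = report[report["feature"].isin(["tc", "sdd"])][cols]
print(sel.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

print("\n=== clean cohort (n=10, no shadow) ===")
cfg10 = PipelineConfig(n_benign=5, n_malignant=5, pas_fraction=0.0, master_seed=1)
report10 = run_experiment(cfg10).report
sel10 = report10[report10["feature"].isin(["tc", "sdd"])][cols]
print(sel10.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

# In the shadowed cohort the full-contour TC collapses toward chance (the
# merged shadow region swamps the lesion's shape signal) while half-contour
# TC stays strongly discriminative: the upper half of the boundary is
# unaffected by the shadow.  Without shadowing, full and half contours
# perform comparably.
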