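"""Compute the six contour-shape parameters in full- and half-contour mode.

Compares a smooth (benign-like) and a spiculated (malignant-like) lesion:
every irregularity measure — circularity TC, radial-length spread NRL_STD,
area ratio AR, roughness RI and the angle dispersion SDD — is larger for the
spiculated shape.
"""

from halfcontour import ShapeSpec, feature_vector, make_shape_mask
from halfcontour.segmentation import TumorRegion, trace_contour

shapes = {
    "smooth": ShapeSpec(base_radius_px=40.0, center=(128.0, 128.0)),
    "spiculated": ShapeSpec(
        base_radius_px=40.0,
        spiculation_amplitude=0.3,
        spiculation_lobes=12,
        center=(128.0, 128.0),
        rng_seed=7,
    ),
}

header = f"{'shape':<11}{'mode':<6}{'TC':>7}{'NRL_M':>7}{'NRL_STD':>9}{'AR':>7}{'RI':>8}{'SDD':>7}"
print(header)
for name, spec in shapes.items():
    mask = make_shape_mask(spec, (256, 256))
    contour = trace_contour(TumorRegion(mask=mask, seed=(128, 128)))
    for mode in ("full", "half"):
        fv = feature_vector(contour, mode=mode, k=5)
        print(
            f"{name:<11}{mode:<6}{fv.tc:7.1f}{fv.nrl_m:7.2f}{fv.nrl_std:9.3f}"
            f"{fv.ar:7.3f}{fv.ri:8.4f}{fv.sdd:7.1f}"
        )

# TC is minimized by a disk (continuum limit 4*pi ~ 12.6); the spiculated
# shape roughly triples it.  SDD, the angle-dispersion statistic, separates
# the two shapes by tens of degrees in both contour modes.
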