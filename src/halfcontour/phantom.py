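"""Synthetic B-mode breast-ultrasound phantoms.

Real breast ultrasound shows a speckled background with a hypoechoic (dark)
lesion; strongly attenuating masses additionally cast a posterior acoustic
shadow (PAS) — a dark stripe extending below the mass that corrupts the lower
lesion boundary.  This module renders such images with known ground truth so
that segmentation and contour-feature code can be exercised end to end:

* lesion geometry is a star-shaped polar curve whose single "malignancy" knob
  is the spiculation amplitude (benign masses are smooth, malignant masses
  spiculated);
* echogenicity is a two-level mean field (lesion darker than background)
  modulated by unit-mean multiplicative speckle;
* PAS multiplies every pixel below the lesion, in the central fraction of its
  lateral span, by an attenuation factor with per-row exponential decay.

All outputs are pure functions of their specs and seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import polygon

__all__ = [
    "ShapeSpec",
    "EchoSpec",
    "PasSpec",
    "Phantom",
    "make_shape_mask",
    "render_phantom",
    "apply_pas",
    "generate_cohort",
    "save_phantom",
]

# angular samples used to rasterize the polar boundary
_N_VERTICES = 720


@dataclass(frozen=True)
class ShapeSpec:
    """Lesion geometry: an ellipse with sinusoidal radial undulations.

    ``base_radius_px`` is the geometric-mean semi-axis; ``aspect_ratio`` is
    width/height of the ellipse; ``spiculation_amplitude`` (``a``) scales the
    radial undulation as a fraction of the local radius and must stay below 1
    so the radius remains positive; ``spiculation_lobes`` is the dominant
    angular frequency of the undulation.  ``center`` is (x, y) in pixels with
    x = column (lateral) and y = row (depth, increasing downward).
    """

    base_radius_px: float = 36.0
    aspect_ratio: float = 1.0
    spiculation_amplitude: float = 0.0
    spiculation_lobes: int = 8
    center: tuple[float, float] = (128.0, 128.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius_px <= 0:
            raise ValueError("base_radius_px must be positive")
        if self.aspect_ratio <= 0:
            raise ValueError("aspect_ratio must be positive")
        if not 0.0 <= self.spiculation_amplitude < 1.0:
            raise ValueError("spiculation_amplitude must be in [0, 1)")
        if self.spiculation_lobes < 0:
            raise ValueError("spiculation_lobes must be >= 0")


@dataclass(frozen=True)
class EchoSpec:
    """B-mode intensity model: hypoechoic lesion, speckled background.

    ``speckle_scale`` is the standard deviation of the unit-mean multiplicative
    speckle field (0 disables noise).  Intensities are floats on the 8-bit
    range by convention and are clipped into ``intensity_range`` after noise.

    ``texture_strength`` adds a smooth unit-mean multiplicative macro-texture
    whose amplitude ramps linearly with depth, emulating the increasing
    heterogeneity of deep tissue (imperfect gain compensation, reverberation,
    chest-wall structure); 0 (the default) renders a homogeneous background.
    ``texture_scale_px`` is its correlation length.
    """

    background_mean: float = 180.0
    lesion_mean: float = 50.0
    speckle_scale: float = 0.3
    intensity_range: tuple[float, float] = (0.0, 255.0)
    texture_strength: float = 0.0
    texture_scale_px: float = 20.0

    def __post_init__(self) -> None:
        if self.lesion_mean >= self.background_mean:
            raise ValueError("lesion_mean must be below background_mean (hypoechoic)")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be >= 0")
        if self.texture_strength < 0:
            raise ValueError("texture_strength must be >= 0")
        if self.texture_scale_px <= 0:
            raise ValueError("texture_scale_px must be positive")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValueError("intensity_range must be (lo, hi) with lo < hi")


@dataclass(frozen=True)
class PasSpec:
    """Posterior acoustic shadow: attenuation below the mass.

    Pixels strictly below the lesion's lowest boundary row, in the central
    ``lateral_coverage`` fraction of the lesion's column span, are multiplied
    by ``attenuation_factor * depth_decay**rows_below``.
    """

    attenuation_factor: float = 0.4
    lateral_coverage: float = 0.7
    depth_decay: float = 0.995

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation_factor <= 1.0:
            raise ValueError("attenuation_factor must be in [0, 1]")
        if not 0.0 < self.lateral_coverage <= 1.0:
            raise ValueError("lateral_coverage must be in (0, 1]")
        if not 0.0 < self.depth_decay <= 1.0:
            raise ValueError("depth_decay must be in (0, 1]")


@dataclass
class Phantom:
    """One synthetic case: image, ground-truth lesion mask, and provenance."""

    image: np.ndarray
    truth_mask: np.ndarray
    label: str  # "benign" | "malignant"
    has_pas: bool
    shape_spec: ShapeSpec
    echo_spec: EchoSpec
    pas_spec: PasSpec | None = None
    case_id: str = ""


def _undulation(phi: np.ndarray, lobes: int, rng: np.random.Generator) -> np.ndarray:
    """Normalized radial undulation: a few sinusoids with random phases.

    Returns values in [-1, 1] so that ``1 + a * u`` stays positive for a < 1.
    """
    if lobes == 0:
        return np.zeros_like(phi)
    freqs = [lobes]
    weights = [1.0]
    if lobes >= 4:
        freqs.append(max(2, lobes // 2))
        weights.append(0.4)
    u = np.zeros_like(phi)
    for f, w in zip(freqs, weights):
        u += w * np.sin(f * phi + rng.uniform(0.0, 2.0 * np.pi))
    return u / sum(weights)


def make_shape_mask(spec: ShapeSpec, image_size: tuple[int, int]) -> np.ndarray:
    """Rasterize the lesion boundary r(phi) = R * s(phi) * (1 + a*u(phi)).

    Parameters
    ----------
    spec
        Lesion geometry.
    image_size
        (rows, cols) of the output mask.

    Returns
    -------
    uint8 array of shape ``image_size`` with lesion pixels set to 1.
    """
    rows, cols = image_size
    rng = np.random.default_rng(spec.rng_seed)
    phi = np.linspace(0.0, 2.0 * np.pi, _N_VERTICES, endpoint=False)
    u = _undulation(phi, spec.spiculation_lobes, rng)
    radial = 1.0 + spec.spiculation_amplitude * u
    # area-preserving ellipse axes: rx/ry = aspect_ratio, sqrt(rx*ry) = R
    rx = spec.base_radius_px * np.sqrt(spec.aspect_ratio)
    ry = spec.base_radius_px / np.sqrt(spec.aspect_ratio)
    cx, cy = spec.center
    xs = cx + rx * radial * np.cos(phi)
    ys = cy + ry * radial * np.sin(phi)
    if xs.min() < 0 or ys.min() < 0 or xs.max() > cols - 1 or ys.max() > rows - 1:
        raise ValueError("lesion exceeds image bounds; enlarge image or shrink lesion")
    mask = np.zeros((rows, cols), dtype=np.uint8)
    rr, cc = polygon(ys, xs, shape=(rows, cols))
    mask[rr, cc] = 1
    return mask


def render_phantom(
    mask: np.ndarray, echo: EchoSpec = EchoSpec(), rng_seed: int = 0
) -> np.ndarray:
    """Render a speckled image from a lesion mask.

    The mean field is ``background_mean`` outside the mask and ``lesion_mean``
    inside; a unit-mean gamma-distributed multiplicative field with standard
    deviation ``speckle_scale`` models speckle (0 gives the noise-free
    two-level image).  With ``texture_strength > 0`` a smooth multiplicative
    macro-texture whose amplitude grows linearly with depth is applied first.
    Output is float64 clipped into ``intensity_range``.
    """
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    field_img = np.where(mask.astype(bool), echo.lesion_mean, echo.background_mean)
    field_img = field_img.astype(np.float64)
    rng = np.random.default_rng(rng_seed)
    rows = mask.shape[0]
    if echo.texture_strength > 0:
        from scipy import ndimage as ndi

        raw = rng.standard_normal(mask.shape)
        smooth = ndi.gaussian_filter(raw, sigma=echo.texture_scale_px / 2.0)
        smooth /= smooth.std() or 1.0
        depth_ramp = (np.arange(rows, dtype=np.float64) / rows)[:, np.newaxis]
        texture = 1.0 + echo.texture_strength * depth_ramp * smooth
        field_img = field_img * np.maximum(texture, 0.0)
    s = echo.speckle_scale
    if s > 0:
        # gamma(shape=1/s^2, scale=s^2): mean 1, std s
        noise = rng.gamma(shape=1.0 / s**2, scale=s**2, size=mask.shape)
        field_img = field_img * noise
    lo, hi = echo.intensity_range
    return np.clip(field_img, lo, hi)


def apply_pas(image: np.ndarray, mask: np.ndarray, pas: PasSpec) -> np.ndarray:
    """Cast a posterior acoustic shadow below the lesion.

    For each shadowed column (the central ``lateral_coverage`` fraction of the
    lesion's column span), every pixel strictly below the lesion's lowest row
    in that column is multiplied by
    ``attenuation_factor * depth_decay**rows_below``.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    out = np.asarray(image, dtype=np.float64).copy()
    rows = out.shape[0]
    cols_with_lesion = np.flatnonzero(mask.any(axis=0))
    cmin, cmax = cols_with_lesion[0], cols_with_lesion[-1]
    center = 0.5 * (cmin + cmax)
    half_span = 0.5 * pas.lateral_coverage * (cmax - cmin + 1)
    for col in cols_with_lesion:
        if abs(col - center) > half_span:
            continue
        bottom = np.flatnonzero(mask[:, col])[-1]
        depth = np.arange(1, rows - bottom)
        if depth.size == 0:
            continue
        factors = pas.attenuation_factor * pas.depth_decay ** depth.astype(np.float64)
        out[bottom + 1 :, col] *= factors
    return out


# Study-condition parameter ranges for the synthetic cohort.  Lesions are
# superficial (upper third of a deep B-mode field) so a shadow has a long
# path below them, as in clinical breast scans; lesion size, elongation and
# position vary across cases, and the shadow's lateral coverage and decay
# vary from case to case, which makes its merge with the dark lesion region
# ragged and case-dependent — the clinically observed behaviour.
_RADIUS_RANGE = (28.0, 44.0)
_ASPECT_RANGE = (1.0, 1.3)
_LATERAL_JITTER = 15.0
_DEPTH_RANGE = (0.2, 0.5)  # lesion center depth, fraction of image rows
_BENIGN_AMPLITUDE = (0.02, 0.10)
_MALIGNANT_AMPLITUDE = (0.16, 0.30)
_BENIGN_LOBES = (5, 10)
_MALIGNANT_LOBES = (8, 14)
_PAS_COVERAGE = (0.2, 0.9)
_SPECKLE_RANGE = (0.2, 0.35)  # per-case speckle std (gain/patient variability)
_PAS_DECAY = (0.997, 0.9995)
_COHORT_TEXTURE = 0.0  # depth-ramped macro-texture amplitude at full depth


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    pas_fraction: float,
    master_seed: int,
    image_size: tuple[int, int] = (400, 256),
    echo: EchoSpec | None = None,
    pas_attenuation: float = 0.4,
) -> list[Phantom]:
    """Generate a labeled cohort of phantoms, deterministic in ``master_seed``.

    Benign cases use low spiculation amplitude, malignant high; exactly
    ``round(pas_fraction * n)`` phantoms (chosen by a seeded shuffle across
    both classes) carry a posterior shadow of the given attenuation.  When
    ``echo`` is not given, each case draws its own speckle level from the
    study range (scan gain and patient-dependent noise vary between
    acquisitions).
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("case counts must be >= 0")
    per_case_speckle = echo is None
    if echo is None:
        echo = EchoSpec(texture_strength=_COHORT_TEXTURE)
    if not 0.0 <= pas_fraction <= 1.0:
        raise ValueError("pas_fraction must be in [0, 1]")
    rng = np.random.default_rng(master_seed)
    n = n_benign + n_malignant
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    n_pas = int(round(pas_fraction * n))
    pas_cases = set(rng.permutation(n)[:n_pas].tolist())
    rows, cols = image_size
    phantoms: list[Phantom] = []
    for i, label in enumerate(labels):
        if label == "benign":
            amp = rng.uniform(*_BENIGN_AMPLITUDE)
            lobes = int(rng.integers(_BENIGN_LOBES[0], _BENIGN_LOBES[1] + 1))
        else:
            amp = rng.uniform(*_MALIGNANT_AMPLITUDE)
            lobes = int(rng.integers(_MALIGNANT_LOBES[0], _MALIGNANT_LOBES[1] + 1))
        shape = ShapeSpec(
            base_radius_px=rng.uniform(*_RADIUS_RANGE),
            aspect_ratio=rng.uniform(*_ASPECT_RANGE),
            spiculation_amplitude=amp,
            spiculation_lobes=lobes,
            center=(
                cols / 2.0 + rng.uniform(-_LATERAL_JITTER, _LATERAL_JITTER),
                rows * rng.uniform(*_DEPTH_RANGE),
            ),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        mask = make_shape_mask(shape, image_size)
        case_echo = echo
        if per_case_speckle:
            case_echo = dataclasses.replace(
                echo, speckle_scale=rng.uniform(*_SPECKLE_RANGE)
            )
        image = render_phantom(mask, case_echo, rng_seed=int(rng.integers(0, 2**31 - 1)))
        has_pas = i in pas_cases
        pas_spec = None
        if has_pas:
            pas_spec = PasSpec(
                attenuation_factor=pas_attenuation,
                lateral_coverage=rng.uniform(*_PAS_COVERAGE),
                depth_decay=rng.uniform(*_PAS_DECAY),
            )
            image = apply_pas(image, mask, pas_spec)
        phantoms.append(
            Phantom(
                image=image,
                truth_mask=mask,
                label=label,
                has_pas=has_pas,
                shape_spec=shape,
                echo_spec=case_echo,
                pas_spec=pas_spec,
                case_id=f"case{i:03d}_{label}",
            )
        )
    return phantoms


def save_phantom(phantom: Phantom, out_dir: str | Path) -> Path:
    """Write image + truth mask as PNG with a JSON sidecar of the specs."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = phantom.case_id or "phantom"
    img8 = np.clip(np.rint(phantom.image), 0, 255).astype(np.uint8)
    iio.imwrite(out_dir / f"{stem}.png", img8)
    iio.imwrite(out_dir / f"{stem}_mask.png", phantom.truth_mask * np.uint8(255))
    sidecar = {
        "case_id": phantom.case_id,
        "label": phantom.label,
        "has_pas": phantom.has_pas,
        "shape_spec": dataclasses.asdict(phantom.shape_spec),
        "echo_spec": dataclasses.asdict(phantom.echo_spec),
        "pas_spec": dataclasses.asdict(phantom.pas_spec) if phantom.pas_spec else None,
    }
    with open(out_dir / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return out_dir / f"{stem}.png"
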