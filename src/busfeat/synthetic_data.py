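"""Synthetic ultrasound-like phantoms with benign/malignant lesions.

Each phantom is a speckle-textured grayscale image containing one
hypoechoic (darker-than-background) lesion with an exactly known mask.
The lesion boundary is a star-convex radial function

    r(phi) = r0 * (1 + sum_k a_k * cos(k * phi + psi_k))

whose harmonic content is class-dependent: benign-like lesions use a few
low-order harmonics with small amplitudes (smooth, near-elliptical
outlines), malignant-like lesions use many higher-order harmonics with
larger amplitudes (irregular, spiculated outlines).  Speckle is modeled
as the squared magnitude of a smoothed complex Gaussian field — the
standard Rayleigh-family surrogate for the multiplicative granular
texture of coherent ultrasound — applied multiplicatively to the
echogenicity map.

The generator emulates B-mode appearance at desk scale only; it makes
no claim of acoustic realism (no attenuation, posterior shadowing, or
beam-geometry effects).  Masks are guaranteed star-convex, single
connected components fully inside the image.  All randomness flows from
one seeded generator, so a (config, seed) pair is bit-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .io_roi import AnnotatedImage

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom study conditions.

    Defaults: 160x160 px images, lesion radius 18-30 px, benign
    harmonics k <= 4 with relative amplitude 0.04, malignant harmonics
    2 <= k <= 12 with amplitude 0.18, lesion 45% darker than
    background, speckle correlation length 1.5 px.
    """

    image_size: tuple[int, int] = (160, 160)
    n_benign: int = 100
    n_malignant: int = 100
    radius_range: tuple[float, float] = (18.0, 30.0)
    benign_harmonics: tuple[int, int] = (2, 4)  # inclusive k range
    malignant_harmonics: tuple[int, int] = (2, 12)
    benign_amplitude: float = 0.04
    malignant_amplitude: float = 0.18
    lesion_contrast: float = 0.45  # fractional echogenicity drop inside the lesion
    background_level: float = 160.0  # mean background intensity (8-bit scale)
    speckle_sigma: float = 1.5  # smoothing of the complex field, px
    axis_ratio_range: tuple[float, float] = (1.0, 1.6)  # baseline ellipse elongation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("class counts must be >= 1")
        if not self.benign_amplitude < self.malignant_amplitude:
            raise ValueError("benign irregularity amplitude must be < malignant")
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ValueError("invalid radius range")


def _radial_boundary(
    rng: np.random.Generator, cls: str, config: PhantomConfig
) -> tuple[float, np.ndarray, np.ndarray, float, float]:
    """Draw (r0, harmonic amplitudes, phases, axis ratio, orientation)."""
    r0 = rng.uniform(*config.radius_range)
    if cls == "benign":
        k_lo, k_hi = config.benign_harmonics
        amp = config.benign_amplitude
    else:
        k_lo, k_hi = config.malignant_harmonics
        amp = config.malignant_amplitude
    ks = np.arange(k_lo, k_hi + 1)
    # amplitudes drawn per harmonic, scaled so the expected total stays ~amp
    a = rng.uniform(0.3, 1.0, size=len(ks)) * amp / np.sqrt(len(ks))
    psi = rng.uniform(0, 2 * np.pi, size=len(ks))
    ratio = rng.uniform(*config.axis_ratio_range)
    theta0 = rng.uniform(0, np.pi)
    return r0, np.column_stack([ks, a, psi]), ratio, theta0


def _lesion_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    r0: float,
    harmonics: np.ndarray,
    ratio: float,
    theta0: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    # elongate along a random axis: stretch coordinates before the radial test
    u = dc * np.cos(theta0) + dr * np.sin(theta0)
    v = -dc * np.sin(theta0) + dr * np.cos(theta0)
    u = u / ratio
    dist = np.sqrt(u**2 + v**2)
    phi = np.arctan2(v, u)
    r_phi = r0 * (
        1.0
        + sum(a * np.cos(k * phi + psi) for k, a, psi in harmonics)
    )
    return dist <= r_phi


def _speckle(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-mean speckle field: squared magnitude of a smoothed complex Gaussian."""
    re = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    im = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    intensity = re**2 + im**2
    return intensity / intensity.mean()


def generate_phantom(config: PhantomConfig, cls: str, seed: int) -> AnnotatedImage:
    """One phantom of class ``cls`` ('benign' | 'malignant'), reproducible from seed."""
    if cls not in ("benign", "malignant"):
        raise ValueError(f"class must be 'benign' or 'malignant', got {cls!r}")
    rng = np.random.default_rng(seed)
    h, w = config.image_size
    r0, harmonics, ratio, theta0 = _radial_boundary(rng, cls, config)
    max_r = r0 * ratio * (1.0 + harmonics[:, 1].sum())
    if 2 * max_r >= min(h, w) - 4:
        raise ValueError(
            f"lesion (max radius {max_r:.1f}) exceeds image bounds {config.image_size}"
        )
    margin = max_r + 2.0
    center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
    mask = _lesion_mask((h, w), center, r0, harmonics, ratio, theta0)
    echogenicity = np.where(mask, 1.0 - config.lesion_contrast, 1.0)
    pixels = config.background_level * echogenicity * _speckle(rng, (h, w), config.speckle_sigma)
    pixels = np.clip(pixels, 0.0, 255.0)
    return AnnotatedImage(pixels=pixels, mask=mask, label=cls, id=f"{cls}_{seed}")


def generate_phantoms(config: PhantomConfig) -> list[AnnotatedImage]:
    """The full in-memory dataset for ``config`` (benign first, then malignant)."""
    root = np.random.default_rng(config.seed)
    # child seeds below 2^31 so they stay portable across integer conventions
    seeds = root.integers(0, 2**31 - 1, size=config.n_benign + config.n_malignant)
    out = []
    for i in range(config.n_benign):
        out.append(generate_phantom(config, "benign", int(seeds[i])))
    for i in range(config.n_malignant):
        out.append(generate_phantom(config, "malignant", int(seeds[config.n_benign + i])))
    for j, img in enumerate(out):
        img.id = f"phantom_{j:04d}_{img.label}"
    return out


def generate_dataset(
    config: PhantomConfig,
    out_dir: str | Path,
    split: float | None = None,
) -> dict[str, Path]:
    """Write phantoms as PNG image/mask pairs plus a manifest CSV.

    With ``split`` in (0, 1), additionally writes disjoint stratified
    ``manifest_train.csv`` / ``manifest_test.csv`` covering all ids
    (train fraction = ``split``), emulating a two-dataset
    train-on-A/test-on-B protocol.  Returns the manifest paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = generate_phantoms(config)
    rows = []
    for img in images:
        img_name, mask_name = f"{img.id}.png", f"{img.id}_mask.png"
        Image.fromarray(img.pixels.astype(np.uint8)).save(out_dir / img_name)
        Image.fromarray((img.mask * 255).astype(np.uint8)).save(out_dir / mask_name)
        rows.append({"id": img.id, "image_path": img_name, "mask_path": mask_name, "label": img.label})

    def _write(path: Path, subset) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["id", "image_path", "mask_path", "label"])
            writer.writeheader()
            writer.writerows(subset)

    manifests = {"all": out_dir / "manifest.csv"}
    _write(manifests["all"], rows)
    if split is not None:
        if not 0.0 < split < 1.0:
            raise ValueError("split must be in (0, 1)")
        rng = np.random.default_rng(config.seed + 1)
        train_rows, test_rows = [], []
        for label in ("benign", "malignant"):
            cls_rows = [r for r in rows if r["label"] == label]
            perm = rng.permutation(len(cls_rows))
            n_train = int(round(split * len(cls_rows)))
            train_rows += [cls_rows[i] for i in perm[:n_train]]
            test_rows += [cls_rows[i] for i in perm[n_train:]]
        manifests["train"] = out_dir / "manifest_train.csv"
        manifests["test"] = out_dir / "manifest_test.csv"
        _write(manifests["train"], train_rows)
        _write(manifests["test"], test_rows)
    return manifests
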