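"""Synthetic multi-scanner radiomic data with known ground truth.

Two generators:

* :func:`simulate_features` draws feature tables from the additive/
  multiplicative batch-effect model

  .. math:: y_{ijg} = \\alpha_g + X\\beta_g + \\gamma_{ig}
            + \\delta_{ig}\\,\\epsilon_{ijg},

  where ``i`` indexes the scanner batch, ``j`` the sample and ``g`` the
  feature; ``X`` is the binary texture-class indicator. Ground-truth
  parameters are returned so harmonization can be tested as a parameter
  recovery problem.

* :func:`simulate_phantom` builds a small 3D volume containing equal-size
  labeled cubes of two textures (speckle vs honeycomb-like), mimicking the
  rubber and ABS cartridges of a texture phantom, for the feature-extraction
  path.

Prior families mirror what the empirical-Bayes harmonization step assumes:
``alpha ~ N(0,1)``, ``beta ~ N(0, class_effect_scale^2)``,
``gamma ~ N(0, additive_effect_scale^2)``, ``delta ~ U(range)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy import ndimage

from .datatypes import FeatureTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PhantomVolume",
    "simulate_features",
    "simulate_phantom",
    "write_nifti",
    "read_nifti",
    "DEFAULT_TEXTURES",
]


class ConfigurationError(ValueError):
    """A simulation parameter violates its contract."""


@dataclass
class SimulationConfig:
    """Free parameters of the batch-effect generative model.

    Defaults reproduce the study structure: three scanner batches of
    53/42/40 samples and 100 features, with a unit class effect, unit
    additive batch spread, mild multiplicative spread and unit noise.
    """

    n_per_batch: list[int] = field(default_factory=lambda: [53, 42, 40])
    n_features: int = 100
    class_effect_scale: float = 1.0
    additive_effect_scale: float = 1.0
    multiplicative_effect_range: tuple[float, float] = (0.75, 1.33)
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_batch) < 2:
            raise ConfigurationError("n_per_batch: need at least 2 batches")
        if any(int(n) < 2 for n in self.n_per_batch):
            raise ConfigurationError("n_per_batch: every batch needs >= 2 samples")
        if self.n_features < 1:
            raise ConfigurationError("n_features: must be positive")
        if self.class_effect_scale < 0:
            raise ConfigurationError("class_effect_scale: must be nonnegative")
        if self.additive_effect_scale < 0:
            raise ConfigurationError("additive_effect_scale: must be nonnegative")
        lo, hi = self.multiplicative_effect_range
        if not (0 < lo <= hi):
            raise ConfigurationError(
                "multiplicative_effect_range: need 0 < low <= high"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd: must be positive")


@dataclass
class GroundTruth:
    """True generative parameters behind a simulated :class:`FeatureTable`."""

    alpha: np.ndarray    # (n_features,)
    beta: np.ndarray     # (n_features,) class effect
    gamma: np.ndarray    # (n_batches, n_features) additive batch effect
    delta: np.ndarray    # (n_batches, n_features) multiplicative batch effect


def simulate_features(config: SimulationConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw a feature table from the location/scale batch-effect model.

    Classes are balanced within each batch (odd batch sizes put the extra
    sample in class 0). The same seed always yields bitwise-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_batches = len(config.n_per_batch)
    G = config.n_features

    alpha = rng.normal(0.0, 1.0, G)
    beta = rng.normal(0.0, config.class_effect_scale, G) \
        if config.class_effect_scale > 0 else np.zeros(G)
    gamma = rng.normal(0.0, config.additive_effect_scale, (n_batches, G)) \
        if config.additive_effect_scale > 0 else np.zeros((n_batches, G))
    lo, hi = config.multiplicative_effect_range
    delta = rng.uniform(lo, hi, (n_batches, G)) if hi > lo \
        else np.full((n_batches, G), float(lo))

    rows, batch_labels, class_labels = [], [], []
    for i, n_i in enumerate(config.n_per_batch):
        n_i = int(n_i)
        # class 0 first; the extra sample of an odd batch lands in class 0
        x = np.r_[np.zeros(n_i - n_i // 2, dtype=int), np.ones(n_i // 2, dtype=int)]
        eps = rng.normal(0.0, config.noise_sd, (n_i, G))
        y = alpha + x[:, None] * beta + gamma[i] + delta[i] * eps
        rows.append(y)
        batch_labels.append(np.full(n_i, f"batch{i}"))
        class_labels.append(x)

    table = FeatureTable(
        np.vstack(rows),
        [f"f{g:03d}" for g in range(G)],
        np.concatenate(batch_labels),
        np.concatenate(class_labels),
    )
    return table, GroundTruth(alpha, beta, gamma, delta)


# ---------------------------------------------------------------------------
# phantom volumes


@dataclass
class PhantomVolume:
    """3D voxel grid with an integer ROI label map.

    Label codes: background ``-1``; ``0`` rubber-like speckle cubes;
    ``1`` ABS-like honeycomb cubes. Spacing in millimetres.
    """

    voxels: np.ndarray
    label_map: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    BACKGROUND: int = -1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.label_map = np.asarray(self.label_map, dtype=int)
        if self.voxels.shape != self.label_map.shape:
            raise ValueError("voxels and label_map must share a shape")


@dataclass
class TextureParams:
    """Per-class texture descriptors for the phantom generator."""

    speckle_sd: float = 1.0       # white-noise amplitude of class 0
    speckle_smooth: float = 1.0   # Gaussian kernel (voxels) smoothing class 0
    honeycomb_period: float = 4.0  # sinusoid period (voxels) of class 1
    honeycomb_contrast: float = 2.0
    honeycomb_noise_sd: float = 0.3


DEFAULT_TEXTURES = TextureParams()


def _speckle(shape, rng, p: TextureParams) -> np.ndarray:
    field_ = rng.normal(0.0, p.speckle_sd, shape)
    return ndimage.gaussian_filter(field_, p.speckle_smooth)


def _honeycomb(shape, rng, p: TextureParams) -> np.ndarray:
    # thresholded sum of three phase-shifted sinusoids: a cheap periodic
    # cell pattern, separable from smoothed speckle by texture statistics
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    w = 2.0 * np.pi / p.honeycomb_period
    s = (
        np.sin(w * xx)
        + np.sin(w * yy + 2.0 * np.pi / 3.0)
        + np.sin(w * zz + 4.0 * np.pi / 3.0)
    )
    cells = np.where(s > 0.0, p.honeycomb_contrast, -p.honeycomb_contrast)
    return cells + rng.normal(0.0, p.honeycomb_noise_sd, shape)


def simulate_phantom(
    side_voxels: int = 12,
    n_cubes_per_class: int = 4,
    texture_params: TextureParams = DEFAULT_TEXTURES,
    seed: int = 0,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> PhantomVolume:
    """Build a volume of 2*n_cubes_per_class equal-size labeled texture cubes.

    Cubes are laid out on a regular grid with a one-voxel gap, class labels
    alternating, so no two ROIs touch. Raises ``ValueError`` if the grid
    cannot be packed (it always can here, because the volume is sized to
    fit), or if ``side_voxels`` is too small for meaningful texture.
    """
    if side_voxels < 5:
        raise ValueError("side_voxels must be >= 5")
    if n_cubes_per_class < 1:
        raise ValueError("n_cubes_per_class must be positive")
    rng = np.random.default_rng(seed)

    n_total = 2 * n_cubes_per_class
    # grid of cells, each cell = cube + 1 voxel margin on each side
    cell = side_voxels + 2
    per_axis = int(np.ceil(n_total ** (1.0 / 3.0)))
    while per_axis**3 < n_total:
        per_axis += 1
    shape = (cell * per_axis,) * 3
    voxels = rng.normal(0.0, 0.05, shape)  # faint background noise
    labels = np.full(shape, PhantomVolume.BACKGROUND, dtype=int)

    placed = 0
    for cz in range(per_axis):
        for cy in range(per_axis):
            for cx in range(per_axis):
                if placed >= n_total:
                    break
                cls = placed % 2
                z0, y0, x0 = cell * cz + 1, cell * cy + 1, cell * cx + 1
                sl = (
                    slice(z0, z0 + side_voxels),
                    slice(y0, y0 + side_voxels),
                    slice(x0, x0 + side_voxels),
                )
                tex = (_speckle if cls == 0 else _honeycomb)(
                    (side_voxels,) * 3, rng, texture_params
                )
                voxels[sl] = tex
                labels[sl] = cls
                placed += 1
    if placed < n_total:
        raise ValueError(
            f"could not pack {n_total} cubes of side {side_voxels}"
        )
    return PhantomVolume(voxels, labels, voxel_spacing)


# ---------------------------------------------------------------------------
# NIfTI round trip


def write_nifti(volume: PhantomVolume, image_path: str | Path,
                label_path: str | Path) -> None:
    """Write voxels and label map as a NIfTI-1 pair with shared geometry."""
    affine = np.diag(list(volume.voxel_spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine),
             str(image_path))
    nib.save(nib.Nifti1Image(volume.label_map.astype(np.int16), affine),
             str(label_path))


def read_nifti(image_path: str | Path, label_path: str | Path) -> PhantomVolume:
    """Read a volume/label NIfTI pair; raises a format error on bad files."""
    try:
        img = nib.load(str(image_path))
        lab = nib.load(str(label_path))
        voxels = np.asarray(img.dataobj, dtype=float)
        labels = np.asarray(lab.dataobj).astype(int)
    except Exception as exc:  # nibabel raises several unrelated types
        raise IOError(f"could not read NIfTI pair: {exc}") from exc
    if voxels.shape != labels.shape:
        raise IOError("image and label map geometries differ")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PhantomVolume(voxels, labels, spacing)
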