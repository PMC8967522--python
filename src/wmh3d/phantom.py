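"""Synthetic phantoms: WMH-like lesion stacks and analytic scalar fields.

The phantom emulates the salient features of FLAIR-style lesion imaging —
bright, roughly ellipsoidal hyperintense blobs on a darker, textured
brain-shaped background — with a voxel-exact ground-truth mask.  Lesions are
ellipsoids in 3D, so each lesion occupies a contiguous run of slices and the
3D mask component per lesion is connected.  An analytic signed sphere field
is provided for validating isosurface extraction against closed-form area
and volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .volume import MaskVolume, SliceStack

__all__ = [
    "PhantomSpec",
    "Lesion",
    "sample_lesions",
    "generate_phantom",
    "sphere_field",
    "write_phantom_dataset",
]

# Background model: a dark elliptical "brain" on a near-black field.
_BRAIN_LEVEL = 0.30
_OUTSIDE_LEVEL = 0.02
_BRAIN_SEMIAXIS_FRACTION = 0.42  # of image height/width
_EDGE_SIGMA = 1.0  # Gaussian softening of the lesion rim, in voxels


@dataclass
class PhantomSpec:
    """Parameters of one synthetic lesion phantom.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 64x64 slices (the production-scale input is 512x512), a handful
    of lesions of 3-7 px radius, lesion contrast 0.35 above the 0.30 brain
    background, mild tissue texture and acquisition noise.
    """

    image_height: int = 64
    image_width: int = 64
    n_slices: int = 16
    n_lesions: int = 3
    lesion_radius_range: tuple[float, float] = (3.0, 7.0)
    lesion_intensity: float = 0.35
    background_texture_sd: float = 0.03
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0 or self.n_slices <= 0:
            raise ValueError("image dimensions and slice count must be positive")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be non-negative")
        rmin, rmax = self.lesion_radius_range
        if rmin > rmax or rmin <= 0:
            raise ValueError("lesion_radius_range must satisfy 0 < min <= max")
        if self.noise_sd < 0 or self.background_texture_sd < 0:
            raise ValueError("noise and texture standard deviations must be >= 0")
        brain_ry = _BRAIN_SEMIAXIS_FRACTION * self.image_height
        brain_rx = _BRAIN_SEMIAXIS_FRACTION * self.image_width
        if self.n_lesions > 0 and rmax >= min(brain_ry, brain_rx):
            raise ValueError(
                f"lesion radius up to {rmax} px cannot fit inside the brain region "
                f"(semi-axes {brain_ry:.1f} x {brain_rx:.1f} px)"
            )


@dataclass
class Lesion:
    """One ellipsoidal lesion: center and semi-axes in voxel units,
    both in (slice, row, col) order."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def contains(self, z: float, y: float, x: float) -> bool:
        cz, cy, cx = self.center
        rz, ry, rx = self.radii
        return ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + (
            (x - cx) / rx
        ) ** 2 <= 1.0


def _brain_mask(height: int, width: int) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ry = _BRAIN_SEMIAXIS_FRACTION * height
    rx = _BRAIN_SEMIAXIS_FRACTION * width
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def sample_lesions(spec: PhantomSpec) -> list[Lesion]:
    """Draw the lesion ellipsoids for a spec (deterministic in the seed).

    The lesion stream is independent of the texture and noise streams, so
    the same lesions are produced regardless of ``background_texture_sd``
    and ``noise_sd``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[1])
    ns, h, w = spec.n_slices, spec.image_height, spec.image_width
    rmin, rmax = spec.lesion_radius_range
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    brain_ry = _BRAIN_SEMIAXIS_FRACTION * h
    brain_rx = _BRAIN_SEMIAXIS_FRACTION * w
    lesions = []
    for _ in range(spec.n_lesions):
        ry = rng.uniform(rmin, rmax)
        rx = rng.uniform(rmin, rmax)
        # Through-plane extent: half the in-plane scale, capped to the stack,
        # and always >= 1 voxel so each lesion spans a contiguous slice run.
        rz = min(rng.uniform(max(1.0, 0.5 * rmin), max(1.5, 0.5 * rmax)),
                 (ns - 1) / 2.0)
        # Place the center so the ellipsoid stays inside the brain ellipse
        # (in-plane) and inside the slice range (through-plane).
        cy = cy0
        cx = cx0
        for _attempt in range(200):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rho = np.sqrt(rng.uniform(0.0, 1.0))
            y = cy0 + rho * (brain_ry - ry) * np.sin(theta)
            x = cx0 + rho * (brain_rx - rx) * np.cos(theta)
            if (((y - cy0) / (brain_ry - ry)) ** 2
                    + ((x - cx0) / (brain_rx - rx)) ** 2) <= 1.0:
                cy, cx = y, x
                break
        cz = rng.uniform(rz, ns - 1 - rz) if ns - 1 > 2 * rz else (ns - 1) / 2.0
        lesions.append(Lesion(center=(cz, cy, cx), radii=(rz, ry, rx)))
    return lesions


def generate_phantom(spec: PhantomSpec) -> tuple[SliceStack, MaskVolume]:
    """Generate a lesion phantom and its voxel-exact ground-truth mask.

    The image is built deterministically from ``spec.seed``: background
    (dark ellipse + smoothed texture), plus ``lesion_intensity`` added over
    each ellipsoidal lesion (full strength inside the exact ellipsoid, a
    Gaussian-softened halo just outside it), plus i.i.d. Gaussian noise,
    clipped to [0, 1].  The returned mask thresholds the *unsmoothed*
    ellipsoids (see :func:`sample_lesions`), so ground truth is exact by
    construction.
    """
    spec.validate()
    texture_seed, _, noise_seed = np.random.SeedSequence(spec.seed).spawn(3)
    ns, h, w = spec.n_slices, spec.image_height, spec.image_width

    brain2d = _brain_mask(h, w)
    background = np.where(brain2d, _BRAIN_LEVEL, _OUTSIDE_LEVEL)[None, :, :]
    background = np.repeat(background, ns, axis=0).astype(np.float64)
    if spec.background_texture_sd > 0:
        texture_rng = np.random.default_rng(texture_seed)
        texture = texture_rng.normal(0.0, spec.background_texture_sd,
                                     size=(ns, h, w))
        texture = gaussian_filter(texture, sigma=(0.0, 2.0, 2.0))
        background = background + np.where(brain2d[None], texture, 0.0)

    mask = np.zeros((ns, h, w), dtype=np.uint8)
    zz, yy, xx = np.mgrid[0:ns, 0:h, 0:w].astype(np.float64)
    for les in sample_lesions(spec):
        cz, cy, cx = les.center
        rz, ry, rx = les.radii
        inside = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
                  + ((xx - cx) / rx) ** 2) <= 1.0
        mask[inside] = 1

    clean = background.copy()
    if mask.any():
        halo = gaussian_filter(mask.astype(np.float64), sigma=_EDGE_SIGMA)
        additive = spec.lesion_intensity * np.where(mask > 0, 1.0, halo)
        clean = clean + additive

    image = clean
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng(noise_seed)
        image = image + noise_rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    stack = SliceStack(image)
    return stack, MaskVolume(mask)


def sphere_field(
    grid_shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radius: float,
) -> SliceStack:
    """Signed distance-like field ``radius - |p - center|`` on a voxel grid.

    The 0-isosurface is an exact sphere, which makes the field the standard
    validation input for surface extraction: its area (4 pi r^2) and volume
    (4/3 pi r^3) are known in closed form.  ``center`` is in voxel
    coordinates, index order (slice, row, col).

    Raises
    ------
    ValueError
        If the sphere touches or crosses the grid boundary (the isosurface
        would then be open and watertightness checks meaningless).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    for dim, c in zip(grid_shape, center):
        if c - radius <= 0 or c + radius >= dim - 1:
            raise ValueError(
                f"sphere (center {center}, radius {radius}) touches the boundary "
                f"of the {grid_shape} grid"
            )
    zz, yy, xx = np.mgrid[0 : grid_shape[0], 0 : grid_shape[1], 0 : grid_shape[2]]
    dist = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    return SliceStack(radius - dist)


def write_phantom_dataset(
    spec: PhantomSpec, out_dir: str | Path
) -> tuple[SliceStack, MaskVolume]:
    """Generate a phantom and write it as per-slice PNGs plus a manifest.

    Layout: ``images/slice_###.png`` (8-bit grayscale), ``masks/slice_###.png``
    (0/255), and ``manifest.yaml`` recording the spec and seed.
    """
    from . import imaging_io  # local import: avoid a cycle at module load

    stack, mask = generate_phantom(spec)
    out = Path(out_dir)
    imaging_io.save_png_stack(stack, out / "images")
    imaging_io.save_png_stack(
        SliceStack(mask.labels.astype(np.float64)), out / "masks"
    )
    manifest = {"spec": dataclasses.asdict(spec), "seed": spec.seed}
    manifest["spec"]["lesion_radius_range"] = list(spec.lesion_radius_range)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return stack, mask
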