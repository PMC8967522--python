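"""Reading, writing and preprocessing of medical image stacks.

Supports DICOM series directories (via pydicom), NIfTI volumes (via
nibabel) and per-slice grayscale PNG stacks (via Pillow), all normalised
into the package's :class:`~wmh3d.volume.SliceStack` convention:
(slice, row, col) index order, intensities in [0, 1], spacings in mm.

Also provides the preprocessing (per-slice histogram equalization) and the
patient-level train/test split plus cross-validation fold assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .volume import MaskVolume, SliceStack

__all__ = [
    "load_stack",
    "save_png_stack",
    "save_nifti",
    "load_mask",
    "save_mask_png",
    "equalize_histogram",
    "DatasetIndex",
    "make_splits",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stack I/O
# ---------------------------------------------------------------------------

def _rescale_unit(arr: np.ndarray) -> np.ndarray:
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if lo >= 0.0 and hi <= 1.0:  # already in unit range: keep values exact
        return arr
    if hi > lo:
        return (arr - lo) / (hi - lo)
    return np.zeros_like(arr)


def _load_png_stack(path: Path) -> SliceStack:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
    if not files:
        raise FileNotFoundError(f"no PNG slices found in {path}")
    slices = []
    for f in files:
        img = np.asarray(Image.open(f).convert("L"), dtype=np.float64) / 255.0
        slices.append(img)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"mixed slice dimensions in {path}: {sorted(shapes)}")
    warnings.warn(
        f"PNG stack {path} carries no spacing metadata; defaulting to 1.0 mm",
        stacklevel=2,
    )
    return SliceStack(np.stack(slices))


def _load_nifti(path: Path) -> SliceStack:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    # NIfTI stores (x, y, z) = (col, row, slice); transpose to (slice, row, col).
    vox = np.transpose(data, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    sx, sy, sz = (float(z) for z in zooms)
    if min(sx, sy, sz) <= 0:
        warnings.warn(
            f"NIfTI {path} has non-positive spacing {zooms}; defaulting to 1.0 mm",
            stacklevel=2,
        )
        sx = sy = sz = 1.0
    return SliceStack(_rescale_unit(vox), pixel_spacing=(sy, sx), slice_spacing=sz)


def _load_dicom_series(path: Path) -> SliceStack:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:  # not a DICOM file — skip silently
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FileNotFoundError(f"no readable DICOM slices in {path}")

    def sort_key(ds):
        if getattr(ds, "ImagePositionPatient", None) is not None:
            return float(ds.ImagePositionPatient[2])
        if getattr(ds, "SliceLocation", None) is not None:
            return float(ds.SliceLocation)
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"mixed slice dimensions in {path}: {sorted(shapes)}")

    ds0 = datasets[0]
    if getattr(ds0, "PixelSpacing", None) is not None:
        pixel_spacing = (float(ds0.PixelSpacing[0]), float(ds0.PixelSpacing[1]))
    else:
        warnings.warn(
            f"DICOM series {path} lacks PixelSpacing; defaulting to 1.0 mm",
            stacklevel=2,
        )
        pixel_spacing = (1.0, 1.0)
    locations = [sort_key(ds) for ds in datasets]
    diffs = np.diff(locations)
    if len(diffs) and np.all(diffs > 0):
        slice_spacing = float(np.mean(diffs))
    elif getattr(ds0, "SliceThickness", None) is not None:
        slice_spacing = float(ds0.SliceThickness)
    else:
        warnings.warn(
            f"DICOM series {path} lacks slice spacing metadata; defaulting to 1.0 mm",
            stacklevel=2,
        )
        slice_spacing = 1.0
    return SliceStack(
        _rescale_unit(np.stack(slices)),
        pixel_spacing=pixel_spacing,
        slice_spacing=slice_spacing,
    )


def load_stack(path: str | Path, format: str | None = None) -> SliceStack:
    """Load a volume as a :class:`SliceStack`.

    ``format`` is one of ``dicom_series``, ``nifti``, ``png_stack``; when
    omitted it is inferred (directory of PNGs -> png_stack, ``.nii``/
    ``.nii.gz`` -> nifti, other directory -> dicom_series).

    Slices are ordered by acquisition position: ascending slice location
    for DICOM, lexicographic filename for PNG stacks (zero-padded indices
    expected).  Intensities are rescaled to [0, 1]; missing spacing
    metadata falls back to 1.0 mm with a warning.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            has_png = any(p.suffix.lower() == ".png" for p in path.iterdir())
            format = "png_stack" if has_png else "dicom_series"
        elif path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise ValueError(f"cannot infer stack format of {path}")
    if format == "png_stack":
        return _load_png_stack(path)
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown stack format {format!r}")


def save_png_stack(stack: SliceStack, out_dir: str | Path) -> list[Path]:
    """Write a stack as 8-bit grayscale ``slice_###.png`` files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sl in enumerate(stack.voxels):
        arr = np.clip(np.round(sl * 255.0), 0, 255).astype(np.uint8)
        p = out / f"slice_{i:03d}.png"
        Image.fromarray(arr, mode="L").save(p)
        paths.append(p)
    return paths


def save_nifti(stack: SliceStack, path: str | Path) -> None:
    """Write a stack (values as-is) to NIfTI with its spacings."""
    import nibabel as nib

    data = np.transpose(np.asarray(stack.voxels, dtype=np.float32), (2, 1, 0))
    sz, sy, sx = stack.spacing_zyx()
    affine = np.diag([sx, sy, sz, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_mask(path: str | Path) -> MaskVolume:
    """Load a binary mask stack (PNG directory with 0/255, or NIfTI {0,1})."""
    stack = load_stack(path)
    labels = (stack.voxels >= 0.5).astype(np.uint8)
    return MaskVolume(
        labels,
        pixel_spacing=stack.pixel_spacing,
        slice_spacing=stack.slice_spacing,
    )


def save_mask_png(mask: MaskVolume, out_dir: str | Path) -> list[Path]:
    """Write a binary mask as per-slice 0/255 PNGs."""
    return save_png_stack(SliceStack(mask.labels.astype(np.float64)), out_dir)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def equalize_histogram(stack: SliceStack) -> SliceStack:
    """Per-slice global histogram equalization onto 256 gray levels.

    Each slice is quantised to 256 levels, remapped through its cumulative
    distribution (the classic ``(cdf - cdf_min) / (N - cdf_min)`` rule) and
    rescaled back to [0, 1].  The mapping is monotone non-decreasing; a
    constant slice is returned unchanged (its CDF is degenerate).
    """
    out = np.empty_like(stack.voxels, dtype=np.float64)
    for i, sl in enumerate(stack.voxels):
        out[i] = _equalize_slice(np.asarray(sl, dtype=np.float64))
    return SliceStack(out, stack.pixel_spacing, stack.slice_spacing)


def _equalize_slice(sl: np.ndarray) -> np.ndarray:
    if sl.max() > 1.0:  # tolerate [0, 255] input
        sl = sl / 255.0
    levels = np.clip(np.round(sl * 255.0), 0, 255).astype(np.intp)
    hist = np.bincount(levels.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = sl.size
    nonzero = hist > 0
    if nonzero.sum() <= 1:
        return sl.copy()
    cdf_min = cdf[np.argmax(nonzero)]  # count at the lowest occupied level
    mapping = np.round((cdf - cdf_min) / (n - cdf_min) * 255.0)
    return mapping[levels] / 255.0


# ---------------------------------------------------------------------------
# Splits and folds
# ---------------------------------------------------------------------------

@dataclass
class DatasetIndex:
    """Item list with patient-level train/test split and CV folds.

    ``items`` are ``(image_path, mask_path, patient_id)`` triples.  All
    slices of one patient always land in the same split and fold, so no
    near-duplicate adjacent slices leak between train and test.  Folds are
    defined over the training portion only; the test split is held out
    from cross-validation entirely.
    """

    items: list[tuple[str, str, str]]
    split_assignment: dict[int, str] = field(default_factory=dict)
    folds: dict[int, int] = field(default_factory=dict)

    def train_indices(self) -> list[int]:
        return [i for i, s in self.split_assignment.items() if s == "train"]

    def test_indices(self) -> list[int]:
        return [i for i, s in self.split_assignment.items() if s == "test"]

    def fold_indices(self, fold: int) -> list[int]:
        return [i for i, f in self.folds.items() if f == fold]

    def validate(self) -> None:
        for i in range(len(self.items)):
            if self.split_assignment.get(i) not in ("train", "test"):
                raise ValueError(f"item {i} has no split assignment")
        patient_split: dict[str, str] = {}
        patient_fold: dict[str, int] = {}
        for i, (_, _, pid) in enumerate(self.items):
            s = self.split_assignment[i]
            if patient_split.setdefault(pid, s) != s:
                raise ValueError(f"patient {pid} appears in both splits")
            if i in self.folds:
                f = self.folds[i]
                if patient_fold.setdefault(pid, f) != f:
                    raise ValueError(f"patient {pid} spans multiple folds")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "items": [list(t) for t in self.items],
            "split_assignment": {int(k): v for k, v in self.split_assignment.items()},
            "folds": {int(k): int(v) for k, v in self.folds.items()},
        }
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetIndex":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            items=[tuple(t) for t in doc["items"]],
            split_assignment={int(k): v for k, v in doc["split_assignment"].items()},
            folds={int(k): int(v) for k, v in doc["folds"].items()},
        )


def make_splits(
    items: list[tuple[str, str, str]],
    ratio: float = 0.8,
    n_folds: int = 5,
    seed: int = 0,
) -> DatasetIndex:
    """Patient-level 8:2 train/test split plus fold assignment.

    Patients are shuffled by ``seed``, then accumulated into the training
    split until the train item count best approximates ``ratio`` of all
    items.  Cross-validation folds partition the *training* patients
    round-robin.
    """
    patients: dict[str, list[int]] = {}
    for i, (_, _, pid) in enumerate(items):
        patients.setdefault(pid, []).append(i)
    if len(patients) < n_folds:
        raise ValueError(
            f"need at least {n_folds} patients for {n_folds}-fold CV, "
            f"got {len(patients)}"
        )
    rng = np.random.default_rng(seed)
    order = list(patients)
    rng.shuffle(order)

    n_items = len(items)
    target = ratio * n_items
    train_patients: list[str] = []
    count = 0
    for pid in order:
        k = len(patients[pid])
        # add this patient only if it brings the train count closer to target
        if abs(count + k - target) <= abs(count - target):
            train_patients.append(pid)
            count += k
    if len(train_patients) < n_folds:  # degenerate small inputs
        train_patients = order[:n_folds]

    split = {}
    folds = {}
    train_set = set(train_patients)
    for pid, idxs in patients.items():
        s = "train" if pid in train_set else "test"
        for i in idxs:
            split[i] = s
    for fi, pid in enumerate(train_patients):
        for i in patients[pid]:
            folds[i] = fi % n_folds
    index = DatasetIndex(items=list(items), split_assignment=split, folds=folds)
    index.validate()
    return index
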