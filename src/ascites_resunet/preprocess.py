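"""CT slice IO and the preprocessing/augmentation pipeline.

The pipeline mirrors standard abdominal-CT practice: read DICOM pixels
back to Hounsfield units through the rescale tags, apply an abdomen
display window (width 400 HU / level 60 HU) that linearly maps
[-140, 260] HU onto [0, 1], down-sample 512 -> 256, replicate the
grayscale to three channels, and augment image/mask pairs with small
rotations and flips.  Class balancing draws augmented copies with
replacement until both classes reach a common target count.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from PIL import Image
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .core import AugmentSpec, HUSlice, WindowSpec, validate_binary_mask, validate_model_input
from .phantom import DatasetEntry, PhantomDataset

# ---------------------------------------------------------------------------
# DICOM / PNG IO


def read_dicom_slice(path: str | Path) -> HUSlice:
    """Read one DICOM file into HU via ``stored * RescaleSlope + RescaleIntercept``."""
    ds = pydicom.dcmread(str(path))
    for tag in ("RescaleSlope", "RescaleIntercept", "PixelSpacing", "SliceThickness"):
        if getattr(ds, tag, None) is None:
            raise ValueError(f"DICOM file {path} is missing required tag {tag}")
    stored = ds.pixel_array.astype(np.float32)
    if stored.ndim != 2 or stored.shape[0] != stored.shape[1]:
        raise ValueError(f"expected a square 2-D slice, got shape {stored.shape}")
    hu = stored * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
    return HUSlice(
        pixels=hu,
        pixel_spacing_mm=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
        slice_thickness_mm=float(ds.SliceThickness),
    )


def write_dicom_slice(hu: HUSlice, path: str | Path) -> None:
    """Write an HU slice as secondary-capture DICOM (slope 1, intercept -1024)."""
    intercept = -1024.0
    stored = np.rint(hu.pixels - intercept)
    if stored.min() < 0 or stored.max() > 65535:
        raise ValueError("HU values outside the storable range")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientID = hu.subject_id or "PHANTOM"
    ds.InstanceNumber = hu.slice_index
    ds.Rows, ds.Columns = hu.pixels.shape
    ds.PixelSpacing = [f"{hu.pixel_spacing_mm[0]:.6f}", f"{hu.pixel_spacing_mm[1]:.6f}"]
    ds.SliceThickness = f"{hu.slice_thickness_mm:.6f}"
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = f"{intercept:.0f}"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = stored.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def write_png16_slice(hu: HUSlice, path: str | Path) -> None:
    """16-bit PNG (HU + 1024) with a JSON sidecar carrying the geometry."""
    stored = np.rint(hu.pixels + 1024.0)
    Image.fromarray(stored.astype(np.uint16)).save(str(path))
    sidecar = {
        "rescale_intercept": -1024.0,
        "rescale_slope": 1.0,
        "pixel_spacing_mm": list(hu.pixel_spacing_mm),
        "slice_thickness_mm": hu.slice_thickness_mm,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_png16_slice(path: str | Path) -> HUSlice:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    stored = np.asarray(Image.open(str(path)), dtype=np.float32)
    hu = stored * sidecar["rescale_slope"] + sidecar["rescale_intercept"]
    return HUSlice(
        pixels=hu,
        pixel_spacing_mm=tuple(sidecar["pixel_spacing_mm"]),
        slice_thickness_mm=sidecar["slice_thickness_mm"],
    )


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    mask = validate_binary_mask(mask)
    Image.fromarray((mask * 255).astype(np.uint8)).save(str(path))


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(str(path)))
    return (arr > 127).astype(np.uint8)


# ---------------------------------------------------------------------------
# windowing / resizing


def apply_window(hu: HUSlice | np.ndarray, window: WindowSpec = WindowSpec()) -> np.ndarray:
    """Window-normalize HU to [0, 1]: clip((HU - lo) / width, 0, 1).

    With the abdomen defaults the clipping bounds are [-140, 260] HU.
    Monotone non-decreasing in HU.
    """
    pixels = hu.pixels if isinstance(hu, HUSlice) else np.asarray(hu)
    return np.clip((pixels - window.lo) / window.width, 0.0, 1.0)


def resize_image(grid: np.ndarray, target: int) -> np.ndarray:
    """Down-sample a square grid to ``target`` x ``target``.

    Integer reduction factors use aligned block averaging (the exact
    bilinear limit for 2x); other ratios fall back to bilinear
    interpolation.  Up-sizing is rejected: this pipeline only reduces
    512 -> 256.
    """
    grid = np.asarray(grid, dtype=np.float64)
    n = grid.shape[0]
    if grid.ndim != 2 or grid.shape[1] != n:
        raise ValueError(f"expected a square 2-D grid, got {grid.shape}")
    if target > n:
        raise ValueError(f"up-sizing {n} -> {target} is not supported")
    if target == n:
        return grid.copy()
    if n % target == 0:
        f = n // target
        return grid.reshape(target, f, target, f).mean(axis=(1, 3))
    return _sk_resize(grid, (target, target), order=1, anti_aliasing=False, preserve_range=True)


def resize_mask(mask: np.ndarray, target: int) -> np.ndarray:
    """Nearest-neighbour mask down-sampling; output strictly binary."""
    mask = validate_binary_mask(mask)
    n = mask.shape[0]
    if target > n:
        raise ValueError(f"up-sizing {n} -> {target} is not supported")
    idx = np.floor((np.arange(target) + 0.5) * n / target).astype(int)
    return mask[np.ix_(idx, idx)]


def to_model_input(windowed: np.ndarray) -> np.ndarray:
    """Replicate a windowed grid to the (H, W, 3) model input tensor."""
    windowed = np.asarray(windowed)
    if windowed.ndim != 2:
        raise ValueError("expected a 2-D windowed grid")
    return validate_model_input(np.repeat(windowed[:, :, None], 3, axis=2))


# ---------------------------------------------------------------------------
# augmentation


def apply_augment(
    image: np.ndarray,
    mask: np.ndarray,
    angle_deg: float,
    hflip: bool,
    vflip: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a fixed rotation-then-flips transform to an image/mask pair.

    The image is rotated with bilinear interpolation (out-of-frame
    pixels fill with 0); the mask follows the same rotation and is
    re-binarized at 0.5.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = validate_binary_mask(mask).astype(np.float64)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} sizes differ")
    if angle_deg != 0.0:
        image = ndimage.rotate(
            image, angle_deg, axes=(1, 0), reshape=False, order=1, mode="constant", cval=0.0
        )
        mask = ndimage.rotate(
            mask, angle_deg, axes=(1, 0), reshape=False, order=1, mode="constant", cval=0.0
        )
    if hflip:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if vflip:
        image = image[::-1, :]
        mask = mask[::-1, :]
    image = np.clip(image, 0.0, 1.0)
    return np.ascontiguousarray(image), (mask >= 0.5).astype(np.uint8)


def draw_augment(spec: AugmentSpec, rng: np.random.Generator) -> tuple[float, bool, bool]:
    """One random (angle, hflip, vflip) draw under ``spec``."""
    lo, hi = spec.rotation_range_deg
    angle = float(rng.uniform(lo, hi)) if hi > lo else 0.0
    hflip = bool(rng.random() < 0.5) if spec.allow_horizontal_flip else False
    vflip = bool(rng.random() < 0.5) if spec.allow_vertical_flip else False
    return angle, hflip, vflip


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    spec: AugmentSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly rotate/flip an image and its mask with the same transform."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    angle, hflip, vflip = draw_augment(spec, rng)
    return apply_augment(image, mask, angle, hflip, vflip)


# ---------------------------------------------------------------------------
# dataset-level operations


def balance_and_augment(
    dataset: PhantomDataset, target_per_class: int, spec: AugmentSpec
) -> PhantomDataset:
    """Bring both classes to ``target_per_class`` entries.

    Originals are always retained; the deficit per class is filled with
    augmented copies drawn with replacement from that class's originals.
    Augmented entries are manifest-level records (source + draw seed);
    pixels are materialized later by :func:`materialize`.
    """
    by_class: dict[bool, list[DatasetEntry]] = {True: [], False: []}
    for e in dataset.entries:
        by_class[e.has_ascites].append(e)
    if not by_class[True] or not by_class[False]:
        raise ValueError("both classes must be non-empty to balance")
    for label, members in by_class.items():
        if target_per_class < len(members):
            raise ValueError(
                f"target_per_class={target_per_class} would discard originals "
                f"(class {label} has {len(members)})"
            )
    rng = np.random.default_rng(spec.seed)
    new_entries = list(dataset.entries)
    for label in (True, False):
        members = by_class[label]
        deficit = target_per_class - len(members)
        picks = rng.integers(0, len(members), size=deficit)
        for p in picks:
            src = members[int(p)]
            new_entries.append(
                DatasetEntry(
                    subject_id=src.subject_id,
                    slice_index=src.slice_index,
                    has_ascites=src.has_ascites,
                    augment_of=src,
                    augment_seed=int(rng.integers(2**31 - 1)),
                )
            )
    return PhantomDataset(new_entries)


def split_train_test(
    dataset: PhantomDataset, ratio: float = 0.8, seed: int = 0
) -> tuple[PhantomDataset, PhantomDataset]:
    """Stratified subject-level split (no subject straddles the partitions)."""
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must lie in (0, 1)")
    labels = dataset.subject_labels()
    rng = np.random.default_rng(seed)
    train_ids: set[str] = set()
    for label in (True, False):
        ids = sorted(s for s, l in labels.items() if l == label)
        if len(ids) < 2:
            raise ValueError(
                f"need at least 2 subjects per class to split, class {label} has {len(ids)}"
            )
        rng.shuffle(ids)
        n_train = int(round(len(ids) * ratio))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.update(ids[:n_train])
    test_ids = set(labels) - train_ids
    return dataset.subset(train_ids), dataset.subset(test_ids)


def materialize(
    dataset: PhantomDataset,
    window: WindowSpec = WindowSpec(),
    target_size: int = 256,
    augment: AugmentSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the full preprocessing pipeline over a manifest.

    Returns ``(X, y, labels)``: model inputs (n, target, target, 3) in
    [0, 1], masks (n, target, target) in {0, 1}, and per-slice ascites
    flags.  Augmented entries re-use their source pixels and apply their
    recorded random draw (seeded per entry).
    """
    n = len(dataset.entries)
    X = np.empty((n, target_size, target_size, 3), dtype=np.float32)
    y = np.empty((n, target_size, target_size), dtype=np.uint8)
    labels = np.empty(n, dtype=bool)
    cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, e in enumerate(dataset.entries):
        src = e.source()
        key = id(src)
        if key not in cache:
            hu, mask = src.load()
            img = resize_image(apply_window(hu, window), target_size)
            msk = resize_mask(mask, target_size)
            cache[key] = (img, msk)
        img, msk = cache[key]
        if e.augment_of is not None:
            if augment is None:
                raise ValueError("dataset contains augmented entries but no AugmentSpec given")
            rng = np.random.default_rng(e.augment_seed)
            angle, hflip, vflip = draw_augment(augment, rng)
            img, msk = apply_augment(img, msk, angle, hflip, vflip)
        X[i] = to_model_input(img)
        y[i] = msk
        labels[i] = e.has_ascites
    return X, y, labels
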