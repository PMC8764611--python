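"""Synthetic abdominopelvic CT phantom with ground-truth ascites masks.

The phantom is deliberately schematic: an elliptical body cross-section
with subcutaneous fat, a soft-tissue interior, and ellipse-based organ
analogues (liver, bowel, paraspinal muscle, spine).  Free fluid
(ascites) is painted as near-water pockets — crescents along the flanks
or dependent blobs — and only those pockets enter the ground-truth
mask.  Confounders reproduce the two reported failure modes of
fluid-intensity structures that must NOT be segmented: a fully
distended urinary bladder and an ovarian cyst larger than 3 cm.
Because confounder fluid shares the ascites HU band, intensity alone
cannot separate the classes; shape and location carry the signal.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64),
so a spec with a fixed seed reproduces bit-identical slices.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FLUID_HU_RANGE, HUSlice

AIR_HU = -1000.0

#: default organ analogues: (name, centre (row, col) as grid fractions,
#: semi-axes as grid fractions, mean HU, HU texture sd)
DEFAULT_ORGAN_TEMPLATES: tuple[tuple[str, tuple[float, float], tuple[float, float], float, float], ...] = (
    ("liver", (0.38, 0.34), (0.16, 0.18), 100.0, 8.0),
    ("bowel", (0.52, 0.58), (0.14, 0.16), 35.0, 12.0),
    ("muscle_left", (0.70, 0.36), (0.08, 0.05), 55.0, 5.0),
    ("muscle_right", (0.70, 0.64), (0.08, 0.05), 55.0, 5.0),
    ("spine", (0.72, 0.50), (0.055, 0.045), 700.0, 30.0),
)


@dataclass
class AscitesPocket:
    """One free-fluid pocket.

    ``shape`` is ``"blob"`` (ellipse) or ``"crescent"`` (outer ellipse
    minus an inner ellipse offset toward the body centre — fluid layering
    along a flank).  If ``area_px`` is given the pocket is rasterized to
    exactly that many pixels by growing elliptical shells outward from
    the centre (stable tie-break on flattened pixel order).
    """

    center: tuple[float, float]  # grid fractions (row, col)
    semi_axes: tuple[float, float]  # grid fractions
    hu_range: tuple[float, float] = (0.0, 20.0)
    shape: str = "blob"
    area_px: int | None = None
    inner_scale: float = 0.72  # crescent inner ellipse scale
    inner_shift: tuple[float, float] = (0.0, 0.04)  # toward body centre

    def __post_init__(self) -> None:
        lo, hi = self.hu_range
        if not (FLUID_HU_RANGE[0] <= lo <= hi <= FLUID_HU_RANGE[1]):
            raise ValueError(
                f"ascites HU range {self.hu_range} must lie within the "
                f"near-water band {FLUID_HU_RANGE}"
            )
        if self.shape not in ("blob", "crescent"):
            raise ValueError(f"unknown pocket shape {self.shape!r}")

    def region(self, n: int) -> np.ndarray:
        """Boolean pixel region of this pocket on an n x n grid."""
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        cy, cx = self.center[0] * n, self.center[1] * n
        a, b = max(self.semi_axes[0] * n, 1e-6), max(self.semi_axes[1] * n, 1e-6)
        r2 = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2
        if self.shape == "blob" and self.area_px is not None:
            # exact pixel count: keep the area_px smallest elliptical radii
            order = np.argsort(r2, axis=None, kind="stable")
            if self.area_px > n * n:
                raise ValueError("pocket area exceeds grid")
            region = np.zeros(n * n, dtype=bool)
            region[order[: self.area_px]] = True
            return region.reshape(n, n)
        region = r2 <= 1.0
        if self.shape == "crescent":
            icy = cy + self.inner_shift[0] * n
            icx = cx + self.inner_shift[1] * n
            ia, ib = a * self.inner_scale, b * self.inner_scale
            inner = ((rr - icy) / ia) ** 2 + ((cc - icx) / ib) ** 2 <= 1.0
            region &= ~inner
            if self.area_px is not None:
                idx = np.flatnonzero(region.ravel())
                if self.area_px > idx.size:
                    raise ValueError("crescent cannot supply requested area_px")
                order = idx[np.argsort(r2.ravel()[idx], kind="stable")]
                region = np.zeros(n * n, dtype=bool)
                region[order[: self.area_px]] = True
                region = region.reshape(n, n)
        return region


@dataclass
class Confounder:
    """A fluid-filled structure that mimics ascites intensity.

    ``kind`` is ``"bladder"`` (large pelvic ellipse) or
    ``"ovarian_cyst"`` (circle; diameter must exceed 3 cm to model the
    reported failure mode).
    """

    kind: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    hu_range: tuple[float, float] = (-5.0, 18.0)

    def __post_init__(self) -> None:
        if self.kind not in ("bladder", "ovarian_cyst"):
            raise ValueError(f"unknown confounder kind {self.kind!r}")
        lo, hi = self.hu_range
        alo, ahi = FLUID_HU_RANGE
        if hi < alo or lo > ahi:
            raise ValueError(
                "confounder fluid HU range must overlap the ascites band "
                f"{FLUID_HU_RANGE}; got {self.hu_range}"
            )

    def region(self, n: int) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        cy, cx = self.center[0] * n, self.center[1] * n
        a, b = self.semi_axes[0] * n, self.semi_axes[1] * n
        return ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0


@dataclass
class PhantomSpec:
    """Full generative description of one synthetic CT slice."""

    grid_size: int = 512
    pixel_spacing_mm: float = 0.74
    slice_thickness_mm: float = 5.0
    body_axes_px: tuple[float, float] | None = None  # default 0.42/0.46 of grid
    organ_templates: tuple = DEFAULT_ORGAN_TEMPLATES
    ascites_pockets: tuple[AscitesPocket, ...] = ()
    confounders: tuple[Confounder, ...] = ()
    noise_sd_hu: float = 10.0
    seed: int = 0
    fat_hu: tuple[float, float] = (-95.0, 5.0)  # (mean, sd)
    soft_tissue_hu: tuple[float, float] = (45.0, 6.0)

    def __post_init__(self) -> None:
        if self.grid_size <= 0 or self.pixel_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("grid size, spacing and thickness must be positive")
        if self.body_axes_px is None:
            self.body_axes_px = (0.42 * self.grid_size, 0.46 * self.grid_size)
        for _, _, _, mean, _ in self.organ_templates:
            if not (-1000.0 <= mean <= 2000.0):
                raise ValueError(f"organ HU mean {mean} outside [-1000, 2000]")
        self.ascites_pockets = tuple(self.ascites_pockets)
        self.confounders = tuple(self.confounders)

    def body_region(self) -> np.ndarray:
        n = self.grid_size
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        cy = cx = (n - 1) / 2.0
        a, b = self.body_axes_px
        return ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0

    def analytic_pocket_area_mm2(self) -> float:
        """Continuous-geometry total pocket area of this slice in mm^2.

        Exact for pockets given by ``area_px``; for ellipse blobs uses
        pi*a*b.  Crescents without area_px are not supported (their
        rasterized area has no simple closed form).
        """
        total_px = 0.0
        n = self.grid_size
        for p in self.ascites_pockets:
            if p.area_px is not None:
                total_px += p.area_px
            elif p.shape == "blob":
                total_px += np.pi * (p.semi_axes[0] * n) * (p.semi_axes[1] * n)
            else:
                raise ValueError("analytic area needs area_px for crescents")
        return total_px * self.pixel_spacing_mm**2


def generate_slice(spec: PhantomSpec) -> tuple[HUSlice, np.ndarray]:
    """Render one phantom slice and its ground-truth ascites mask.

    Confounder fluid is painted into the image but never into the mask.
    Raises ``ValueError`` if any ascites pocket leaves the body ellipse.
    Deterministic given ``spec.seed``.
    """
    n = spec.grid_size
    rng = np.random.default_rng(spec.seed)
    body = spec.body_region()
    img = np.full((n, n), AIR_HU, dtype=np.float64)

    # body: subcutaneous fat shell around a soft-tissue interior
    img[body] = rng.normal(spec.fat_hu[0], spec.fat_hu[1], body.sum())
    inner_spec_axes = (spec.body_axes_px[0] * 0.88, spec.body_axes_px[1] * 0.88)
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    cy = cx = (n - 1) / 2.0
    interior = ((rr - cy) / inner_spec_axes[0]) ** 2 + (
        (cc - cx) / inner_spec_axes[1]
    ) ** 2 <= 1.0
    img[interior] = rng.normal(
        spec.soft_tissue_hu[0], spec.soft_tissue_hu[1], interior.sum()
    )

    for name, center, axes, mean, sd in spec.organ_templates:
        region = _ellipse(n, center, axes) & body
        img[region] = rng.normal(mean, sd, region.sum())

    for conf in spec.confounders:
        region = conf.region(n) & body
        lo, hi = conf.hu_range
        img[region] = rng.uniform(lo, hi, region.sum())

    mask = np.zeros((n, n), dtype=np.uint8)
    for pocket in spec.ascites_pockets:
        region = pocket.region(n)
        if np.any(region & ~body):
            raise ValueError(
                f"ascites pocket at {pocket.center} extends outside the body ellipse"
            )
        lo, hi = pocket.hu_range
        img[region] = rng.uniform(lo, hi, region.sum())
        mask[region] = 1

    if spec.noise_sd_hu > 0:
        img = img + rng.normal(0.0, spec.noise_sd_hu, img.shape)

    # CT scanners reconstruct integer HU clamped to the 12-bit range;
    # integral values also round-trip exactly through DICOM storage
    img = np.clip(np.rint(img), -1024, 3071)

    hu = HUSlice(
        pixels=img.astype(np.float32),
        pixel_spacing_mm=(spec.pixel_spacing_mm, spec.pixel_spacing_mm),
        slice_thickness_mm=spec.slice_thickness_mm,
    )
    return hu, mask


def _ellipse(n: int, center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    cy, cx = center[0] * n, center[1] * n
    a, b = max(axes[0] * n, 1e-6), max(axes[1] * n, 1e-6)
    return ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# dataset bookkeeping


@dataclass
class DatasetEntry:
    """One slice in a phantom dataset manifest.

    Entries generated by :func:`generate_dataset` carry their
    ``PhantomSpec`` (the generative record) and cached pixel data.
    Entries produced by augmentation reference their source entry plus a
    draw seed; pixels are materialized downstream in the preprocessing
    pipeline.
    """

    subject_id: str
    slice_index: int
    has_ascites: bool
    spec: PhantomSpec | None = None
    slice_path: str | None = None
    mask_path: str | None = None
    augment_of: "DatasetEntry | None" = None
    augment_seed: int | None = None
    _hu: HUSlice | None = None
    _mask: np.ndarray | None = None

    def source(self) -> "DatasetEntry":
        return self.augment_of.source() if self.augment_of is not None else self

    def load(self) -> tuple[HUSlice, np.ndarray]:
        """HU slice and mask of the *source* slice (pre-augmentation)."""
        src = self.source()
        if src._hu is not None:
            return src._hu, src._mask
        if src.spec is not None:
            hu, mask = generate_slice(src.spec)
        elif src.slice_path is not None:
            from . import preprocess  # cycle-free at call time

            hu = preprocess.read_dicom_slice(src.slice_path)
            hu.subject_id, hu.slice_index = src.subject_id, src.slice_index
            mask = preprocess.read_mask_png(src.mask_path)
        else:
            raise ValueError("entry has neither a spec nor file paths")
        src._hu, src._mask = hu, mask
        return hu, mask


@dataclass
class PhantomDataset:
    """Manifest of phantom slices with per-class bookkeeping."""

    entries: list[DatasetEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def class_counts(self) -> dict[bool, int]:
        counts = {True: 0, False: 0}
        for e in self.entries:
            counts[e.has_ascites] += 1
        return counts

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.subject_id)
        return list(seen)

    def subject_labels(self) -> dict[str, bool]:
        """Subject has ascites iff any of its slices does."""
        labels: dict[str, bool] = {}
        for e in self.entries:
            labels[e.subject_id] = labels.get(e.subject_id, False) or e.has_ascites
        return labels

    def subset(self, subject_ids: set[str]) -> "PhantomDataset":
        return PhantomDataset([e for e in self.entries if e.subject_id in subject_ids])

    def manifest_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": e.subject_id,
                "slice_index": e.slice_index,
                "slice_path": e.slice_path or "",
                "mask_path": e.mask_path or "",
                "has_ascites": e.has_ascites,
                "augmented": e.augment_of is not None,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows)

    def validate(self) -> None:
        for e in self.entries:
            if e.augment_of is not None:
                continue
            _, mask = e.load()
            if bool(mask.any()) != e.has_ascites:
                raise ValueError(
                    f"manifest entry {e.subject_id}/{e.slice_index}: mask "
                    f"nonzero={bool(mask.any())} but has_ascites={e.has_ascites}"
                )


def generate_dataset(
    n_subjects_ascites: int,
    n_subjects_control: int,
    slices_per_subject: int,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
    pocket_prob: float = 0.8,
    confounder_prob: float = 0.3,
) -> PhantomDataset:
    """Generate a subject-partitioned phantom dataset.

    Ascites subjects receive at least one slice with a fluid pocket
    (each further slice with probability ``pocket_prob``); control
    subjects receive none but may carry confounders, as may ascites
    subjects.  Pocket geometry (crescent flank collections and dependent
    blobs, graded sizes) is randomized per slice.
    """
    if n_subjects_ascites < 0 or n_subjects_control < 0:
        raise ValueError("subject counts must be non-negative")
    if slices_per_subject <= 0:
        raise ValueError("slices_per_subject must be positive")
    template = spec_template or PhantomSpec()
    rng = np.random.default_rng(seed)
    entries: list[DatasetEntry] = []

    def subject_slices(subject_id: str, ascites: bool) -> None:
        pocket_slices = np.zeros(slices_per_subject, dtype=bool)
        if ascites:
            pocket_slices = rng.random(slices_per_subject) < pocket_prob
            if not pocket_slices.any():
                pocket_slices[int(rng.integers(slices_per_subject))] = True
        has_bladder = rng.random() < confounder_prob
        has_cyst = rng.random() < confounder_prob
        for s in range(slices_per_subject):
            spec = copy.deepcopy(template)
            spec.seed = int(rng.integers(2**31 - 1))
            pockets: list[AscitesPocket] = []
            if pocket_slices[s]:
                n_pockets = int(rng.integers(1, 3))
                for _ in range(n_pockets):
                    pockets.append(_random_pocket(rng))
            confs: list[Confounder] = []
            if has_bladder and s >= slices_per_subject // 2:
                confs.append(
                    Confounder(
                        "bladder",
                        center=(0.62 + 0.03 * rng.random(), 0.5),
                        semi_axes=(0.09 + 0.03 * rng.random(), 0.11 + 0.03 * rng.random()),
                    )
                )
            if has_cyst and s < slices_per_subject // 2 + 1:
                # > 3 cm diameter: radius fraction > 15 mm / (spacing * grid)
                min_frac = 15.0 / (spec.pixel_spacing_mm * spec.grid_size)
                r = min_frac * (1.1 + 0.6 * rng.random())
                side = 0.30 if rng.random() < 0.5 else 0.70
                confs.append(
                    Confounder(
                        "ovarian_cyst",
                        center=(0.58 + 0.05 * rng.random(), side),
                        semi_axes=(r, r),
                    )
                )
            spec.ascites_pockets = tuple(pockets)
            spec.confounders = tuple(confs)
            # random pocket geometry can graze the body boundary; redraw
            # the pockets (bounded) until the slice is valid
            for _attempt in range(20):
                try:
                    hu, mask = generate_slice(spec)
                    break
                except ValueError:
                    spec.ascites_pockets = tuple(
                        _random_pocket(rng) for _ in range(max(len(pockets), 1))
                    )
            else:
                raise RuntimeError("could not place ascites pockets inside the body")
            hu.subject_id, hu.slice_index = subject_id, s
            entries.append(
                DatasetEntry(
                    subject_id=subject_id,
                    slice_index=s,
                    has_ascites=bool(mask.any()),
                    spec=spec,
                    _hu=hu,
                    _mask=mask,
                )
            )

    for i in range(n_subjects_ascites):
        subject_slices(f"ascites_{i:03d}", True)
    for i in range(n_subjects_control):
        subject_slices(f"control_{i:03d}", False)
    return PhantomDataset(entries)


def _random_pocket(rng: np.random.Generator) -> AscitesPocket:
    """A random flank crescent or dependent blob, graded small-to-large.

    Size strata are arbitrary (no quantitative small/moderate/large
    definition exists for ascites); they span ~0.5% to ~8% of the body
    area so both subtle and gross collections appear.
    """
    kind = rng.random()
    scale = 0.5 + 1.3 * rng.random()  # size grade
    if kind < 0.5:  # flank crescent (left or right)
        side = 0.24 if rng.random() < 0.5 else 0.76
        shift = 0.05 if side < 0.5 else -0.05
        return AscitesPocket(
            center=(0.45 + 0.1 * rng.random(), side),
            semi_axes=(0.09 * scale, 0.065 * scale),
            shape="crescent",
            inner_shift=(0.0, shift),
        )
    # dependent blob (pelvic / perihepatic)
    return AscitesPocket(
        center=(0.35 + 0.3 * rng.random(), 0.35 + 0.3 * rng.random()),
        semi_axes=(0.05 * scale, 0.045 * scale),
        shape="blob",
    )


def naive_fluid_mask(hu: HUSlice, body: np.ndarray | None = None) -> np.ndarray:
    """Threshold segmenter: pixels in the near-water band inside the body.

    Used to demonstrate that intensity alone cannot separate ascites
    from confounder fluid.
    """
    lo, hi = FLUID_HU_RANGE
    m = (hu.pixels >= lo) & (hu.pixels <= hi)
    if body is not None:
        m &= body
    return m.astype(np.uint8)


# ---------------------------------------------------------------------------
# on-disk formats


def write_dataset(
    dataset: PhantomDataset, outdir: str | Path, image_format: str = "dicom"
) -> PhantomDataset:
    """Write slices (DICOM or 16-bit PNG + JSON sidecar), masks (8-bit PNG
    {0, 255}) and a CSV manifest; returns a path-backed dataset."""
    from . import preprocess

    outdir = Path(outdir)
    (outdir / "slices").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    new_entries = []
    for e in dataset.entries:
        if e.augment_of is not None:
            raise ValueError("write_dataset expects un-augmented entries")
        hu, mask = e.load()
        stem = f"{e.subject_id}_{e.slice_index:03d}"
        ext = "dcm" if image_format == "dicom" else "png"
        slice_path = outdir / "slices" / f"{stem}.{ext}"
        mask_path = outdir / "masks" / f"{stem}.png"
        if image_format == "dicom":
            preprocess.write_dicom_slice(hu, slice_path)
        else:
            preprocess.write_png16_slice(hu, slice_path)
        preprocess.write_mask_png(mask, mask_path)
        new_entries.append(
            DatasetEntry(
                subject_id=e.subject_id,
                slice_index=e.slice_index,
                has_ascites=e.has_ascites,
                spec=e.spec,
                slice_path=str(slice_path),
                mask_path=str(mask_path),
                _hu=hu,
                _mask=mask,
            )
        )
    out = PhantomDataset(new_entries)
    out.manifest_frame().to_csv(outdir / "manifest.csv", index=False)
    return out


def read_dataset(root: str | Path) -> PhantomDataset:
    """Load a dataset written by :func:`write_dataset` from its manifest."""
    root = Path(root)
    frame = pd.read_csv(root / "manifest.csv")
    entries = [
        DatasetEntry(
            subject_id=str(row.subject_id),
            slice_index=int(row.slice_index),
            has_ascites=bool(row.has_ascites),
            slice_path=str(row.slice_path),
            mask_path=str(row.mask_path),
        )
        for row in frame.itertuples()
    ]
    return PhantomDataset(entries)
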