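"""Reading and writing CVC-style image/mask datasets.

A dataset directory holds paired RGB images and binary masks, either flat::

    root/images/*.png     root/masks/*.png

or split into one sub-directory per collection (CVC-ClinicDB etc.), each
with its own ``images``/``masks`` folders. Pairing is by filename stem.
Masks are binarised on load (8-bit value > 127 means polyp) and written as
lossless 8-bit PNGs with polyp=255. Pixel coordinates are 0-based,
row-major, (row, col) ordered throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "DatasetRecord",
    "DatasetManifest",
    "SampleRecord",
    "UnpairedFilesError",
    "load_dataset",
    "split_dataset",
    "load_sample",
    "standardize_sample",
    "write_mask",
    "read_mask",
]

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")
DEFAULT_LAYOUT = {"images_subdir": "images", "masks_subdir": "masks"}


class UnpairedFilesError(ValueError):
    """Raised when images and masks cannot be paired one-to-one."""

    def __init__(self, orphan_images: Sequence[str],
                 orphan_masks: Sequence[str]):
        self.orphan_images = sorted(orphan_images)
        self.orphan_masks = sorted(orphan_masks)
        super().__init__(
            "unpaired dataset entries; orphan image stems: "
            f"{self.orphan_images}; orphan mask stems: {self.orphan_masks}")


@dataclass(frozen=True)
class DatasetRecord:
    image_path: str
    mask_path: str
    collection: str
    split: str = "unassigned"  # train | test | unassigned


@dataclass
class DatasetManifest:
    records: List[DatasetRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def collection_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for r in self.records:
            out[r.collection] = out.get(r.collection, 0) + 1
        return out

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.split == split])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        df = pd.read_csv(path)
        return cls([DatasetRecord(r.image_path, r.mask_path, r.collection,
                                  r.split) for r in df.itertuples()])


@dataclass
class SampleRecord:
    """One loaded image/mask pair; image in [0, 1], mask strictly binary."""

    image: np.ndarray  # (H, W, 3) float32
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    native_resolution: Tuple[int, int]
    collection: str = "unknown"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask resolutions differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be strictly binary after loading")


def _collect_stems(folder: Path) -> Dict[str, Path]:
    out: Dict[str, Path] = {}
    for p in sorted(folder.iterdir()):
        if p.suffix.lower() in IMAGE_EXTENSIONS:
            out[p.stem] = p
    return out


def _pair_folder(images_dir: Path, masks_dir: Path, collection: str
                 ) -> List[DatasetRecord]:
    images = _collect_stems(images_dir)
    masks = _collect_stems(masks_dir)
    orphan_images = set(images) - set(masks)
    orphan_masks = set(masks) - set(images)
    if orphan_images or orphan_masks:
        raise UnpairedFilesError(orphan_images, orphan_masks)
    return [DatasetRecord(str(images[s]), str(masks[s]), collection)
            for s in sorted(images)]


def load_dataset(root_dir, layout_config: Optional[dict] = None
                 ) -> DatasetManifest:
    """Build a manifest from a dataset directory (see module docstring)."""
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    layout = dict(DEFAULT_LAYOUT, **(layout_config or {}))
    img_sub, mask_sub = layout["images_subdir"], layout["masks_subdir"]
    records: List[DatasetRecord] = []
    if (root / img_sub).is_dir():
        records += _pair_folder(root / img_sub, root / mask_sub,
                                layout.get("collection", root.name))
    else:
        for sub in sorted(p for p in root.iterdir() if p.is_dir()):
            if (sub / img_sub).is_dir():
                records += _pair_folder(sub / img_sub, sub / mask_sub,
                                        sub.name)
    if not records:
        raise ValueError(f"no image/mask pairs found under {root}")
    return DatasetManifest(records)


def split_dataset(manifest: DatasetManifest, train_fraction: float = 0.7,
                  seed: int = 0,
                  per_collection_counts: Optional[Dict[str, int]] = None
                  ) -> DatasetManifest:
    """Random, seeded, disjoint train/test split of the pooled manifest.

    By default round(train_fraction * n) records are tagged ``train`` and the
    rest ``test``. ``per_collection_counts`` (collection -> training count)
    instead draws exactly that many training records from each collection,
    reproducing a published allocation.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = len(manifest)
    records = list(manifest.records)
    train_idx: set = set()
    if per_collection_counts is None:
        n_train = int(round(train_fraction * n))
        train_idx = set(rng.permutation(n)[:n_train].tolist())
    else:
        by_coll: Dict[str, List[int]] = {}
        for i, r in enumerate(records):
            by_coll.setdefault(r.collection, []).append(i)
        for coll, k in per_collection_counts.items():
            idxs = by_coll.get(coll, [])
            if k > len(idxs):
                raise ValueError(
                    f"requested {k} training records from collection "
                    f"{coll!r} which has only {len(idxs)}")
            chosen = rng.permutation(len(idxs))[:k]
            train_idx.update(idxs[j] for j in chosen)
    out = [dataclasses.replace(r, split="train" if i in train_idx else "test")
           for i, r in enumerate(records)]
    return DatasetManifest(out)


def _binarize(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def load_sample(record: DatasetRecord) -> SampleRecord:
    with Image.open(record.image_path) as im:
        image = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    with Image.open(record.mask_path) as im:
        mask = _binarize(np.asarray(im.convert("L")))
    return SampleRecord(image=image, mask=mask,
                        native_resolution=image.shape[:2],
                        collection=record.collection)


def standardize_sample(sample: SampleRecord,
                       target_resolution: Tuple[int, int]) -> SampleRecord:
    """Resize to (height, width): bilinear for the image, nearest-neighbour
    for the mask, which is re-binarised so values stay exactly {0, 1}."""
    th, tw = int(target_resolution[0]), int(target_resolution[1])
    if th < 1 or tw < 1:
        raise ValueError("target resolution must be positive")
    if sample.image.shape[:2] == (th, tw):
        return sample
    img8 = np.clip(np.rint(sample.image * 255.0), 0, 255).astype(np.uint8)
    image = np.asarray(
        Image.fromarray(img8).resize((tw, th), Image.BILINEAR),
        dtype=np.float32) / 255.0
    mask = np.asarray(
        Image.fromarray(sample.mask * 255).resize((tw, th), Image.NEAREST))
    return SampleRecord(image=image, mask=_binarize(mask),
                        native_resolution=sample.native_resolution,
                        collection=sample.collection)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as lossless 8-bit grayscale PNG (polyp=255)."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("write_mask requires a strictly binary mask")
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(
        path, format="PNG")


def read_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        return _binarize(np.asarray(im.convert("L")))


def samples_to_arrays(manifest: DatasetManifest,
                      target_resolution: Optional[Tuple[int, int]] = None
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Load a manifest into training arrays (N, 3, H, W) / (N, H, W)."""
    images, masks = [], []
    for record in manifest:
        s = load_sample(record)
        if target_resolution is not None:
            s = standardize_sample(s, target_resolution)
        images.append(s.image.transpose(2, 0, 1))
        masks.append(s.mask)
    return np.stack(images), np.stack(masks)
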