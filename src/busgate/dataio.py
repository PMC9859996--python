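"""Dataset I/O, preprocessing, augmentation and cross-validation folds.

Images are 8-bit grayscale PNGs with strictly binary {0, 255} masks,
indexed by a CSV manifest (`image_path,mask_path,label,patient_id,
lesion_class`, paths relative to the manifest). Preprocessing mirrors the
training protocol: resize to a square target and map intensities affinely
from [0, 255] to [-1, 1]; masks are resized with nearest-neighbor so they
stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from .phantom import SegSample

__all__ = ["Manifest", "FoldSplit", "load_manifest", "save_manifest",
           "preprocess", "preprocess_mask", "augment", "make_folds",
           "samples_to_arrays"]

_VALID_LABELS = {"normal", "abnormal"}


@dataclass
class Manifest:
    """Ordered record list backing a dataset; records are `SegSample`s
    whose pixel data may be lazily absent (paths only) until loaded."""

    records: list[SegSample]
    root: Path

    def __len__(self):
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([r.patient_id for r in self.records])


@dataclass(frozen=True)
class FoldSplit:
    k: int
    assignments: np.ndarray  # record index -> fold index in [0, k)

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, val_idx) for one rotation: `fold` is held out."""
        val = np.where(self.assignments == fold)[0]
        train = np.where(self.assignments != fold)[0]
        return train, val

    def save(self, path) -> None:
        pd.DataFrame({"record_index": np.arange(len(self.assignments)),
                      "fold": self.assignments}).to_csv(path, index=False)


def load_manifest(path) -> Manifest:
    """Read a manifest CSV; verifies files exist and labels are valid."""
    path = Path(path)
    root = path.parent
    df = pd.read_csv(path, dtype=str)
    required = {"image_path", "mask_path", "label", "patient_id"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest missing columns {required - set(df.columns)}")
    records = []
    for row in df.itertuples(index=False):
        if row.label not in _VALID_LABELS:
            raise ValueError(f"invalid label {row.label!r}")
        img_p, mask_p = root / row.image_path, root / row.mask_path
        for p in (img_p, mask_p):
            if not p.exists():
                raise FileNotFoundError(p)
        lesion_class = getattr(row, "lesion_class", "none")
        image = np.asarray(iio.imread(img_p))
        raw_mask = np.asarray(iio.imread(mask_p))
        if not set(np.unique(raw_mask)) <= {0, 255}:
            raise ValueError(f"mask {mask_p} is not strictly {{0,255}}")
        mask = (raw_mask > 0).astype(np.uint8)
        records.append(SegSample(
            image=image, mask=mask, label=row.label,
            patient_id=row.patient_id, lesion_class=lesion_class,
            image_path=str(row.image_path), mask_path=str(row.mask_path)))
    return Manifest(records=records, root=root)


def save_manifest(manifest: Manifest, path) -> Path:
    path = Path(path)
    rows = [{"image_path": r.image_path, "mask_path": r.mask_path,
             "label": r.label, "patient_id": r.patient_id,
             "lesion_class": r.lesion_class} for r in manifest.records]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def preprocess(image: np.ndarray, target_size: int) -> np.ndarray:
    """Resize to target_size x target_size and map [0,255] -> [-1,1]."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:  # collapse an incidental color axis
        image = image.mean(axis=2)
    resized = resize(image.astype(np.float64), (target_size, target_size),
                     order=1, mode="edge", anti_aliasing=False,
                     preserve_range=True)
    return (resized / 127.5 - 1.0).astype(np.float32)


def preprocess_mask(mask: np.ndarray, target_size: int) -> np.ndarray:
    """Nearest-neighbor resize keeping the mask strictly binary."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    resized = resize((mask > 0).astype(np.float64),
                     (target_size, target_size), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return (resized > 0.5).astype(np.uint8)


def augment(sample: SegSample, flip_probability: float,
            rng: np.random.Generator) -> SegSample:
    """Random horizontal flip applied jointly to image and mask."""
    if not 0.0 <= flip_probability <= 1.0:
        raise ValueError("flip_probability must be in [0, 1]")
    if rng.uniform() < flip_probability:
        return SegSample(image=sample.image[:, ::-1].copy(),
                         mask=sample.mask[:, ::-1].copy(),
                         label=sample.label, patient_id=sample.patient_id,
                         lesion_class=sample.lesion_class,
                         image_path=sample.image_path,
                         mask_path=sample.mask_path)
    return sample


def make_folds(manifest: Manifest, k: int, seed: int,
               grouping: str = "image") -> FoldSplit:
    """Seeded random partition into k folds.

    grouping="image": record-level shuffle + round-robin, so fold sizes
    differ by at most one. grouping="patient": patients are shuffled and
    each assigned greedily to the currently smallest fold, keeping all of
    a patient's images together (no cross-fold leakage).
    """
    n = len(manifest)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=np.int64)
    if grouping == "image":
        if k > n:
            raise ValueError(f"k={k} exceeds number of records {n}")
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            assignments[idx] = pos % k
    elif grouping == "patient":
        patients = manifest.patient_ids
        unique = sorted(set(patients))
        if k > len(unique):
            raise ValueError(f"k={k} exceeds number of patients {len(unique)}")
        order = rng.permutation(len(unique))
        fold_sizes = np.zeros(k, dtype=np.int64)
        for pi in order:
            pid = unique[pi]
            members = np.where(patients == pid)[0]
            fold = int(np.argmin(fold_sizes))
            assignments[members] = fold
            fold_sizes[fold] += len(members)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return FoldSplit(k=k, assignments=assignments)


def samples_to_arrays(records: list[SegSample], image_size: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stack records into model-ready (X, y) arrays.

    X: (n, S, S) float32 in [-1, 1]; y: (n, S, S) uint8 binary masks.
    """
    xs = np.stack([preprocess(r.image, image_size) for r in records])
    ys = np.stack([preprocess_mask(r.mask, image_size) for r in records])
    return xs, ys
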