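"""Dataset plumbing between manifests and model inputs.

An :class:`ImageDataset` binds manifest rows to standardized model inputs.
Frames are either rendered on the fly from the generator's stored seeds
(``path`` empty) or read from disk, then center-cropped and standardized to
224 x 224 x 3. Stem-pooled tensors are cached so repeated training runs over
the same pool (seed sweeps, fraction sweeps, regime comparisons) pay the
image pipeline cost once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classes import CLASS_ORDER, MorphClass
from .nn import CompactCNN
from .preprocess import center_crop_square, load_image, to_model_input
from .synth import DomainParams, default_domains, domains_by_key, render_record

_CLASS_INDEX = {c.value: i for i, c in enumerate(CLASS_ORDER)}


def labels_to_indices(labels) -> np.ndarray:
    """Map class labels (strings or MorphClass) to canonical indices."""
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        key = lab.value if isinstance(lab, MorphClass) else str(lab)
        if key not in _CLASS_INDEX:
            raise KeyError(f"unknown class label {lab!r}")
        out[i] = _CLASS_INDEX[key]
    return out


class ImageDataset:
    """Lazy model-input view over a manifest.

    ``ds[i]`` yields the i-th row's 224 x 224 x 3 standardized input;
    ``ds.stem_array()`` yields (and caches) the (N, 1, 28, 28) stem tensor
    consumed by the compact backbone; ``ds.labels`` gives integer class
    indices in canonical order.
    """

    def __init__(
        self,
        manifest: pd.DataFrame,
        doms: list[DomainParams] | dict | None = None,
        canvas: int = 96,
    ):
        self.manifest = manifest.reset_index(drop=True)
        self.dom_map = (
            doms
            if isinstance(doms, dict)
            else domains_by_key(doms if doms is not None else default_domains())
        )
        self.canvas = canvas
        self._stem: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.manifest)

    def raw_image(self, i: int) -> np.ndarray:
        row = self.manifest.iloc[i]
        raw_path = row.get("path", "")
        path = "" if pd.isna(raw_path) else str(raw_path)
        if path:
            return load_image(path)
        img, _ = render_record(row, self.dom_map, canvas=self.canvas)
        return img

    def __getitem__(self, i: int) -> np.ndarray:
        return to_model_input(center_crop_square(self.raw_image(i)))

    @property
    def labels(self) -> np.ndarray:
        return labels_to_indices(np.asarray(self.manifest["label"]))

    def stem_array(self, batch: int = 256) -> np.ndarray:
        if self._stem is None:
            chunks = []
            for start in range(0, len(self), batch):
                block = np.stack(
                    [self[i] for i in range(start, min(start + batch, len(self)))]
                )
                chunks.append(CompactCNN.stem(block))
            self._stem = (
                np.concatenate(chunks)
                if chunks
                else np.empty((0, 1, 28, 28), dtype=np.float32)
            )
        return self._stem

    def subset(self, manifest_subset: pd.DataFrame) -> "ImageDataset":
        """View over a subset of rows, reusing cached stem tensors.

        ``manifest_subset`` must be a row-subset of this dataset's manifest
        (matched by image_id).
        """
        child = ImageDataset(manifest_subset, self.dom_map, self.canvas)
        if self._stem is not None:
            lut = pd.Series(
                np.arange(len(self.manifest)),
                index=self.manifest["image_id"].to_numpy(),
            )
            pos = lut.loc[manifest_subset["image_id"].to_numpy()].to_numpy()
            child._stem = self._stem[pos]
        return child


def augmented_inputs(
    dataset,
    policy,
    split_tag: str,
    rng_seed: int = 0,
) -> np.ndarray:
    """One stochastic augmentation per record, training split only.

    Augmentation is part of the training-time pipeline exclusively; calling
    this on any other split is a protocol violation and raises.
    """
    from .preprocess import augment

    if split_tag != "train":
        raise ValueError(
            f"augmentation is restricted to the 'train' split, got {split_tag!r}"
        )
    rng = np.random.default_rng(rng_seed)
    return np.stack([augment(dataset[i], policy, rng) for i in range(len(dataset))])


def as_stem_and_labels(data) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a (inputs, labels) pair or ImageDataset to stem tensors.

    Accepts an ImageDataset, or a tuple (X, y) where X is an array of model
    inputs (N, 224, 224, 3) / raw grayscale frames and y is a label vector.
    """
    if isinstance(data, ImageDataset):
        return data.stem_array(), data.labels
    x, y = data
    if isinstance(x, ImageDataset):
        return x.stem_array(), labels_to_indices(np.asarray(y))
    x = np.asarray(x)
    if x.ndim == 4 and x.shape[1:] == (224, 224, 3):
        stems = CompactCNN.stem(x)
    elif x.ndim == 4 and x.shape[1:] == (1, 28, 28):
        stems = x.astype(np.float32)
    else:
        raise ValueError(
            f"expected model inputs (N,224,224,3) or stem tensors, got {x.shape}"
        )
    y = np.asarray(y)
    if y.dtype.kind in "iu":
        return stems, y.astype(np.int64)
    return stems, labels_to_indices(y)
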