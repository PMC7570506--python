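"""Per-pixel patch extraction from score-image stacks or hypercubes.

Every foreground pixel yields one ``k x k x d`` patch centered on it.  Pixels
near the sample edge naturally include background voxels (value 0); pixels
near the *image* border are handled by zero-padding the stack by
``(k-1)/2`` on each side, keeping both edge cases consistent with the 0
background fill used by score projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from hsipix.core_io import Hypercube, LabelImage

__all__ = ["PatchSet", "extract_patches", "extract_patches_3d",
           "subsample_every", "iter_patch_batches"]


@dataclass
class PatchSet:
    """Stack of per-pixel patches with center coordinates and labels.

    ``patches`` is stored sample-first, ``(n, k, k, d)``; label 0 is only
    meaningful at predict time (unknown class).
    """

    patches: np.ndarray        # (n, k, k, d)
    centers: np.ndarray        # (n, 2)
    labels: np.ndarray         # (n,)
    k: int
    d: int

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError("window size k must be odd")
        n = self.patches.shape[0]
        if not (len(self.centers) == n and len(self.labels) == n):
            raise ValueError("patches, centers and labels must agree in length")
        if self.patches.shape[1:] != (self.k, self.k, self.d):
            raise ValueError(
                f"patch array shape {self.patches.shape[1:]} != ({self.k}, {self.k}, {self.d})")

    @property
    def n(self) -> int:
        return self.patches.shape[0]

    def save(self, path) -> None:
        np.savez_compressed(path, patches=self.patches, centers=self.centers,
                            labels=self.labels, k=self.k, d=self.d)

    @staticmethod
    def load(path) -> "PatchSet":
        with np.load(path) as z:
            return PatchSet(z["patches"], z["centers"], z["labels"],
                            int(z["k"]), int(z["d"]))

    def centers_labels_frame(self):
        """Centers and labels as a DataFrame for CSV audit export."""
        import pandas as pd

        return pd.DataFrame({"row": self.centers[:, 0], "col": self.centers[:, 1],
                             "label": self.labels})


def _windows(stack: np.ndarray, mask: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Gather k x k windows around each foreground pixel (zero-padded)."""
    half = (k - 1) // 2
    padded = np.pad(stack, ((half, half), (half, half), (0, 0)))
    rr, cc = np.nonzero(mask)
    view = np.lib.stride_tricks.sliding_window_view(padded, (k, k), axis=(0, 1))
    # view[r, c] is the k x k window whose top-left sits at padded (r, c),
    # i.e. the window centered on original pixel (r, c)
    patches = view[rr, cc]                       # (n, d, k, k)
    patches = np.ascontiguousarray(patches.transpose(0, 2, 3, 1))
    return patches, np.stack([rr, cc], axis=1)


def extract_patches(stack: np.ndarray, mask: np.ndarray,
                    labels: Optional[LabelImage] = None, k: int = 7,
                    dtype=np.float32) -> PatchSet:
    """One ``k x k x d`` patch per foreground pixel of a score stack.

    ``labels=None`` yields label 0 everywhere (predict-time patches).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (x, y, d)")
    if k % 2 == 0 or k < 1:
        raise ValueError(f"window size k must be a positive odd integer, got {k}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape[:2]:
        raise ValueError("mask shape does not match stack spatial shape")
    if not mask.any():
        raise ValueError("no foreground pixels to extract patches from")
    patches, centers = _windows(stack.astype(dtype, copy=False), mask, k)
    if labels is not None:
        lab = labels.labels[centers[:, 0], centers[:, 1]].astype(np.int32)
    else:
        lab = np.zeros(len(centers), dtype=np.int32)
    return PatchSet(patches=patches, centers=centers, labels=lab,
                    k=k, d=stack.shape[2])


def extract_patches_3d(cube: Hypercube, k: int = 7,
                       labels: Optional[LabelImage] = None,
                       dtype=np.float32) -> PatchSet:
    """Spectral-spatial ``k x k x bands`` patches straight from a hypercube."""
    if cube.mask is None:
        raise ValueError("cube needs a foreground mask for patch extraction")
    return extract_patches(cube.data, cube.mask, labels=labels, k=k, dtype=dtype)


def subsample_every(patchset: PatchSet, m: int) -> PatchSet:
    """Keep every m-th observation (index mod m == 0), preserving order.

    The standard remedy when a full 3-D patch training set exceeds memory;
    ``n_out = ceil(n / m)``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    sel = slice(None, None, m)
    return PatchSet(patches=patchset.patches[sel], centers=patchset.centers[sel],
                    labels=patchset.labels[sel], k=patchset.k, d=patchset.d)


def iter_patch_batches(stack: np.ndarray, mask: np.ndarray, k: int,
                       batch_size: int = 2048,
                       dtype=np.float32) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Lazily yield ``(patches, centers)`` batches without materializing all.

    Memory-safe path for predict-time extraction from large cubes (the 3-D
    case easily exhausts RAM if materialized eagerly).
    """
    stack = np.asarray(stack).astype(dtype, copy=False)
    half = (k - 1) // 2
    padded = np.pad(stack, ((half, half), (half, half), (0, 0)))
    view = np.lib.stride_tricks.sliding_window_view(padded, (k, k), axis=(0, 1))
    rr, cc = np.nonzero(np.asarray(mask, dtype=bool))
    for start in range(0, len(rr), batch_size):
        r = rr[start:start + batch_size]
        c = cc[start:start + batch_size]
        batch = np.ascontiguousarray(view[r, c].transpose(0, 2, 3, 1))
        yield batch, np.stack([r, c], axis=1)
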