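"""Hypercube container, ENVI / portable-container I/O, unfolding and refolding.

A hypercube ``I(x, y, lambda)`` is stored as a float64 array of shape
``(rows, cols, bands)`` together with its wavelength vector in nm.  Pixel
spectra are moved between the image domain and the flat ``(pixels x bands)``
matrix domain by :func:`unfold` / :func:`refold`; all downstream chemometric
models operate on the flat matrix, and classification maps come back through
refolding.

Coordinates are 0-based ``(row, col)`` and scan order is row-major
throughout, so training-set ordering is reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Hypercube", "FlatSpectra", "LabelImage",
    "read_cube", "write_cube", "band_index", "unfold", "refold",
    "label_from_scene", "write_label_tiff",
]


# ENVI data-type codes <-> numpy dtypes (the subset a reflectance camera emits)
_ENVI_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2", 13: "u4"}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class Hypercube:
    """Reflectance image cube with wavelength metadata.

    Parameters
    ----------
    data
        Reflectance array, shape ``(rows, cols, bands)``.  Dimensionless,
        typically in [0, ~1.2]; specular-saturated pixels may exceed 1.
    wavelengths
        Band centers in nm, strictly increasing, one per band.
    mask
        Optional boolean foreground image of shape ``(rows, cols)``.
    label
        Optional scene-level class name (single-object scenes).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    mask: Optional[np.ndarray] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (rows, cols, bands); got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths.size} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.isnan(self.data).any():
            raise ValueError("hypercube contains NaN reflectance values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match spatial shape {self.data.shape[:2]}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class FlatSpectra:
    """Unfolded pixel spectra: ``values[i]`` is the spectrum at ``coords[i]``.

    ``feature_axis`` carries either wavelengths in nm or PC indices so a flat
    matrix always knows what its columns mean; ``source_shape`` enables
    lossless refolding.
    """

    values: np.ndarray
    coords: np.ndarray          # (n, 2) int, 0-based (row, col)
    source_shape: tuple[int, int]
    feature_axis: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.intp)
        self.feature_axis = np.asarray(self.feature_axis)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (pixels x features)")
        if self.coords.shape != (self.values.shape[0], 2):
            raise ValueError("coords must be (n_pixels, 2) and match values rows")
        r, c = self.source_shape
        if self.coords.size and (
            self.coords.min() < 0
            or self.coords[:, 0].max() >= r
            or self.coords[:, 1].max() >= c
        ):
            raise ValueError("coords fall outside source_shape")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]


@dataclass
class LabelImage:
    """Integer label image: 0 = background, 1..C = classes."""

    labels: np.ndarray
    class_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative (0 = background)")
        if self.class_names and self.labels.max() > len(self.class_names):
            raise ValueError(
                f"label {self.labels.max()} exceeds the {len(self.class_names)} named classes"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_names) if self.class_names else int(self.labels.max())


# ---------------------------------------------------------------------------
# ENVI format


def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI ASCII header into a dict (keys lower-cased).

    Values in ``{ }`` become lists of strings; scalars stay strings.
    """
    fields: dict = {}
    # join brace-delimited multi-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI" or "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{"):
            inner = val.strip("{}").strip()
            fields[key] = [v.strip() for v in inner.split(",") if v.strip()]
        else:
            fields[key] = val
    return fields


def _read_envi(path: Path) -> Hypercube:
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"no ENVI header found for {path}")
    hdr = _parse_envi_header(hdr_path.read_text())

    for required in ("samples", "lines", "bands"):
        if required not in hdr:
            raise ValueError(f"ENVI header missing required field '{required}'")
    if "wavelength" not in hdr:
        raise ValueError("ENVI header missing required field 'wavelength'")

    samples = int(hdr["samples"])   # columns
    lines = int(hdr["lines"])       # rows
    bands = int(hdr["bands"])
    interleave = hdr.get("interleave", "bsq").lower()
    dcode = int(hdr.get("data type", 4))
    if dcode not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dcode}")
    dtype = np.dtype(_ENVI_DTYPES[dcode])
    if int(hdr.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")

    raw = np.fromfile(path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"ENVI payload has {raw.size} elements but header declares "
            f"{lines}x{samples}x{bands} = {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave '{interleave}' (expected bil/bip/bsq)")

    wavelengths = np.array([float(w) for w in hdr["wavelength"]])
    if wavelengths.size != bands:
        raise ValueError(
            f"header lists {wavelengths.size} wavelengths for {bands} bands"
        )
    return Hypercube(data=data.astype(np.float64), wavelengths=wavelengths)


def _write_envi(cube: Hypercube, path: Path, interleave: str = "bsq",
                dtype: str = "f8") -> None:
    interleave = interleave.lower()
    rows, cols, bands = cube.shape
    arr = cube.data.astype(np.dtype(dtype))
    if interleave == "bsq":
        payload = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        payload = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        payload = arr
    else:
        raise ValueError(f"unknown interleave '{interleave}'")
    payload = np.ascontiguousarray(payload)
    payload.tofile(path)
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)


# ---------------------------------------------------------------------------
# Portable container (single .npz with named arrays)


def _read_npz(path: Path) -> Hypercube:
    with np.load(path, allow_pickle=False) as z:
        if "wavelengths" not in z:
            raise ValueError("container missing required array 'wavelengths'")
        data = z["data"]
        wavelengths = z["wavelengths"]
        mask = z["mask"].astype(bool) if "mask" in z else None
        label = str(z["label"]) if "label" in z else None
    if data.shape[2] != wavelengths.size:
        raise ValueError(
            f"container declares {wavelengths.size} wavelengths for "
            f"{data.shape[2]} bands"
        )
    return Hypercube(data=data, wavelengths=wavelengths, mask=mask, label=label)


def _write_npz(cube: Hypercube, path: Path,
               labels: Optional["LabelImage"] = None) -> None:
    arrays = {"data": cube.data, "wavelengths": cube.wavelengths}
    if cube.mask is not None:
        arrays["mask"] = cube.mask
    if cube.label is not None:
        arrays["label"] = np.asarray(cube.label)
    if labels is not None:
        arrays["labels"] = labels.labels
        arrays["class_names"] = np.asarray(list(labels.class_names), dtype="U64")
    np.savez_compressed(path, **arrays)


def read_cube(path, format: Optional[str] = None) -> Hypercube:
    """Read a hypercube from ENVI (header + binary) or the portable container.

    ``format`` is inferred from the extension when omitted (``.npz`` →
    container, anything else → ENVI).  All three ENVI interleaves (BIL, BIP,
    BSQ) load to the same in-memory ``(rows, cols, bands)`` layout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "envi"
    if format == "envi":
        return _read_envi(path)
    if format in ("npz", "npz-container", "container"):
        return _read_npz(path)
    raise ValueError(f"unknown format '{format}' (expected 'envi' or 'npz')")


def write_cube(cube: Hypercube, path, format: Optional[str] = None,
               interleave: str = "bsq",
               labels: Optional["LabelImage"] = None) -> None:
    """Write a hypercube as ENVI or as the portable ``.npz`` container.

    The container can optionally carry a pixel-label image and its class
    names (read back with :func:`read_labels`); ENVI cannot.
    """
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "envi"
    if format == "envi":
        if labels is not None:
            raise ValueError("ENVI files cannot carry label images; "
                             "use the npz container or a label TIFF")
        _write_envi(cube, path, interleave=interleave)
    elif format in ("npz", "npz-container", "container"):
        _write_npz(cube, path, labels=labels)
    else:
        raise ValueError(f"unknown format '{format}'")


def read_labels(path) -> Optional[LabelImage]:
    """Read the label image stored in a portable container, if any."""
    with np.load(Path(path), allow_pickle=False) as z:
        if "labels" not in z:
            return None
        names = [str(n) for n in z["class_names"]] if "class_names" in z else []
        return LabelImage(labels=z["labels"], class_names=names)


# ---------------------------------------------------------------------------
# Band arithmetic and (un)folding


def band_index(wavelengths: np.ndarray, target: float) -> int:
    """Index of the band center nearest ``target`` (nm); ties break low.

    A target farther than one median band spacing outside the grid is
    rejected — asking for 1496 nm on a visible-range cube is a usage error,
    not a nearest-neighbour query.
    """
    w = np.asarray(wavelengths, dtype=float)
    if w.size == 0:
        raise ValueError("empty wavelength vector")
    if w.size > 1 and not np.all(np.diff(w) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    spacing = float(np.median(np.diff(w))) if w.size > 1 else 0.0
    if target < w[0] - spacing or target > w[-1] + spacing:
        raise ValueError(
            f"target {target} nm outside wavelength range "
            f"[{w[0]:g}, {w[-1]:g}] nm (± one band spacing)"
        )
    # argmin returns the first occurrence, which is the lower index on ties
    return int(np.argmin(np.abs(w - target)))


def unfold(cube: Hypercube, use_mask: bool = True) -> FlatSpectra:
    """Unfold a cube to a ``(pixels x bands)`` matrix in row-major scan order.

    With ``use_mask`` (and a mask present) only foreground pixels are
    retained; their coordinates are recorded for refolding.
    """
    rows, cols, _ = cube.shape
    if use_mask and cube.mask is not None:
        mask = cube.mask
        if not mask.any():
            raise ValueError("mask retains no foreground pixels")
    elif use_mask and cube.mask is None:
        raise ValueError("use_mask=True but the cube has no mask")
    else:
        mask = np.ones((rows, cols), dtype=bool)
    rr, cc = np.nonzero(mask)  # nonzero scans row-major
    values = cube.data[rr, cc, :]
    coords = np.stack([rr, cc], axis=1)
    return FlatSpectra(values=values, coords=coords,
                       source_shape=(rows, cols),
                       feature_axis=cube.wavelengths.copy())


def refold(flat: FlatSpectra, values: Optional[np.ndarray] = None,
           fill: float = 0.0) -> np.ndarray:
    """Place per-pixel rows back at their coordinates; elsewhere ``fill``.

    ``values`` defaults to ``flat.values``.  A single column refolds to an
    ``(x, y, 1)`` stack, e.g. a classification map from predicted classes.
    """
    if values is None:
        values = flat.values
    values = np.asarray(values)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] != flat.n_pixels:
        raise ValueError(
            f"values has {values.shape[0]} rows for {flat.n_pixels} recorded pixels"
        )
    rows, cols = flat.source_shape
    out = np.full((rows, cols, values.shape[1]), fill, dtype=values.dtype)
    out[flat.coords[:, 0], flat.coords[:, 1], :] = values
    return out


def label_from_scene(cube: Hypercube, class_id: int,
                     class_names: Sequence[str] = ()) -> LabelImage:
    """Ground truth for a single-object scene: ``class_id`` on the mask.

    Mirrors direct labelling of one-class cubes after background removal.
    """
    if cube.mask is None:
        raise ValueError("cube has no foreground mask")
    if class_id < 1:
        raise ValueError("class_id must be >= 1 (0 is reserved for background)")
    labels = np.where(cube.mask, class_id, 0).astype(np.int32)
    return LabelImage(labels=labels, class_names=list(class_names))


def write_label_tiff(label: LabelImage, path) -> None:
    """Export a label image as a single-band integer TIFF."""
    import tifffile

    tifffile.imwrite(str(path), label.labels.astype(np.int32))
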