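"""Background masking and chemometric spectral pre-treatments.

Three pre-treatments commonly used on NIR reflectance spectra are provided:

* **SNV** (standard normal variate) — per-spectrum centering and scaling to
  unit standard deviation, removing multiplicative scatter and baseline
  offsets caused by variable sample surface properties.
* **Savitzky-Golay first derivative** — local polynomial least-squares
  differentiation per spectrum, suppressing additive baseline effects.
* **EPO** (external parameter orthogonalization) — projection of spectra
  onto the orthogonal complement of a "parasitic" subspace estimated from
  interference spectra (e.g. per-sample mean spectra dominated by thickness
  or batch effects).

Treatments compose through :class:`PreprocessChain`, which is serializable so
the exact fitted state applied to training spectra is replayed on test
spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from hsipix.core_io import Hypercube, band_index, refold, unfold

__all__ = [
    "EPOModel", "PreprocessChain", "background_mask", "snv",
    "sg_first_derivative", "epo_fit", "epo_apply", "apply_chain",
    "preprocess_cube", "EmptyMaskWarning",
]


class EmptyMaskWarning(UserWarning):
    """Background removal produced an empty foreground."""


def background_mask(cube: Hypercube, high_nm: float, low_nm: float,
                    threshold: float, store: bool = True) -> np.ndarray:
    """Foreground mask by band difference: ``R[high] - R[low] > threshold``.

    Subtracting a low-reflectance band from a high-reflectance band enhances
    sample/background contrast before a simple threshold.  Presets used for
    the two study scenarios: sweets 957/1496 nm at 0.22; salmon 944/1450 nm
    at 0.2.

    An empty mask raises :class:`EmptyMaskWarning` (a warning, not an error:
    per-cube threshold overrides are legitimate and the caller decides).
    """
    hi = band_index(cube.wavelengths, high_nm)
    lo = band_index(cube.wavelengths, low_nm)
    diff = cube.data[:, :, hi] - cube.data[:, :, lo]
    mask = diff > threshold
    if not mask.any():
        warnings.warn(
            f"background_mask({high_nm=}, {low_nm=}, {threshold=}) retained "
            "no foreground pixels", EmptyMaskWarning, stacklevel=2)
    if store:
        cube.mask = mask
    return mask


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row to zero mean and unit sample sd.

    Uses the (n-1)-denominator sample standard deviation (the dominant
    chemometric convention).  Rows with sd below 1e-12 are degenerate —
    constant spectra carry no shape information to normalize — and raise.
    """
    X = np.asarray(spectra, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("snv expects an (n x bands) matrix with >= 2 bands")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.nonzero(sd[:, 0] < 1e-12)[0]
    if bad.size:
        raise ValueError(f"snv: row(s) {bad[:5].tolist()} have (near-)zero variance")
    return (X - mu) / sd


def sg_first_derivative(spectra: np.ndarray, window: int = 11,
                        polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay first derivative per row, w.r.t. band index.

    The half-window of bands at each end has no full SG support; those edge
    bands are dropped rather than padded (padding would fabricate spectral
    values), so the output has ``bands - window + 1`` columns.

    The derivative is taken with respect to band index (unit spacing); a
    uniform nm spacing only contributes a constant factor, irrelevant to
    classifiers downstream.
    """
    X = np.asarray(spectra, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected an (n x bands) matrix")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if X.shape[1] < window:
        raise ValueError(f"{X.shape[1]} bands < window {window}")
    half = (window - 1) // 2
    full = savgol_filter(X, window, polyorder, deriv=1, axis=1)
    return full[:, half:X.shape[1] - half]


@dataclass
class EPOModel:
    """Fitted EPO operator: parasitic basis ``V`` and projection ``P = I - V Vᵀ``.

    ``interference_loadings`` has orthonormal columns spanning the parasitic
    subspace; ``projection`` is the symmetric idempotent projector onto its
    orthogonal complement.
    """

    interference_loadings: np.ndarray   # (bands x c)
    n_components: int
    projection: np.ndarray              # (bands x bands)

    def __post_init__(self) -> None:
        V = self.interference_loadings
        if np.abs(V.T @ V - np.eye(V.shape[1])).max() > 1e-10:
            raise ValueError("interference loadings are not orthonormal")
        P = self.projection
        if np.abs(P @ P - P).max() > 1e-8 or np.abs(P - P.T).max() > 1e-8:
            raise ValueError("projection is not a symmetric idempotent")


def epo_fit(interference_spectra: np.ndarray, n_components: int = 1) -> EPOModel:
    """Estimate the parasitic subspace from interference spectra.

    ``V`` holds the first ``n_components`` right singular vectors of the
    column-centered interference matrix (centering isolates the directions
    of *variation* of the external influence).  With per-sample mean spectra
    as the interference — the usual choice when thickness or batch effects
    dominate — one component usually captures the parasitic direction.
    """
    D = np.asarray(interference_spectra, dtype=np.float64)
    if D.ndim != 2:
        raise ValueError("interference_spectra must be (m x bands)")
    m, p = D.shape
    if not 1 <= n_components <= m:
        raise ValueError(f"need 1 <= n_components <= {m}, got {n_components}")
    Dc = D - D.mean(axis=0, keepdims=True)
    _, s, Vt = np.linalg.svd(Dc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds interference matrix rank {rank}")
    V = Vt[:n_components].T                      # (bands x c)
    P = np.eye(p) - V @ V.T
    return EPOModel(interference_loadings=V, n_components=n_components, projection=P)


def epo_apply(spectra: np.ndarray, model: EPOModel) -> np.ndarray:
    """Project spectra onto the orthogonal complement of the parasitic basis."""
    X = np.asarray(spectra, dtype=np.float64)
    p = model.projection.shape[0]
    if X.ndim != 2 or X.shape[1] != p:
        raise ValueError(f"spectra must have {p} bands to match the EPO model")
    return X @ model.projection


# ---------------------------------------------------------------------------
# Chains

_STEP_NAMES = ("snv", "sg_derivative", "epo")


@dataclass
class PreprocessChain:
    """Ordered, replayable sequence of pre-treatment steps.

    Each step is ``("snv", {})``, ``("sg_derivative", {"window": w,
    "polyorder": o})`` or ``("epo", {"model": EPOModel})``.  Order matters:
    "SG then SNV" and "SNV then SG" are different treatments, and both are
    expressible.  :meth:`to_config` emits a human-readable description
    stored alongside trained models (the EPO basis is serialized with the
    model container, not the config).
    """

    steps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, params in self.steps:
            if name not in _STEP_NAMES:
                raise ValueError(f"unknown step '{name}'; valid: {_STEP_NAMES}")
            if name == "epo" and not isinstance(params.get("model"), EPOModel):
                raise ValueError("epo step requires a fitted EPOModel under 'model'")

    def to_config(self) -> list[dict]:
        out = []
        for name, params in self.steps:
            if name == "epo":
                out.append({"step": "epo",
                            "n_components": params["model"].n_components})
            else:
                out.append({"step": name, **params})
        return out

    def output_bands(self, n_bands: int) -> int:
        for name, params in self.steps:
            if name == "sg_derivative":
                n_bands = n_bands - params.get("window", 11) + 1
        return n_bands

    @staticmethod
    def parse(names: str, epo_model: Optional[EPOModel] = None,
              window: int = 11, polyorder: int = 3) -> "PreprocessChain":
        """Build a chain from a compact string like ``"sg+snv"`` or ``"epo"``."""
        steps: list = []
        for token in filter(None, (t.strip().lower() for t in names.split("+"))):
            if token in ("raw", "none"):
                continue
            elif token == "snv":
                steps.append(("snv", {}))
            elif token in ("sg", "sg_derivative", "deriv"):
                steps.append(("sg_derivative", {"window": window, "polyorder": polyorder}))
            elif token == "epo":
                if epo_model is None:
                    raise ValueError("chain requests epo but no EPOModel was provided")
                steps.append(("epo", {"model": epo_model}))
            else:
                raise ValueError(f"unknown pre-treatment '{token}'")
        return PreprocessChain(steps=steps)


def apply_chain(spectra: np.ndarray, chain: PreprocessChain) -> np.ndarray:
    """Apply chain steps in order; an empty chain is the identity."""
    X = np.asarray(spectra, dtype=np.float64)
    for i, (name, params) in enumerate(chain.steps):
        try:
            if name == "snv":
                X = snv(X)
            elif name == "sg_derivative":
                X = sg_first_derivative(X, **params)
            elif name == "epo":
                X = epo_apply(X, params["model"])
        except ValueError as exc:
            raise ValueError(f"chain step {i} ({name}): {exc}") from exc
    return X


def preprocess_cube(cube: Hypercube, chain: PreprocessChain) -> Hypercube:
    """Apply a chain to a cube's foreground spectra and refold.

    SG derivative shrinks the band axis; the wavelength vector is cropped
    symmetrically to the retained bands.  Background pixels become 0.
    """
    flat = unfold(cube, use_mask=cube.mask is not None)
    values = apply_chain(flat.values, chain)
    wl = cube.wavelengths
    for name, params in chain.steps:
        if name == "sg_derivative":
            half = (params.get("window", 11) - 1) // 2
            wl = wl[half:len(wl) - half]
    stack = refold(flat, values, fill=0.0)
    return Hypercube(data=stack, wavelengths=wl, mask=cube.mask, label=cube.label)
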