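"""Synthetic NIR reflectance scenes with exact ground truth.

Two scenario families are generated, mirroring the structure the pipeline's
stages exist to handle:

* **sweets-like** — four object classes, one object class per cube, each with
  a distinct spectral baseline (plus Gaussian absorption dips around the
  NIR water and CH bands) and a distinct spatial shape and surface texture;
  101 bands over 943-1643 nm on a bright white tile.
* **salmon-like** — two interleaved tissue classes (bright connective-tissue
  stripes vs red muscle) in a zebra-stripe pattern inside a fillet blob,
  with per-scene smooth baseline interference (thickness/batch effects),
  occasional specular-saturated pixels, 180 bands over 900-1700 nm on a
  dark stage.

Every foreground pixel's spectrum is

    class signature x multiplicative scatter + additive offset
    + interference amplitude x thickness field x interference spectrum
    + Gaussian noise,

specular pixels are clipped near saturation (1.2), and the returned label
image is the exact placement truth.  Rendering is deterministic given the
config seed.

The generator emulates the *structure* real cubes exhibit (spectral class
signatures, scatter, interference, textures), not radiometry: there is no
camera model, no physically based rendering, and shape fidelity is
irrelevant to the pipeline's contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from hsipix.core_io import Hypercube, LabelImage

__all__ = ["ClassSignature", "SceneConfig", "render_scene", "generate_dataset",
           "spatial_only_variant", "sweets_config", "salmon_config", "Dataset"]


# ---------------------------------------------------------------------------
# Spectral + texture signatures


@dataclass
class ClassSignature:
    """Spectral and textural description of one class.

    The reflectance curve is ``baseline`` minus a smooth sigmoidal drop of
    amplitude ``water_drop`` toward long wavelengths (the broad water
    absorption edge that also powers band-difference background masking)
    minus Gaussian dips ``(center nm, width nm, depth)``.  ``texture``
    modulates pixel brightness between the class spectrum and a darker
    partner spectrum; kinds: ``none``, ``stripes(period, orientation_deg)``,
    ``blobs(scale)``.
    """

    name: str
    baseline: float
    water_drop: float = 0.35
    bands: Sequence[tuple] = field(default_factory=list)
    texture: dict = field(default_factory=lambda: {"kind": "none"})
    texture_amplitude: float = 0.15
    shape: str = "ellipse"

    def spectrum(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=np.float64)
        r = self.baseline - self.water_drop / (1.0 + np.exp(-(wl - 1330.0) / 90.0))
        for center, width, depth in self.bands:
            if not wl[0] <= center <= wl[-1]:
                raise ValueError(f"band center {center} nm outside wavelength range")
            r = r - depth * np.exp(-0.5 * ((wl - center) / width) ** 2)
        if r.min() < 0 or r.max() > 1.3:
            raise ValueError(f"signature '{self.name}' leaves [0, 1.3]")
        return r


@dataclass
class SceneConfig:
    """Full description of one renderable scene (seed mandatory)."""

    scenario: str                       # "sweets" | "salmon"
    image_size: int
    wavelengths: np.ndarray
    signatures: Sequence[ClassSignature]
    scene_classes: Sequence[int]        # 1-based class ids present in the scene
    seed: int
    background_level: float = 0.88
    noise_sd: float = 0.015
    scatter_range: tuple = (0.95, 1.05)
    offset_range: tuple = (-0.02, 0.02)
    # one (lo, hi) amplitude range per interference basis component;
    # explicit per-scene amplitudes (e.g. batch-structured) override the draw
    interference_amplitude_ranges: tuple = ()
    interference_amplitudes: Optional[tuple] = None
    specular_fraction: float = 0.0
    stripe_period: int = 9              # salmon zebra geometry
    stripe_width: int = 3

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        lo, hi = self.scatter_range
        if not (0 < lo <= hi):
            raise ValueError("invalid scatter range")
        for lo, hi in self.interference_amplitude_ranges:
            if lo > hi:
                raise ValueError("invalid interference amplitude range")
        if not 0 <= self.specular_fraction < 1:
            raise ValueError("specular_fraction must be in [0, 1)")
        for cid in self.scene_classes:
            if not 1 <= cid <= len(self.signatures):
                raise ValueError(f"scene class {cid} has no signature")

    @property
    def class_names(self) -> list[str]:
        return [s.name for s in self.signatures]

    def interference_basis(self) -> np.ndarray:
        """Parasitic directions, one row per component.

        Component 1 is a thickness/path-length effect: extra tissue lowers
        the broad baseline and deepens the water band.  Component 2 is a
        batch-composition effect on the CH band plus a small offset.  Both
        overlap the very directions the classes differ in — the regime EPO
        exists for.
        """
        wl = self.wavelengths
        u1 = 0.45 + 0.30 * np.exp(-0.5 * ((wl - 1450.0) / 55.0) ** 2)
        u2 = 0.15 + 0.35 * np.exp(-0.5 * ((wl - 1218.0) / 28.0) ** 2)
        return np.stack([u1, u2])


# ---------------------------------------------------------------------------
# Shapes and textures (parametric composites; fidelity is irrelevant)


def _shape_mask(kind: str, h: int, w: int, cy: float, cx: float,
                scale: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy - cy) / scale
    x = (xx - cx) / scale
    if kind == "ellipse":
        return (x / 1.25) ** 2 + y**2 <= 1.0
    if kind == "mushroom":
        cap = (x**2 + (y + 0.35) ** 2 <= 1.0) & (y <= -0.1)
        stalk = (np.abs(x) <= 0.35) & (y > -0.2) & (y <= 1.0)
        return cap | stalk
    if kind == "teeth":
        base = (np.abs(x) <= 1.1) & (np.abs(y) <= 0.55)
        bumps = np.zeros_like(base)
        for bx in (-0.8, -0.27, 0.27, 0.8):
            bumps |= ((x - bx) ** 2 + (y + 0.55) ** 2) <= 0.075
        return base | bumps
    if kind == "bottle":
        body = (np.abs(x) <= 0.55) & (y > -0.25) & (y <= 1.0)
        neck = (np.abs(x) <= 0.22) & (y <= -0.25) & (y >= -1.0)
        return body | neck
    if kind == "fillet":
        return (x / 1.3) ** 2 + (y / 0.95) ** 2 <= 1.0
    raise ValueError(f"unknown shape '{kind}'")


def _texture_field(texture: dict, h: int, w: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Binary mixing field in {0, 1} with mean ~0.5 over the image."""
    kind = texture.get("kind", "none")
    if kind == "none":
        return np.ones((h, w))
    if kind == "stripes":
        period = texture.get("period", 6)
        theta = np.deg2rad(texture.get("orientation", 0.0))
        phase = rng.uniform(0, period)
        yy, xx = np.mgrid[0:h, 0:w]
        u = xx * np.cos(theta) + yy * np.sin(theta) + phase
        return ((u // (period / 2.0)) % 2).astype(np.float64)
    if kind == "blobs":
        scale = texture.get("scale", 3.0)
        f = gaussian_filter(rng.standard_normal((h, w)), scale)
        return (f > np.median(f)).astype(np.float64)
    raise ValueError(f"unknown texture kind '{kind}'")


# ---------------------------------------------------------------------------
# Rendering


def render_scene(config: SceneConfig) -> tuple[Hypercube, LabelImage]:
    """Render one scene deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.image_size
    wl = config.wavelengths
    nb = wl.size
    labels = np.zeros((n, n), dtype=np.int32)

    if config.scenario == "salmon":
        cy, cx = n / 2 + rng.uniform(-1, 1), n / 2 + rng.uniform(-1, 1)
        fg = _shape_mask("fillet", n, n, cy, cx, scale=0.42 * n)
        theta = np.deg2rad(rng.uniform(55, 125))
        yy, xx = np.mgrid[0:n, 0:n]
        u = (xx * np.cos(theta) + yy * np.sin(theta)
             + 2.0 * np.sin(yy / 6.0 + rng.uniform(0, 6.28)))
        stripe = (u % config.stripe_period) < config.stripe_width
        labels[fg & stripe] = 1      # myocommata (white stripe)
        labels[fg & ~stripe] = 2     # myotome (red muscle)
    else:
        n_obj = len(config.scene_classes)
        grid = int(np.ceil(np.sqrt(n_obj)))
        cell = n / grid
        order = list(config.scene_classes)
        rng.shuffle(order)
        for i, cid in enumerate(order):
            gy, gx = divmod(i, grid)
            cy = (gy + 0.5) * cell + rng.uniform(-1.5, 1.5)
            cx = (gx + 0.5) * cell + rng.uniform(-1.5, 1.5)
            sig = config.signatures[cid - 1]
            m = _shape_mask(sig.shape, n, n, cy, cx, scale=0.33 * cell)
            if not m.any():
                raise ValueError(f"shape for class {cid} fell outside the image")
            labels[m] = cid

    data = np.empty((n, n, nb))
    data[:] = config.background_level
    data += rng.normal(0.0, config.noise_sd / 2, size=data.shape)

    for cid in np.unique(labels[labels > 0]):
        sig = config.signatures[cid - 1]
        sel = labels == cid
        spec = sig.spectrum(wl)
        t = _texture_field(sig.texture, n, n, rng)[sel]
        bright = 1.0 - sig.texture_amplitude * (1.0 - t)
        px = bright[:, None] * spec[None, :]
        scatter = rng.uniform(*config.scatter_range, size=sel.sum())
        offset = rng.uniform(*config.offset_range, size=sel.sum())
        px = px * scatter[:, None] + offset[:, None]
        data[sel] = px

    if config.interference_amplitude_ranges or config.interference_amplitudes:
        basis = config.interference_basis()
        if config.interference_amplitudes is not None:
            amps = list(config.interference_amplitudes)
        else:
            amps = [rng.uniform(lo, hi)
                    for lo, hi in config.interference_amplitude_ranges]
        thickness = gaussian_filter(rng.standard_normal((n, n)), n / 6)
        tmin, tmax = thickness.min(), thickness.max()
        thickness = 0.8 + 0.4 * (thickness - tmin) / max(tmax - tmin, 1e-12)
        fgm = labels > 0
        for amp, g in zip(amps, basis):
            # thicker / wetter tissue absorbs more: reflectance drops along g
            data[fgm] -= amp * thickness[fgm][:, None] * g[None, :]

    data[labels > 0] += rng.normal(
        0.0, config.noise_sd, size=(int((labels > 0).sum()), nb))

    if config.specular_fraction > 0:
        fg_idx = np.argwhere(labels > 0)
        n_spec = int(round(config.specular_fraction * len(fg_idx)))
        if n_spec:
            pick = fg_idx[rng.choice(len(fg_idx), size=n_spec, replace=False)]
            data[pick[:, 0], pick[:, 1], :] = rng.uniform(1.15, 1.25,
                                                          size=(n_spec, nb))
    np.clip(data, 0.0, 1.2, out=data)

    cube = Hypercube(data=data, wavelengths=wl.copy(),
                     label=(config.signatures[config.scene_classes[0] - 1].name
                            if len(config.scene_classes) == 1 else None))
    return cube, LabelImage(labels=labels, class_names=config.class_names)


# ---------------------------------------------------------------------------
# Scenario presets (the study conditions)


def sweets_config(seed: int = 0, image_size: int = 56) -> SceneConfig:
    """Four sweets classes: distinct baselines, dips, shapes and textures."""
    wl = 943.0 + 7.0 * np.arange(101)   # 101 bands, 943-1643 nm
    sigs = [
        ClassSignature("RFM", baseline=0.92, water_drop=0.40,
                       bands=[(1450, 45, 0.10), (1200, 35, 0.05)],
                       texture={"kind": "blobs", "scale": 2.5}, shape="mushroom"),
        ClassSignature("Mint", baseline=0.72, water_drop=0.38,
                       bands=[(1410, 40, 0.08), (1210, 30, 0.07)],
                       texture={"kind": "stripes", "period": 7, "orientation": 0},
                       shape="ellipse"),
        ClassSignature("Teeth", baseline=0.84, water_drop=0.42,
                       bands=[(1450, 50, 0.12), (1150, 30, 0.04)],
                       texture={"kind": "stripes", "period": 7, "orientation": 90},
                       shape="teeth"),
        ClassSignature("Tub", baseline=0.60, water_drop=0.34,
                       bands=[(1450, 45, 0.08), (1210, 30, 0.09)],
                       texture={"kind": "blobs", "scale": 6.0}, shape="bottle"),
    ]
    return SceneConfig(scenario="sweets", image_size=image_size, wavelengths=wl,
                       signatures=sigs, scene_classes=(1,), seed=seed,
                       background_level=0.88, noise_sd=0.015,
                       scatter_range=(0.95, 1.05), offset_range=(-0.02, 0.02))


def salmon_config(seed: int = 0, image_size: int = 40,
                  n_bands: int = 180) -> SceneConfig:
    """Two tissue classes in a zebra pattern with per-scene interference."""
    wl = np.linspace(900.0, 1700.0, n_bands)
    sigs = [
        # the bright fatty stripe differs from red muscle mostly *along* the
        # thickness/absorbance direction (higher baseline, shallower water
        # and CH dips) plus a small CH-band center shift (1205 vs 1235 nm)
        # that survives orthogonalization — the structure EPO exploits
        ClassSignature("myocommata", baseline=0.80, water_drop=0.30,
                       bands=[(1218, 28, 0.076), (1450, 55, 0.094),
                              (1205, 25, 0.10)],
                       texture={"kind": "none"}, texture_amplitude=0.0,
                       shape="fillet"),
        ClassSignature("myotome", baseline=0.70, water_drop=0.30,
                       bands=[(1218, 28, 0.12), (1450, 55, 0.16),
                              (1235, 25, 0.10)],
                       texture={"kind": "none"}, texture_amplitude=0.0,
                       shape="fillet"),
    ]
    return SceneConfig(scenario="salmon", image_size=image_size, wavelengths=wl,
                       signatures=sigs, scene_classes=(1, 2), seed=seed,
                       background_level=0.08, noise_sd=0.045,
                       scatter_range=(0.95, 1.05), offset_range=(-0.01, 0.01),
                       interference_amplitude_ranges=((0.0, 0.45), (-0.3, 0.3)),
                       specular_fraction=0.005)


def spatial_only_variant(config: SceneConfig) -> SceneConfig:
    """Adversarial sweets variant: one shared spectrum, texture-only classes.

    Every class adopts the first class's spectral signature, a common
    object shape, and a strong binary brightness texture whose *pattern*
    (stripe orientation, blob scale) is the only class difference.  The
    texture fields all have mean 1/2, so marginal (per-pixel) spectral
    distributions — and class pixel counts — are identical across classes
    and only spatial context can separate them: the case that splits
    spectral-only from spectral-spatial classifiers.
    """
    if config.scenario != "sweets":
        raise ValueError("spatial-only variant is defined for the sweets scenario")
    shared = config.signatures[0]
    textures = [
        {"kind": "stripes", "period": 6, "orientation": 0},
        {"kind": "stripes", "period": 6, "orientation": 90},
        {"kind": "blobs", "scale": 1.5},
        {"kind": "blobs", "scale": 5.0},
    ]
    sigs = [
        replace(shared, name=s.name, texture=textures[i % len(textures)],
                texture_amplitude=0.30, shape="ellipse")
        for i, s in enumerate(config.signatures)
    ]
    return replace(config, signatures=sigs)


# ---------------------------------------------------------------------------
# Datasets


@dataclass
class Dataset:
    """Scene-level split of rendered cubes with exact truth."""

    scenario: str
    train: list            # list of (Hypercube, LabelImage, seed)
    val: list
    test: list
    class_names: Sequence[str]

    def manifest(self) -> dict:
        def entries(split, items):
            out = []
            for cube, truth, seed in items:
                counts = {str(c): int((truth.labels == c).sum())
                          for c in np.unique(truth.labels[truth.labels > 0])}
                out.append({"split": split, "seed": int(seed),
                            "label": cube.label, "shape": list(cube.shape),
                            "class_pixel_counts": counts})
            return out
        return {"scenario": self.scenario,
                "class_names": list(self.class_names),
                "scenes": (entries("train", self.train) + entries("val", self.val)
                           + entries("test", self.test))}


def generate_dataset(config: SceneConfig, n_train: int = 3, n_val: int = 1,
                     n_test: int = 2, mixed_test: bool = True) -> Dataset:
    """Render disjoint scene-level train/val/test splits.

    For the sweets scenario the counts are per class (single-object cubes:
    3 training cubes x 4 classes = 12) and test scenes are mixed images
    containing one object of every class when ``mixed_test``.  For the
    salmon scenario every scene contains both classes and counts are scene
    counts.  Per-scene seeds are spawned deterministically from
    ``config.seed``.
    """
    if min(n_train, n_val) < 1 or n_test < 0:
        raise ValueError("split counts must be >= 1 (n_test >= 0)")
    ss = np.random.SeedSequence(config.seed)
    C = len(config.signatures)

    def seeds(k):
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]

    train, val, test = [], [], []
    if config.scenario == "sweets":
        all_seeds = iter(seeds((n_train + n_val) * C + n_test))
        for cid in range(1, C + 1):
            for _ in range(n_train):
                sc = replace(config, scene_classes=(cid,), seed=next(all_seeds))
                cube, truth = render_scene(sc)
                train.append((cube, truth, sc.seed))
            for _ in range(n_val):
                sc = replace(config, scene_classes=(cid,), seed=next(all_seeds))
                cube, truth = render_scene(sc)
                val.append((cube, truth, sc.seed))
        for _ in range(n_test):
            classes = tuple(range(1, C + 1)) if mixed_test else (1,)
            big = replace(config, scene_classes=classes, seed=next(all_seeds),
                          image_size=config.image_size * 2 if mixed_test
                          else config.image_size)
            cube, truth = render_scene(big)
            test.append((cube, truth, big.seed))
    else:
        # salmon fillets come in batches: the training, validation and test
        # fillets belong to different batches, so the per-batch interference
        # amplitudes (thickness / composition) of the test fillets are
        # unseen at training time
        batch_centers = {"train": (0.06, 0.10), "val": (0.18, -0.05),
                         "test": (0.32, -0.22)}
        amp_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 917]).generate_state(1)[0])
        all_seeds = iter(seeds(n_train + n_val + n_test))
        for split, count in (("train", n_train), ("val", n_val), ("test", n_test)):
            for _ in range(count):
                if config.interference_amplitude_ranges:
                    amps = tuple(c + amp_rng.uniform(-0.04, 0.04)
                                 for c in batch_centers[split])
                else:
                    amps = None
                sc = replace(config, seed=next(all_seeds),
                             interference_amplitudes=amps)
                cube, truth = render_scene(sc)
                {"train": train, "val": val, "test": test}[split].append(
                    (cube, truth, sc.seed))
    return Dataset(scenario=config.scenario, train=train, val=val, test=test,
                   class_names=config.class_names)
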