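"""Confusion matrices, per-class rates, CCR, and map-level diagnostics.

Evaluation is restricted to pixels with truth > 0 (background never
counts).  Per-class rates use the one-vs-rest reduction:

    TPR = TP / (TP + FN)        FNR = FN / (FN + TP)
    PPV = TP / (TP + FP)        FDR = FP / (FP + TP)   (conventional)

A legacy variant prints FDR as FP / (FP + TN) — that quantity is actually
the false-positive rate, not a discovery rate; both are reported so the
divergence is never silent, and ``fdr_as_printed=True`` selects the legacy
form as the headline FDR.  CCR (correct classification rate) is
trace / total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from hsipix.core_io import LabelImage

__all__ = ["ConfusionReport", "confusion", "misclassification_map",
           "local_threshold_truth"]


@dataclass
class ConfusionReport:
    """Per-class confusion counts and rates; fractions internally.

    ``counts[i, j]`` = pixels of true class ``i+1`` predicted as ``j+1``.
    ``fdr_printed`` holds the legacy FP/(FP+TN) form alongside the
    conventional ``fdr`` = 1 - PPV.
    """

    counts: np.ndarray
    tpr: np.ndarray
    fnr: np.ndarray
    ppv: np.ndarray
    fdr: np.ndarray
    fdr_printed: np.ndarray
    ccr: float
    class_names: Sequence[str] = field(default_factory=list)
    fdr_as_printed: bool = False

    @property
    def n_evaluated(self) -> int:
        return int(self.counts.sum())

    def headline_fdr(self) -> np.ndarray:
        return self.fdr_printed if self.fdr_as_printed else self.fdr

    def to_dict(self) -> dict:
        """JSON-ready summary; rates as percentages for display parity."""
        return {
            "counts": self.counts.tolist(),
            "class_names": list(self.class_names),
            "ccr_pct": 100.0 * self.ccr,
            "tpr_pct": (100.0 * self.tpr).tolist(),
            "fnr_pct": (100.0 * self.fnr).tolist(),
            "ppv_pct": (100.0 * self.ppv).tolist(),
            "fdr_pct": (100.0 * self.fdr).tolist(),
            "fdr_printed_pct": (100.0 * self.fdr_printed).tolist(),
            "fdr_mode": "printed" if self.fdr_as_printed else "conventional",
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self):
        import pandas as pd

        names = list(self.class_names) or [str(i + 1) for i in range(len(self.tpr))]
        return pd.DataFrame({"class": names, "TPR": self.tpr, "FNR": self.fnr,
                             "PPV": self.ppv, "FDR": self.headline_fdr()})


def _as_labels(x) -> np.ndarray:
    return x.labels if isinstance(x, LabelImage) else np.asarray(x)


def confusion(truth, pred, n_classes: Optional[int] = None,
              class_names: Sequence[str] = (),
              fdr_as_printed: bool = False) -> ConfusionReport:
    """Confusion counts and one-vs-rest rates over pixels with truth > 0."""
    t = _as_labels(truth)
    p = _as_labels(pred)
    if t.shape != p.shape:
        raise ValueError(f"truth shape {t.shape} != prediction shape {p.shape}")
    sel = t > 0
    if not sel.any():
        raise ValueError("no labelled pixels to evaluate (all truth is background)")
    t, p = t[sel].astype(np.int64), p[sel].astype(np.int64)
    C = int(n_classes or max(t.max(), p.max(), len(class_names) or 0))
    counts = np.zeros((C, C), dtype=np.int64)
    inside = p >= 1
    np.add.at(counts, (t[inside] - 1, p[inside] - 1), 1)
    # a prediction of 0 (background/abstain) counts against the row total
    # but belongs to no predicted column; track it as off-diagonal misses
    total = int(sel.sum())
    tp = np.diag(counts).astype(np.float64)
    row = counts.sum(axis=1).astype(np.float64)
    row += np.bincount(t[~inside] - 1, minlength=C) if (~inside).any() else 0
    col = counts.sum(axis=0).astype(np.float64)
    fn = row - tp
    fp = col - tp
    tn = total - row - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(row > 0, tp / row, np.nan)
        fnr = np.where(row > 0, fn / row, np.nan)
        ppv = np.where(col > 0, tp / col, np.nan)
        fdr = np.where(col > 0, fp / col, np.nan)
        fdr_printed = np.where(fp + tn > 0, fp / (fp + tn), np.nan)
    ccr = float(tp.sum() / total)
    return ConfusionReport(counts=counts, tpr=tpr, fnr=fnr, ppv=ppv, fdr=fdr,
                           fdr_printed=fdr_printed, ccr=ccr,
                           class_names=list(class_names),
                           fdr_as_printed=fdr_as_printed)


def misclassification_map(truth, pred) -> np.ndarray:
    """Boolean image: true where a labelled pixel is predicted wrongly."""
    t = _as_labels(truth)
    p = _as_labels(pred)
    if t.shape != p.shape:
        raise ValueError(f"truth shape {t.shape} != prediction shape {p.shape}")
    return (t > 0) & (p != t)


def local_threshold_truth(score_image: np.ndarray, tile_grid: tuple[int, int],
                          mask: np.ndarray,
                          thresholds: Optional[np.ndarray] = None,
                          high_is_class1: bool = True,
                          class_names: Sequence[str] = ("class1", "class2"),
                          ) -> LabelImage:
    """Two-class ground truth from a score image by per-tile thresholding.

    The image is divided into an ``r x c`` tile grid; each tile gets its own
    threshold — either supplied, or chosen automatically by Otsu's criterion
    (minimal intra-class variance), the objective stand-in for a manual
    per-tile choice.  Pixels above the threshold become class 1 (flip with
    ``high_is_class1=False``); tiles without foreground are skipped.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(score_image, dtype=np.float64)
    if img.ndim == 3 and img.shape[2] == 1:
        img = img[:, :, 0]
    if img.ndim != 2:
        raise ValueError("score_image must be a single-channel image")
    mask = np.asarray(mask, dtype=bool)
    r, c = tile_grid
    if r < 1 or c < 1:
        raise ValueError("tile grid must be at least 1x1")
    if thresholds is not None:
        thresholds = np.asarray(thresholds, dtype=np.float64)
        if thresholds.shape != (r, c):
            raise ValueError(f"thresholds must have shape {(r, c)}")
    labels = np.zeros(img.shape, dtype=np.int32)
    row_edges = np.linspace(0, img.shape[0], r + 1).astype(int)
    col_edges = np.linspace(0, img.shape[1], c + 1).astype(int)
    for i in range(r):
        for j in range(c):
            sl = (slice(row_edges[i], row_edges[i + 1]),
                  slice(col_edges[j], col_edges[j + 1]))
            fg = mask[sl]
            if not fg.any():
                continue
            vals = img[sl][fg]
            if thresholds is not None:
                thr = thresholds[i, j]
            elif np.ptp(vals) < 1e-12:
                thr = vals[0]  # flat tile: everything lands on one side
            else:
                thr = threshold_otsu(vals)
            tile = np.zeros(fg.shape, dtype=np.int32)
            hi = img[sl] > thr
            tile[fg & hi] = 1 if high_is_class1 else 2
            tile[fg & ~hi] = 2 if high_is_class1 else 1
            labels[sl] = tile
    return LabelImage(labels=labels, class_names=list(class_names))
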