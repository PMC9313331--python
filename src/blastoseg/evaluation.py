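"""Jaccard-index evaluation and mask export.

The segmentation quality metric is the per-class Jaccard index over pixel
sets, ``JI_c = TP_c / (TP_c + FP_c + FN_c)`` in percent, with the mean taken
as the unweighted arithmetic mean of the five class values (BG included).
Counts are pooled over all evaluated pixels by default (micro aggregation),
the reading consistent with the set definition of the index; a per-image
averaging mode is also provided.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataio import CLASS_MAP, ImageSample, write_mask
from .network import N_CLASSES, Network, predict

__all__ = [
    "ConfusionCounts",
    "JaccardReport",
    "confusion_counts",
    "evaluate",
    "export_result_masks",
    "jaccard_index",
    "mean_ji",
]

#: Reporting order of the per-class columns (background last, as tabulated).
REPORT_ORDER = ("TE", "ZP", "ICM", "BL", "BG")


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/FN pixel tallies."""

    tp: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES, dtype=np.int64))
    fp: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES, dtype=np.int64))
    fn: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES, dtype=np.int64))

    def __iadd__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


def confusion_counts(pred_label_map: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Tally per-class TP/FP/FN between a predicted and a reference mask."""
    if pred_label_map.shape != gt_mask.shape:
        raise ValueError(
            f"shape mismatch: prediction {pred_label_map.shape} vs mask {gt_mask.shape}"
        )
    pred = np.ravel(pred_label_map).astype(np.int64)
    gt = np.ravel(gt_mask).astype(np.int64)
    if pred.min() < 0 or pred.max() >= N_CLASSES or gt.min() < 0 or gt.max() >= N_CLASSES:
        raise ValueError(f"mask values must lie in 0..{N_CLASSES - 1}")
    cm = np.bincount(gt * N_CLASSES + pred, minlength=N_CLASSES * N_CLASSES).reshape(
        N_CLASSES, N_CLASSES
    )
    tp = np.diag(cm).copy()
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def jaccard_index(counts: ConfusionCounts, class_index: int) -> tuple[float, bool]:
    """Jaccard index of one class in percent.

    A class absent from both prediction and reference (TP+FP+FN = 0) is a
    vacuous perfect match: the value is defined as 100% and flagged.
    """
    tp = int(counts.tp[class_index])
    denom = tp + int(counts.fp[class_index]) + int(counts.fn[class_index])
    if denom == 0:
        return 100.0, True
    return 100.0 * tp / denom, False


def mean_ji(per_class_values: np.ndarray | list[float]) -> float:
    """Unweighted arithmetic mean of the five per-class JIs, to 2 decimals."""
    values = np.asarray(per_class_values, dtype=np.float64)
    if values.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} per-class values, got {values.shape}")
    return round(float(values.mean()), 2)


@dataclass
class JaccardReport:
    """Per-class and mean JI in percent, in the standard column layout."""

    per_class: dict[str, float]  # keys TE, ZP, ICM, BL, BG
    n_images: int
    flagged: tuple[str, ...] = ()  # classes absent from both pred and truth
    params_millions: float | None = None

    @property
    def mean(self) -> float:
        return mean_ji([self.per_class[name] for name in REPORT_ORDER])

    def row(self) -> list[float]:
        return [round(self.per_class[name], 2) for name in REPORT_ORDER] + [self.mean]

    def __str__(self) -> str:
        header = "  ".join(f"{n:>6}" for n in REPORT_ORDER) + "  MeanJI"
        vals = "  ".join(f"{v:6.2f}" for v in self.row())
        return f"{header}\n{vals}   (n={self.n_images})"

    def write_csv(self, path: str | Path, label: str = "") -> None:
        write_report_csv(path, [(label, self)])


def write_report_csv(path: str | Path, rows: list[tuple[str, "JaccardReport"]]) -> None:
    """Ablation-table style CSV: one row per configuration."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["method", *REPORT_ORDER, "MeanJI", "params_millions"])
        for label, rep in rows:
            writer.writerow(
                [label]
                + [f"{v:.2f}" for v in rep.row()]
                + ["" if rep.params_millions is None else f"{rep.params_millions:.2f}"]
            )


def evaluate(
    network: Network,
    test_samples: list[ImageSample],
    mode: str = "pooled",
    detail_path: str | Path | None = None,
) -> JaccardReport:
    """Segment every test sample and report per-class + mean JI.

    ``pooled`` (default) accumulates TP/FP/FN over all test pixels before
    applying the index; ``per_image`` averages per-image JIs instead.
    """
    if not test_samples:
        raise ValueError("test set is empty")
    if mode not in {"pooled", "per_image"}:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    pooled = ConfusionCounts()
    per_image_vals: list[np.ndarray] = []
    detail = []
    for smp in test_samples:
        label_map, _ = predict(network, smp.image)
        counts = confusion_counts(label_map, smp.mask)
        pooled += counts
        vals = np.array([jaccard_index(counts, c)[0] for c in range(N_CLASSES)])
        per_image_vals.append(vals)
        detail.append(
            {
                "sample_id": smp.sample_id,
                "ji": {name: vals[CLASS_MAP.index_of(name)] for name in REPORT_ORDER},
            }
        )
    if mode == "pooled":
        values, flags = {}, []
        for name in REPORT_ORDER:
            ji, flagged = jaccard_index(pooled, CLASS_MAP.index_of(name))
            values[name] = ji
            if flagged:
                flags.append(name)
    else:
        stacked = np.stack(per_image_vals)
        values = {name: float(stacked[:, CLASS_MAP.index_of(name)].mean()) for name in REPORT_ORDER}
        flags = []
    if detail_path is not None:
        Path(detail_path).write_text(json.dumps(detail, indent=2))
    return JaccardReport(per_class=values, n_images=len(test_samples), flagged=tuple(flags))


def export_result_masks(
    prediction: tuple[np.ndarray, np.ndarray] | np.ndarray,
    out_dir: str | Path,
    stem: str = "prediction",
) -> list[Path]:
    """Write 5 binary component masks plus the colour-combined mask.

    Component masks are white where the class is predicted, black elsewhere;
    the combined mask uses the canonical class colours.
    """
    if isinstance(prediction, tuple):
        label_map, masks = prediction
    else:
        label_map = np.asarray(prediction)
        masks = np.stack([(label_map == c) for c in range(N_CLASSES)]).astype(np.uint8)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("TE", "ZP", "ICM", "BL", "BG"):
        idx = CLASS_MAP.index_of(name)
        path = out / f"{stem}_{name}.png"
        from PIL import Image

        Image.fromarray((masks[idx] * 255).astype(np.uint8), mode="L").save(path)
        written.append(path)
    combined = out / f"{stem}_combined.png"
    write_mask(label_map, combined, mode="color")
    written.append(combined)
    return written
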