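"""Detection/segmentation evaluation and training-stochasticity statistics.

Implements the standard instance-evaluation stack: IoU for boxes and masks,
greedy score-ordered matching of predictions to ground truth at an IoU
threshold, precision/recall/F1, average precision by 101-point interpolated
integration of the precision-recall curve (exact all-point integration
available as a flag), mAP50 and mAP50-95 (IoU 0.50 to 0.95 in 0.05 steps),
and the repeated-training variation summary (mean, sample SD, coefficient
of variation = SD/mean x 100, max-min range) used to judge whether
differences between model variants exceed training stochasticity.

All percentages are reported on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IOU_THRESHOLDS_50_95 = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class Detection:
    """A predicted or ground-truth instance (score 1.0 for ground truth)."""

    image_id: str
    class_label: str
    score: float = 1.0
    box: tuple | None = None           # (x, y, w, h)
    mask: np.ndarray | None = None     # binary raster

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must be in [0, 1]")
        if self.box is None and self.mask is None:
            raise ValueError("detection needs a box or a mask")
        if self.box is not None and (self.box[2] <= 0 or self.box[3] <= 0):
            raise ValueError("box must have positive width and height")


def iou(a: Detection, b: Detection) -> float:
    """Intersection over union of two same-kind geometries, in [0, 1]."""
    if (a.box is None) != (b.box is None):
        raise ValueError("cannot mix box and mask geometries")
    if a.box is not None:
        ax, ay, aw, ah = a.box
        bx, by, bw, bh = b.box
        ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
        iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
        inter = ix * iy
        union = aw * ah + bw * bh - inter
    else:
        am, bm = np.asarray(a.mask, bool), np.asarray(b.mask, bool)
        inter = float(np.logical_and(am, bm).sum())
        union = float(np.logical_or(am, bm).sum())
    return inter / union if union > 0 else 0.0


@dataclass
class MatchTable:
    """Outcome of matching ranked predictions to ground truth."""

    tp: int
    fp: int
    fn: int
    # per ranked prediction: (score, is_tp, matched IoU or 0.0)
    ranked: list = field(default_factory=list)
    n_gt: int = 0


def match(preds, gts, iou_threshold: float = 0.5,
          class_label: str | None = None) -> MatchTable:
    """Greedy score-ordered matching (COCO protocol).

    Within each image and class, predictions sorted by descending score are
    each matched to the still-unmatched ground truth of highest IoU >=
    threshold; a ground truth is used at most once, so a double detection
    yields one TP and one FP. Ties in score keep input order.
    """
    classes = {class_label} if class_label else \
        {d.class_label for d in list(preds) + list(gts)}
    ranked_all, tp = [], 0
    n_gt = 0
    for cls in sorted(classes):
        cls_preds = [p for p in preds if p.class_label == cls]
        cls_gts = [g for g in gts if g.class_label == cls]
        n_gt += len(cls_gts)
        by_image: dict = {}
        for g in cls_gts:
            by_image.setdefault(g.image_id, []).append(g)
        order = sorted(range(len(cls_preds)),
                       key=lambda i: -cls_preds[i].score)
        used: dict = {img: [False] * len(gl) for img, gl in by_image.items()}
        for i in order:
            p = cls_preds[i]
            candidates = by_image.get(p.image_id, [])
            best_j, best_iou = -1, iou_threshold
            for j, g in enumerate(candidates):
                if used[p.image_id][j]:
                    continue
                val = iou(p, g)
                if val > best_iou or (best_j < 0 and val >= iou_threshold):
                    best_j, best_iou = j, val
            if best_j >= 0:
                used[p.image_id][best_j] = True
                ranked_all.append((p.score, True, best_iou))
                tp += 1
            else:
                ranked_all.append((p.score, False, 0.0))
    ranked_all.sort(key=lambda t: -t[0])
    fp = len(ranked_all) - tp
    return MatchTable(tp=tp, fp=fp, fn=n_gt - tp, ranked=ranked_all, n_gt=n_gt)


@dataclass(frozen=True)
class PRF1:
    precision: float   # %
    recall: float      # %
    f1: float          # %
    defined: bool = True


def precision_recall_f1(table: MatchTable) -> PRF1:
    """P, R and F1 in percent from a match table.

    Conventions: with no predictions and ground truth present, P = 100
    (vacuously no false positives) and R = 0; with neither predictions nor
    ground truth all three are reported as 0 with ``defined=False``.
    """
    tp, fp, fn = table.tp, table.fp, table.fn
    if tp + fp + fn == 0:
        return PRF1(0.0, 0.0, 0.0, defined=False)
    p = 100.0 * tp / (tp + fp) if tp + fp else 100.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 100.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return PRF1(p, r, f1)


def f1_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of percent precision and recall."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


def _pr_curve(table: MatchTable):
    flags = np.array([t[1] for t in table.ranked], dtype=float)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(1.0 - flags)
    recall = tp_cum / table.n_gt if table.n_gt else np.zeros_like(tp_cum)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    return recall, precision


def average_precision(preds, gts, iou_threshold: float = 0.5,
                      class_label: str | None = None,
                      exact: bool = False) -> float:
    """AP (%) at one IoU threshold for one class.

    101-point interpolation by default (precision envelope sampled at
    recall 0, 0.01, ..., 1); ``exact=True`` integrates the envelope over
    all recall increments instead.
    """
    table = match(preds, gts, iou_threshold, class_label)
    if table.n_gt == 0:
        return 0.0
    if not table.ranked:
        return 0.0
    recall, precision = _pr_curve(table)
    # precision envelope: running max from the right
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    if exact:
        r_prev = np.concatenate([[0.0], recall[:-1]])
        return float(100.0 * np.sum((recall - r_prev) * envelope))
    sample_points = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, sample_points, side="left")
    sampled = np.where(idx < len(envelope), envelope[np.minimum(idx, len(envelope) - 1)], 0.0)
    return float(100.0 * sampled.mean())


def mean_ap(preds, gts, thresholds=IOU_THRESHOLDS_50_95,
            exact: bool = False):
    """(mAP50, mAP50-95): per-class AP averaged over classes, then over
    IoU thresholds 0.50:0.05:0.95 for the second value."""
    classes = sorted({g.class_label for g in gts} |
                     {p.class_label for p in preds})
    if not classes:
        return 0.0, 0.0
    ap_by_thr = []
    for thr in thresholds:
        aps = [average_precision(preds, gts, thr, cls, exact=exact)
               for cls in classes]
        ap_by_thr.append(float(np.mean(aps)))
    map50 = ap_by_thr[0] if abs(thresholds[0] - 0.5) < 1e-9 else \
        float(np.mean([average_precision(preds, gts, 0.5, c, exact=exact)
                       for c in classes]))
    return map50, float(np.mean(ap_by_thr))


@dataclass(frozen=True)
class VariationSummary:
    """Spread of a metric across repeated trainings of the same model."""

    mean: float
    sd: float
    cv_percent: float          # sd / mean * 100
    range_max_minus_min: float
    n_runs: int


def variation_summary(values) -> VariationSummary:
    """Mean, sample SD (n-1), CV% and max-min range over repeated runs."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two runs to summarise variation")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return VariationSummary(mean=mean, sd=sd,
                            cv_percent=sd / mean * 100.0,
                            range_max_minus_min=float(v.max() - v.min()),
                            n_runs=v.size)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV% from summary values alone: SD / mean x 100."""
    return sd / mean * 100.0


@dataclass
class EvalResult:
    """Full evaluation bundle mirroring a model-comparison table row."""

    per_class: dict            # class -> {"P": %, "R": %, "F1": %}
    overall: dict              # same keys, classes pooled
    map50: float
    map50_95: float

    def to_row(self) -> dict:
        row = {"P (%)": round(self.overall["P"], 1),
               "R (%)": round(self.overall["R"], 1),
               "mAP50 (%)": round(self.map50, 1),
               "mAP50-95 (%)": round(self.map50_95, 1),
               "F1 Score (%)": round(self.overall["F1"], 1)}
        return row


def evaluate(preds, gts, iou_threshold: float = 0.5) -> EvalResult:
    """Evaluate detections against ground truth at one matching threshold
    plus the mAP50/mAP50-95 pair."""
    classes = sorted({g.class_label for g in gts} |
                     {p.class_label for p in preds})
    per_class = {}
    for cls in classes:
        prf = precision_recall_f1(match(preds, gts, iou_threshold, cls))
        per_class[cls] = {"P": prf.precision, "R": prf.recall, "F1": prf.f1}
    overall_prf = precision_recall_f1(match(preds, gts, iou_threshold))
    map50, map50_95 = mean_ap(preds, gts)
    return EvalResult(per_class=per_class,
                      overall={"P": overall_prf.precision,
                               "R": overall_prf.recall,
                               "F1": overall_prf.f1},
                      map50=map50, map50_95=map50_95)
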