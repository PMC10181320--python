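"""Class-weighted cross-entropy, Lovász-softmax, the composite two-head
loss, and IoU/mIoU evaluation.

The composite loss supervises both heads: the voxel head with weighted
cross-entropy plus Lovász-softmax (a differentiable surrogate of 1 − IoU,
the quantity actually reported), the point head with weighted cross-entropy
alone, summed unweighted.  Class weights are reciprocal class frequencies
computed once over the whole training set, which is what keeps the minority
stem class from being swamped by ground and leaf points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, gather_rows, log_softmax, softmax

__all__ = [
    "ClassWeights",
    "SegmentationReport",
    "class_weights",
    "weighted_ce",
    "lovasz_softmax",
    "total_loss",
    "evaluate",
]


@dataclass(frozen=True)
class ClassWeights:
    """Reciprocal-frequency class weights; absent classes get weight 0 and
    are excluded from the loss."""

    weights: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "weights",
                           np.asarray(self.weights, dtype=np.float64))
        object.__setattr__(self, "frequencies",
                           np.asarray(self.frequencies, dtype=np.float64))


@dataclass
class SegmentationReport:
    """Confusion matrix (rows = truth, cols = prediction) with per-class
    IoU and their mean."""

    confusion: np.ndarray
    per_class_iou: np.ndarray
    miou: float
    class_names: list[str] | None = None
    source: str = ""
    target: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "target": self.target,
                "confusion": self.confusion.tolist(),
                "per_class_iou": self.per_class_iou.tolist(),
                "miou": self.miou,
                "class_names": self.class_names,
            },
            indent=2,
        )

    def format_table(self) -> str:
        """Percentages at two decimals: mIoU then per-class columns."""
        names = self.class_names or [
            f"class{i}" for i in range(len(self.per_class_iou))
        ]
        header = "mIoU    " + "".join(f"{n.capitalize():<8}" for n in names)
        row = f"{100 * self.miou:<8.2f}" + "".join(
            f"{100 * v:<8.2f}" for v in self.per_class_iou
        )
        return header + "\n" + row


def class_weights(labels, num_classes: int | None = None) -> ClassWeights:
    """Weights = 1 / class frequency over the (training-set) labels."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty label set")
    k = int(num_classes if num_classes is not None else labels.max() + 1)
    counts = np.bincount(labels, minlength=k).astype(np.float64)
    freq = counts / labels.size
    weights = np.zeros(k)
    present = counts > 0
    weights[present] = 1.0 / freq[present]
    return ClassWeights(weights=weights, frequencies=freq)


def weighted_ce(logits, labels, weights: ClassWeights | np.ndarray) -> Tensor:
    """Mean over rows of ``w[y]·(−log softmax(logits)[y])``.

    With unit weights this is the ordinary cross-entropy; it is linear in
    the weight vector.
    """
    x = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    k = x.data.shape[1]
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("label out of range")
    if labels.shape[0] != x.data.shape[0]:
        raise ValueError("logits/labels length mismatch")
    w = weights.weights if isinstance(weights, ClassWeights) \
        else np.asarray(weights, dtype=np.float64)
    logp = log_softmax(x, axis=1)
    nll = -logp[np.arange(len(labels)), labels]
    return (nll * w[labels]).mean()


def _jaccard_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Gradient of the Lovász extension of the Jaccard set loss, for one
    class's ground-truth indicator sorted by decreasing error."""
    n = len(gt_sorted)
    gts = gt_sorted.sum()
    intersection = gts - np.cumsum(gt_sorted)
    union = gts + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    if n > 1:
        jaccard[1:] = jaccard[1:] - jaccard[:-1]
    return jaccard


def lovasz_softmax(probs, labels, tol: float = 1e-5) -> Tensor:
    """Lovász-softmax loss, averaged over classes present in the labels.

    For each present class c: errors are ``1 − p_c`` on its points and
    ``p_c`` elsewhere; sorted descending, their inner product with the
    Lovász-extension gradient of the Jaccard loss is the class's
    contribution.  For hard 0/1 rows this equals ``1 − IoU_c`` exactly.
    """
    needs_grad = isinstance(probs, Tensor) and probs.requires_grad
    p_arr = probs.data if isinstance(probs, Tensor) else np.asarray(
        probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if p_arr.shape[0] != labels.shape[0]:
        raise ValueError("probs/labels length mismatch")
    rowsum = p_arr.sum(axis=1)
    if np.abs(rowsum - 1.0).max() > tol or p_arr.min() < -tol:
        raise ValueError("probability rows must lie on the simplex")
    present = np.unique(labels)
    if not needs_grad and p_arr.shape[0] <= 8:
        # tiny inputs: plain loops beat array-dispatch overhead
        labs = labels.tolist()
        total = 0.0
        for c in present.tolist():
            col = p_arr[:, c].tolist()
            errs = [abs((1.0 if l == c else 0.0) - pc)
                    for l, pc in zip(labs, col)]
            order = sorted(range(len(labs)), key=lambda i: -errs[i])
            gts = float(sum(1 for l in labs if l == c))
            inter, union, prev, acc = gts, gts, 0.0, 0.0
            for i in order:
                g = 1.0 if labs[i] == c else 0.0
                inter -= g
                union += 1.0 - g
                jac = 1.0 - inter / union
                acc += errs[i] * (jac - prev)
                prev = jac
            total += acc
        return Tensor(total / len(present))
    if not needs_grad:
        # evaluation-only fast path: identical arithmetic, vectorized over
        # the present classes, no tape
        fg = (labels[None, :] == present[:, None]).astype(np.float64)
        errors = np.abs(fg - p_arr[:, present].T)
        order = np.argsort(-errors, axis=1, kind="stable")
        es = np.take_along_axis(errors, order, 1)
        gs = np.take_along_axis(fg, order, 1)
        gts = gs.sum(axis=1, keepdims=True)
        inter = gts - np.cumsum(gs, axis=1)
        union = gts + np.cumsum(1.0 - gs, axis=1)
        jac = 1.0 - inter / union
        jac[:, 1:] = np.diff(jac, axis=1)
        return Tensor((es * jac).sum() / len(present))
    p = probs
    terms = []
    for c in present:
        fg = (labels == c).astype(np.float64)
        sign = 1.0 - 2.0 * fg                      # −1 on class-c points
        errors = Tensor(fg) + sign * p[:, int(c)]  # |fg − p_c|, affine in p
        order = np.argsort(-errors.data, kind="stable")
        grad = _jaccard_grad(fg[order])
        terms.append((gather_rows(errors, order) * grad).sum())
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / len(terms))


def total_loss(
    voxel_logits, voxel_labels, point_logits, point_labels,
    weights: ClassWeights,
) -> tuple[Tensor, Tensor, Tensor]:
    """Returns (total, voxel-head loss, point-head loss).

    voxel loss = weighted CE + Lovász-softmax on the voxel head;
    point loss = weighted CE on the point head; total = their plain sum.
    """
    v_ce = weighted_ce(voxel_logits, voxel_labels, weights)
    v_lov = lovasz_softmax(softmax(as_tensor(voxel_logits), axis=1),
                           voxel_labels)
    loss_v = v_ce + v_lov
    loss_p = weighted_ce(point_logits, point_labels, weights)
    return loss_v + loss_p, loss_v, loss_p


def evaluate(pred_labels, true_labels, num_classes: int,
             class_names: list[str] | None = None) -> SegmentationReport:
    """Exact confusion counts and IoU = TP/(TP+FN+FP) per class.

    A class absent from both truth and prediction scores IoU 1 (vacuously
    perfect); predicted-but-absent scores 0.
    """
    pred = np.asarray(pred_labels, dtype=np.int64)
    true = np.asarray(true_labels, dtype=np.int64)
    if pred.shape != true.shape:
        raise ValueError("length mismatch between predictions and truth")
    if pred.size and (
        min(pred.min(), true.min()) < 0
        or max(pred.max(), true.max()) >= num_classes
    ):
        raise ValueError("label out of range")
    confusion = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(confusion, (true, pred), 1)
    tp = np.diag(confusion).astype(np.float64)
    fn = confusion.sum(axis=1) - tp
    fp = confusion.sum(axis=0) - tp
    denom = tp + fn + fp
    iou = np.where(denom > 0, tp / np.maximum(denom, 1), 1.0)
    return SegmentationReport(
        confusion=confusion,
        per_class_iou=iou,
        miou=float(iou.mean()),
        class_names=class_names,
    )
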