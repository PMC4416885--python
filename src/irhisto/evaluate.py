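"""ROC analysis, confusion matrices and sample-level rejection calls.

The headline evaluation statistic is Pd@Pfa: the probability of
detection at a fixed probability of false alarm (default 10%), read off
a one-vs-rest ROC curve of per-pixel class posteriors against ground
truth.  Confusion tables are column-normalized per truth class (each
column sums to 100%), with an explicit "Unclassified" predicted row.

The sample-level call mirrors how a biopsy is graded for acute cellular
rejection: count lymphocyte pixels, group them into foci (8-connected
components above a minimum size) and check whether any lymphocyte pixel
encroaches on (is 8-adjacent to) myocardium.  A sample is called
positive only when the lymphocyte burden is non-negligible *and*
encroaching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import PixelMask
from .spectral_io import CLASS_NAMES

__all__ = [
    "ROCCurve",
    "ConfusionTable",
    "RejectionReport",
    "roc_one_vs_rest",
    "pd_at_pfa",
    "confusion",
    "rejection_report",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class ROCCurve:
    """Ordered (pfa, pd) pairs from (0,0) to (1,1), plus trapezoid AUC."""

    pfa: np.ndarray
    pd: np.ndarray
    auc: float
    class_code: int

    def __post_init__(self) -> None:
        self.pfa = np.asarray(self.pfa, dtype=np.float64)
        self.pd = np.asarray(self.pd, dtype=np.float64)
        if self.pfa.shape != self.pd.shape or self.pfa.ndim != 1:
            raise ValueError("pfa and pd must be matching 1-D arrays")
        if not (self.pfa[0] == 0 and self.pd[0] == 0
                and self.pfa[-1] == 1 and self.pd[-1] == 1):
            raise ValueError("ROC curve endpoints must be (0,0) and (1,1)")
        if np.any(np.diff(self.pfa) < 0) or np.any(np.diff(self.pd) < 0):
            raise ValueError("ROC curve must be non-decreasing in both axes")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"pfa": self.pfa, "pd": self.pd})


def _roc_from_scores(scores: np.ndarray, positive: np.ndarray,
                     class_code: int) -> ROCCurve:
    """Threshold sweep over unique score values (descending).

    Undefined scores (NaN) rank below every threshold: such positives are
    permanent misses, such negatives permanent true negatives — this keeps
    Pd honest about pixels the classifier declined to score.
    """
    scores = np.where(np.isfinite(scores), scores, -np.inf)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative pixels")
    order = np.argsort(-scores, kind="stable")
    sorted_pos = positive[order]
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    sorted_scores = scores[order]
    distinct = np.nonzero(sorted_scores[1:] != sorted_scores[:-1])[0]  # last index of each score
    tp = np.concatenate([[0], tp[distinct], [n_pos]])
    fp = np.concatenate([[0], fp[distinct], [n_neg]])
    pd_arr = tp / n_pos
    pfa_arr = fp / n_neg
    auc = float(np.trapezoid(pd_arr, pfa_arr))
    return ROCCurve(pfa_arr, pd_arr, auc, class_code)


def roc_one_vs_rest(posterior_c: np.ndarray, truth: np.ndarray,
                    mask: PixelMask, class_code: int) -> ROCCurve:
    """ROC of one class's posterior raster against ground truth.

    Only kept, truth-labeled pixels enter; positives are pixels whose
    truth equals ``class_code``.
    """
    truth = np.asarray(truth)
    posterior_c = np.asarray(posterior_c, dtype=np.float64)
    if posterior_c.shape != truth.shape or truth.shape != mask.keep.shape:
        raise ValueError("posterior, truth and mask shapes must match")
    eligible = mask.keep & (truth > 0)
    positive = truth[eligible] == class_code
    return _roc_from_scores(posterior_c[eligible], positive, class_code)


def pd_at_pfa(curve: ROCCurve, pfa_target: float = 0.10) -> float:
    """Pd linearly interpolated at the target Pfa.

    Vertical ROC segments (several Pd at one Pfa) resolve to the highest
    Pd, the achievable operating point.
    """
    if not 0.0 <= pfa_target <= 1.0:
        raise ValueError("pfa_target must be in [0, 1]")
    # collapse duplicate pfa values to their best pd
    uniq, inverse = np.unique(curve.pfa, return_inverse=True)
    best = np.zeros_like(uniq)
    np.maximum.at(best, inverse, curve.pd)
    return float(np.interp(pfa_target, uniq, best))


@dataclass
class ConfusionTable:
    """Counts and column-normalized percentages.

    ``counts[p, t]``: predicted code ``p`` (0..5, row 0 = Unclassified)
    against truth class ``t`` (1..5).  Percent columns are normalized to
    their truth-class totals, so each non-empty column sums to 100.
    """

    counts: np.ndarray
    percent: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.percent = np.asarray(self.percent, dtype=np.float64)
        if self.counts.shape != (6, 5) or self.percent.shape != (6, 5):
            raise ValueError("confusion table must be 6 predicted x 5 truth classes")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.percent,
            index=[CLASS_NAMES[c] for c in range(6)],
            columns=[CLASS_NAMES[c] for c in range(1, 6)],
        )


def confusion(pred: np.ndarray, truth: np.ndarray, mask: PixelMask) -> ConfusionTable:
    """Column-normalized confusion table over kept, truth-labeled pixels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or truth.shape != mask.keep.shape:
        raise ValueError("pred, truth and mask shapes must match")
    eligible = mask.keep & (truth > 0)
    if not eligible.any():
        raise ValueError("no kept truth-labeled pixels to evaluate")
    counts = np.zeros((6, 5), dtype=np.int64)
    for t in range(1, 6):
        sel = eligible & (truth == t)
        if sel.any():
            counts[:, t - 1] = np.bincount(pred[sel], minlength=6)[:6]
    totals = counts.sum(axis=0)
    percent = np.where(totals > 0, 100.0 * counts / np.where(totals > 0, totals, 1), 0.0)
    return ConfusionTable(counts, percent)


@dataclass
class RejectionReport:
    """Sample-level lymphocyte-infiltration summary and rejection call."""

    lymphocyte_pixels: int
    lymphocyte_foci: int
    encroaching: bool
    call: str                 # "positive" | "negative"
    tissue_pixels: int
    min_focus_size: int
    negligible_threshold: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def rejection_report(pred: np.ndarray, min_focus_size: int = 4,
                     negligible_fraction: float = 0.001) -> RejectionReport:
    """Quantify lymphocyte infiltration and call the sample.

    - ``lymphocyte_pixels``: count of pixels classified as lymphocytes;
    - ``lymphocyte_foci``: 8-connected lymphocyte components of size
      >= ``min_focus_size`` pixels;
    - ``encroaching``: any lymphocyte pixel 8-adjacent to myocardium;
    - ``call``: positive iff the lymphocyte pixel count exceeds
      ``negligible_fraction`` of tissue pixels *and* encroaches.
    """
    pred = np.asarray(pred)
    lymph = pred == 5
    tissue = pred > 0
    n_lymph = int(lymph.sum())
    n_tissue = int(tissue.sum())

    n_foci = 0
    if n_lymph:
        comp, n_comp = ndimage.label(lymph, structure=_EIGHT_CONNECTED)
        sizes = np.bincount(comp.ravel())[1:]
        n_foci = int((sizes >= min_focus_size).sum())

    encroaching = False
    if n_lymph:
        near_lymph = ndimage.binary_dilation(lymph, structure=_EIGHT_CONNECTED)
        encroaching = bool(np.any(near_lymph & (pred == 1)))

    negligible = negligible_fraction * n_tissue
    call = "positive" if (n_lymph > negligible and encroaching) else "negative"
    return RejectionReport(
        lymphocyte_pixels=n_lymph,
        lymphocyte_foci=n_foci,
        encroaching=encroaching,
        call=call,
        tissue_pixels=n_tissue,
        min_focus_size=min_focus_size,
        negligible_threshold=float(negligible),
    )
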