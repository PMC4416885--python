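"""Per-pixel Bayesian tissue classification.

Each histologic class gets, per spectral metric, a univariate likelihood
(Gaussian by default, optionally a Laplace-smoothed histogram density).
Pixels are assigned by weighted naive-Bayes fusion:

    posterior(c | x)  proportional to  prior(c) * prod_m L_c,m(x_m)^w_m

with metric weights w_m derived from each metric's one-vs-rest ROC AUC
(w_m = max(AUC_m - 0.5, 0), normalized to mean 1), so metrics that
separate classes better count more.  A pixel whose maximum posterior
falls below a threshold is left *unclassified* rather than forced into a
class — the honest option for mixed or atypical spectra.

Metric values that are NaN for a pixel are dropped from that pixel's
product (equivalent to likelihood 1); a pixel with no defined metric at
all has an undefined posterior and is always unclassified.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from .metrics import FeatureImage
from .preprocess import PixelMask
from .spectral_io import CLASS_NAMES

__all__ = [
    "MetricScore",
    "ClassifierConfig",
    "ClassModel",
    "score_metrics",
    "select_metrics",
    "fit",
    "posterior",
    "classify",
]

CLASS_CODES = (1, 2, 3, 4, 5)
_SD_FLOOR = 1e-6
_MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class MetricScore:
    """Separability of one metric for one class (one-vs-rest)."""

    metric_name: str
    class_code: int
    auc: float
    min_error: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0 and 0.0 <= self.min_error <= 0.5 + 1e-12):
            raise ValueError("scores out of range (auc in [0,1], min_error <= 0.5)")


@dataclass(frozen=True)
class ClassifierConfig:
    """Training/decision settings.

    priors: "uniform" or a mapping class_code -> probability (normalized).
    weight_mode: "auc" (AUC-excess weights) or "uniform".
    likelihood: "gaussian" or "histogram" (64 bins, Laplace-smoothed).
    posterior_threshold: minimum max-posterior to assign a class.
    k_per_class: if set, keep only the union over classes of the top-k
        metrics by AUC; None uses the whole library.
    """

    priors: str | dict[int, float] = "uniform"
    weight_mode: str = "auc"
    likelihood: str = "gaussian"
    posterior_threshold: float = 0.5
    k_per_class: int | None = None
    min_class_pixels: int = 20
    hist_bins: int = 64

    def __post_init__(self) -> None:
        if self.weight_mode not in ("auc", "uniform"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.likelihood not in ("gaussian", "histogram"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if not 0.0 <= self.posterior_threshold <= 1.0:
            raise ValueError("posterior_threshold must be in [0, 1]")


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """One-vs-rest AUC by the Mann-Whitney rank statistic (tie-aware)."""
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _min_error(pos: np.ndarray, neg: np.ndarray) -> float:
    """Minimum achievable misclassification rate over all thresholds and
    both orientations of a scalar score."""
    scores = np.concatenate([pos, neg])
    is_pos = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
    order = np.argsort(scores, kind="stable")
    is_pos = is_pos[order]
    n = scores.size
    # After sorting ascending: predicting "positive above threshold i"
    # errs on positives at/below i and negatives above i.
    pos_below = np.concatenate([[0], np.cumsum(is_pos)])
    neg_above = (neg.size - np.concatenate([[0], np.cumsum(~is_pos)]))
    err_up = (pos_below + neg_above) / n
    err_down = ((pos.size - pos_below) + (neg.size - neg_above)) / n
    return float(min(err_up.min(), err_down.min()))


def score_metrics(features: FeatureImage, truth: np.ndarray,
                  min_class_pixels: int = 20) -> list[MetricScore]:
    """AUC and minimum error of every (metric, class) one-vs-rest pair.

    Operates on kept, truth-labeled pixels; NaN metric values are dropped
    pairwise.  AUC is oriented so it is always >= 0.5.  Classes with fewer
    than ``min_class_pixels`` labeled pixels are skipped with a warning.
    """
    truth = np.asarray(truth)
    if truth.shape != features.mask.keep.shape:
        raise ValueError("truth shape does not match features")
    labeled = features.mask.keep & (truth > 0)
    values = features.values[labeled]
    classes = truth[labeled]
    usable = [c for c in CLASS_CODES
              if (classes == c).sum() >= min_class_pixels]
    for c in CLASS_CODES:
        if c not in usable:
            warnings.warn(f"class {CLASS_NAMES[c]} has <{min_class_pixels} labeled "
                          "pixels; skipped in metric scoring")
    if len(usable) < 2:
        raise ValueError("metric scoring needs >=2 classes with enough labeled pixels")

    scores: list[MetricScore] = []
    for j, name in enumerate(features.metric_names):
        col = values[:, j]
        defined = np.isfinite(col)
        for c in usable:
            pos = col[defined & (classes == c)]
            neg = col[defined & (classes != c)]
            if pos.size < 2 or neg.size < 2:
                continue
            auc = _rank_auc(pos, neg)
            if auc < 0.5:
                auc = 1.0 - auc
            scores.append(MetricScore(name, c, auc, _min_error(pos, neg)))
    return scores


def select_metrics(scores: list[MetricScore], k_per_class: int) -> list[str]:
    """Union over classes of each class's top-k metrics by AUC.

    Ties break by lower min_error, then by name; the result is ordered by
    (class code, rank) with duplicates removed, so selection is fully
    deterministic.
    """
    if k_per_class < 1:
        raise ValueError("k_per_class must be >= 1")
    selected: list[str] = []
    for c in CLASS_CODES:
        ranked = sorted((s for s in scores if s.class_code == c),
                        key=lambda s: (-s.auc, s.min_error, s.metric_name))
        n_avail = len(ranked)
        if 0 < n_avail < k_per_class:
            warnings.warn(f"k_per_class={k_per_class} exceeds the {n_avail} scored "
                          f"metrics for class {c}; capped")
        for s in ranked[:k_per_class]:
            if s.metric_name not in selected:
                selected.append(s.metric_name)
    return selected


@dataclass
class ClassModel:
    """Trained Bayesian pixel classifier (JSON-serializable)."""

    classes: tuple[int, ...]
    priors: dict[int, float]
    metric_names: list[str]
    weights: dict[str, float]
    likelihood: str                      # "gaussian" | "histogram"
    params: dict[int, dict[str, dict]]   # class -> metric -> likelihood params
    posterior_threshold: float
    scores: list[MetricScore] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("metric weights must be >= 0")
        missing = [m for m in self.metric_names if m not in self.weights]
        if missing:
            raise ValueError(f"weights missing for metrics: {missing}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": _MODEL_SCHEMA_VERSION,
            "classes": list(self.classes),
            "class_names": {c: CLASS_NAMES[c] for c in self.classes},
            "priors": {str(c): p for c, p in self.priors.items()},
            "metric_names": self.metric_names,
            "weights": self.weights,
            "likelihood": self.likelihood,
            "params": {str(c): m for c, m in self.params.items()},
            "posterior_threshold": self.posterior_threshold,
            "scores": [
                {"metric_name": s.metric_name, "class_code": s.class_code,
                 "auc": s.auc, "min_error": s.min_error}
                for s in self.scores
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClassModel":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and not source.lstrip().startswith("{")):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        if payload.get("schema_version") != _MODEL_SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        return cls(
            classes=tuple(payload["classes"]),
            priors={int(c): p for c, p in payload["priors"].items()},
            metric_names=list(payload["metric_names"]),
            weights=dict(payload["weights"]),
            likelihood=payload["likelihood"],
            params={int(c): m for c, m in payload["params"].items()},
            posterior_threshold=payload["posterior_threshold"],
            scores=[MetricScore(**s) for s in payload.get("scores", [])],
        )


def _fit_gaussian(x: np.ndarray) -> dict:
    x = np.sort(x)  # order-independent reduction: permutation-invariant fit
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return {"mean": mean, "sd": max(sd, _SD_FLOOR)}


def _fit_histogram(x: np.ndarray, edges: np.ndarray) -> dict:
    counts, _ = np.histogram(x, bins=edges)
    smoothed = counts + 1.0  # Laplace smoothing
    density = smoothed / (smoothed.sum() * np.diff(edges))
    return {"edges": edges.tolist(), "log_density": np.log(density).tolist()}


def fit(features: FeatureImage, truth: np.ndarray,
        config: ClassifierConfig = ClassifierConfig()) -> ClassModel:
    """Train the classifier on kept, truth-labeled pixels.

    Deterministic: duplicated or permuted training sets give the identical
    model.  Raises if any of the five classes is absent.
    """
    truth = np.asarray(truth)
    labeled = features.mask.keep & (truth > 0)
    values = features.values[labeled]
    classes = truth[labeled]
    for c in CLASS_CODES:
        if (classes == c).sum() == 0:
            raise ValueError(f"training set lacks class {CLASS_NAMES[c]}")

    scores = score_metrics(features, truth, config.min_class_pixels)
    if config.k_per_class is not None:
        metric_names = select_metrics(scores, config.k_per_class)
    else:
        metric_names = list(features.metric_names)

    best_auc = {name: max((s.auc for s in scores if s.metric_name == name), default=0.5)
                for name in metric_names}
    if config.weight_mode == "auc":
        raw = np.array([max(best_auc[m] - 0.5, 0.0) for m in metric_names])
        weights_arr = raw / raw.mean() if raw.sum() > 0 else np.ones(len(metric_names))
    else:
        weights_arr = np.ones(len(metric_names))
    weights = {m: float(w) for m, w in zip(metric_names, weights_arr)}

    if config.priors == "uniform":
        priors = {c: 1.0 / len(CLASS_CODES) for c in CLASS_CODES}
    else:
        total = sum(config.priors.values())
        priors = {int(c): p / total for c, p in config.priors.items()}

    col_index = {name: features.metric_names.index(name) for name in metric_names}
    params: dict[int, dict[str, dict]] = {}
    for c in CLASS_CODES:
        params[c] = {}
        for name in metric_names:
            x = values[classes == c, col_index[name]]
            x = x[np.isfinite(x)]
            if x.size == 0:
                raise ValueError(f"no defined values of {name} for class {CLASS_NAMES[c]}")
            if config.likelihood == "gaussian":
                params[c][name] = _fit_gaussian(x)
            else:
                pooled = values[:, col_index[name]]
                pooled = pooled[np.isfinite(pooled)]
                span = pooled.max() - pooled.min()
                pad = 1e-9 + 1e-3 * span
                edges = np.linspace(pooled.min() - pad, pooled.max() + pad,
                                    config.hist_bins + 1)
                params[c][name] = _fit_histogram(np.sort(x), edges)

    return ClassModel(
        classes=CLASS_CODES,
        priors=priors,
        metric_names=metric_names,
        weights=weights,
        likelihood=config.likelihood,
        params=params,
        posterior_threshold=config.posterior_threshold,
        scores=scores,
    )


_LOG_2PI = float(np.log(2.0 * np.pi))


def _log_likelihood(x: np.ndarray, spec: dict, likelihood: str) -> np.ndarray:
    if likelihood == "gaussian":
        mu, sd = spec["mean"], spec["sd"]
        return -0.5 * (((x - mu) / sd) ** 2 + _LOG_2PI) - np.log(sd)
    edges = np.asarray(spec["edges"])
    log_density = np.asarray(spec["log_density"])
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, log_density.size - 1)
    return log_density[idx]


def posterior(features: FeatureImage, model: ClassModel):
    """Per-pixel class posteriors.

    Returns ``(post, defined)`` where ``post[rows, cols, k]`` holds the
    posterior of ``model.classes[k]`` (normalized to sum 1, computed in
    the log domain) and ``defined`` flags pixels with at least one
    finite metric.  NaN metrics drop out of the fusion product.
    """
    missing = [m for m in model.metric_names if m not in features.metric_names]
    if missing:
        raise ValueError(f"features lack the model's metrics: {missing}")
    keep = features.mask.keep
    cols_idx = [features.metric_names.index(m) for m in model.metric_names]
    x = features.values[keep][:, cols_idx]          # (n_kept, n_metrics)
    finite = np.isfinite(x)
    x_safe = np.where(finite, x, 0.0)

    n, k = x.shape[0], len(model.classes)
    log_post = np.zeros((n, k), dtype=np.float64)
    for ki, c in enumerate(model.classes):
        acc = np.full(n, np.log(model.priors[c]))
        for j, name in enumerate(model.metric_names):
            ll = _log_likelihood(x_safe[:, j], model.params[c][name], model.likelihood)
            acc += model.weights[name] * np.where(finite[:, j], ll, 0.0)
        log_post[:, ki] = acc

    pixel_defined = finite.any(axis=1)
    norm = logsumexp(log_post, axis=1, keepdims=True)
    probs = np.exp(log_post - norm)

    rows, cols = keep.shape
    post = np.full((rows, cols, k), np.nan, dtype=np.float64)
    post[keep] = np.where(pixel_defined[:, None], probs, np.nan)
    defined = np.zeros((rows, cols), dtype=bool)
    defined[keep] = pixel_defined
    return post, defined


def classify(post: np.ndarray, mask: PixelMask, model: ClassModel,
             defined: np.ndarray | None = None) -> np.ndarray:
    """Label raster from posteriors.

    label = argmax-class posterior where the maximum is >= the model's
    posterior threshold, else 0 (unclassified).  Masked pixels are always
    0.  Argmax ties resolve to the lowest class code.
    """
    post = np.asarray(post)
    keep = mask.keep
    labels = np.zeros(keep.shape, dtype=np.int64)
    if defined is None:
        defined = np.isfinite(post).all(axis=-1)
    valid = keep & defined
    if valid.any():
        p = post[valid]
        best = np.argmax(p, axis=1)             # first (lowest-code) max wins
        best_p = p[np.arange(p.shape[0]), best]
        codes = np.asarray(model.classes)[best]
        codes[best_p < model.posterior_threshold] = 0
        labels[valid] = codes
    return labels
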