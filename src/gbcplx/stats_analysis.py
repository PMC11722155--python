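"""Decoy nulls, ROC discrimination, symmetrized regression and rescoring.

The decoy null for a complex is built by independently resampling surface
points from the two full molecular surfaces, pairing their potentials at
random; discrimination of true interfaces from such decoys (by concordant
fraction or by ec) is summarized by the ROC area under curve, computed in
its Mann–Whitney rank form with the usual tie convention (ties count ½).

Because a symmetrized scatter (each pair plotted twice, coordinates swapped)
has identical marginals, its least-squares slope equals the Pearson
correlation of the pairs exactly; this identity is exposed and tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateDataError, EmptyInputError
from .interface_analysis import complementarity
from .surface import PatchSet

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    """ROC curve and summary for a positive-vs-negative score split."""

    auc: float
    best_threshold: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class ScoredModel:
    """One rescored docking model: id, electrostatic complementarity, label."""

    model_id: str
    ec: float
    quality_label: str | None = None


QUALITY_LABELS = ("high", "medium", "acceptable", "incorrect")


def decoy_pairs(
    patches1: PatchSet,
    patches2: PatchSet,
    n_pairs: int,
    seed: int,
) -> list[tuple[float, float]]:
    """Random surface-potential pairs: one point drawn uniformly (with
    replacement) from each full surface, independently per pair."""
    if len(patches1) == 0 or len(patches2) == 0:
        raise EmptyInputError("cannot draw decoy pairs from an empty surface")
    if patches1.potential is None or patches2.potential is None:
        raise EmptyInputError("patches lack potentials")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, len(patches1), size=n_pairs)
    j = rng.integers(0, len(patches2), size=n_pairs)
    return list(zip(patches1.potential[i].tolist(), patches2.potential[j].tolist()))


def roc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> RocResult:
    """ROC analysis of a score that should be higher for positives.

    AUC is the Mann–Whitney statistic U/(n_pos·n_neg) with ties counted ½.
    The best threshold maximizes Youden's J = TPR − FPR; ties in J are broken
    toward higher specificity (lower FPR, then the higher threshold).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise EmptyInputError("both score lists must be non-empty")
    n_pos, n_neg = len(pos), len(neg)

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))

    # Curve: predict positive when score >= threshold, thresholds descending.
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    thr_list = [np.inf]
    for t in thresholds:
        tpr.append(float((pos >= t).mean()))
        fpr.append(float((neg >= t).mean()))
        thr_list.append(float(t))
    tpr_a = np.array(tpr)
    fpr_a = np.array(fpr)
    thr_a = np.array(thr_list)

    j = tpr_a - fpr_a
    best_j = j.max()
    cand = np.flatnonzero(j == best_j)
    cand = cand[fpr_a[cand] == fpr_a[cand].min()]
    best = cand[np.argmax(thr_a[cand])]
    best_threshold = float(thr_a[best]) if np.isfinite(thr_a[best]) else float(thresholds[0])
    return RocResult(auc=auc, best_threshold=best_threshold, fpr=fpr_a, tpr=tpr_a, thresholds=thr_a)


def symmetrized_regression(pairs) -> tuple[float, float]:
    """OLS fit to the symmetrized scatter (each pair plotted twice, swapped).

    Returns (slope, intercept).  Since both marginals of the symmetrized set
    coincide, the slope equals the Pearson r of the pairs and the intercept
    is mean·(1 − slope).
    """
    arr = np.asarray(
        [(p[0], p[1]) for p in pairs] if not isinstance(pairs, tuple) else np.column_stack(pairs),
        dtype=float,
    ).reshape(-1, 2)
    if len(arr) < 2:
        raise DegenerateDataError("need at least 2 pairs")
    x = np.concatenate([arr[:, 0], arr[:, 1]])
    y = np.concatenate([arr[:, 1], arr[:, 0]])
    vx = x.var()
    if vx == 0:
        raise DegenerateDataError("zero variance after symmetrization; slope undefined")
    slope = float(((x - x.mean()) * (y - y.mean())).mean() / vx)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def rescore_models(
    models: Iterable[tuple[str, object, str | None]],
    ec_fn: Callable[[object], float],
) -> list[ScoredModel]:
    """Rescore docking models by electrostatic complementarity.

    ``models`` yields (model_id, model_input, quality_label_or_None);
    ``ec_fn`` maps a model input to its ec (e.g. the pipeline's
    ``electrostatic_complementarity``).  Models whose analysis raises are
    skipped with a logged reason.  The result is sorted by descending ec,
    stably (ties keep input order).
    """
    scored: list[ScoredModel] = []
    for model_id, model_input, label in models:
        if label is not None and label not in QUALITY_LABELS:
            raise ValueError(f"unknown quality label {label!r}")
        try:
            ec = float(ec_fn(model_input))
        except Exception as exc:  # noqa: BLE001 - individual failures are not fatal
            logger.warning("model %s skipped: %s", model_id, exc)
            continue
        scored.append(ScoredModel(model_id=model_id, ec=ec, quality_label=label))
    return sorted(scored, key=lambda m: -m.ec)


def ec_histogram(
    scored: Sequence[ScoredModel],
    lo: float = -0.5,
    hi: float = 1.0,
    width: float = 0.1,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-quality-label histograms of ec over fixed bins (default −0.5..1,
    width 0.1).  Values outside the range are clipped into the edge bins so
    counts always sum to the number of scored models."""
    edges = np.round(np.arange(lo, hi + width / 2, width), 10)
    n_bins = len(edges) - 1
    labels = sorted({m.quality_label or "unlabeled" for m in scored})
    counts = {lab: np.zeros(n_bins, dtype=int) for lab in labels}
    for m in scored:
        b = int(np.clip((m.ec - lo) // width, 0, n_bins - 1))
        counts[m.quality_label or "unlabeled"][b] += 1
    return edges, counts


def top_fraction_composition(
    scored: Sequence[ScoredModel], fraction: float = 0.1
) -> dict[str, int]:
    """Label composition of the top-ranked fraction (default top decile)."""
    k = max(1, int(round(len(scored) * fraction)))
    comp: dict[str, int] = {}
    for m in list(scored)[:k]:
        lab = m.quality_label or "unlabeled"
        comp[lab] = comp.get(lab, 0) + 1
    return comp
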